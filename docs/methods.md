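# Methods

## Model and estimand

The package implements one-sample Mendelian randomization (MR) for a
continuous, log-scale exposure `x` (a derived lipid concentration such as
remnant cholesterol) against continuous or binary outcomes `y`, using a
weighted genetic risk score (WGRS) as a single composite instrument.

Structural model assumed by the forward analysis:

```
x_i = Σ_j γ_j g_ij + c'z_i + a_x u_i + ε_i          (exposure)
y_i = β x_i + Σ_j δ_j g_ij + d'z_i + a_y u_i + η_i  (outcome, linear predictor)
```

with dosages `g_ij ∈ {0,1,2}`, measured covariates `z` (age, sex, BMI,
smoking), an unobserved confounder `u`, and per-variant direct effects `δ_j`
that are zero for valid instruments.  Binary outcomes replace the Gaussian
error with a Bernoulli draw through the logistic link.  The estimand is `β`.

The three instrumental-variable assumptions take their usual form: relevance
(the score predicts `x`; checked by the first-stage partial F with the
conventional `F > 10` bound), independence (the score is unrelated to `u`;
guaranteed in simulation by random assortment of alleles), and exclusion
restriction (`δ_j = 0`; screened by the cross-adjusted exclusion rule and
stressed by the sensitivity suite).

Estimation is two-stage least squares with the WGRS.  With one instrument the
2SLS coefficient equals the Wald ratio `β̂ = β̂_GY / β̂_GX`, and the package
asserts this identity to 1e-8 in the linear case.  The reported standard
error is the first-order Wald scaling `se_GY / |β̂_GX|`, which ignores
first-stage noise; at the stage-one F values the pipeline requires (hundreds
to thousands) the neglected term is O(1/F).  For binary outcomes the second
stage enters the fitted exposure in a logistic model (predictor
substitution); the control-function alternative is intentionally out of v1.

### Verdict rule

With Bonferroni level `α = 0.002` (0.05 over 11 outcome traits × 2
directions), a direction is called

* `not_causal` when the base reduced form is null (`p_a ≥ α`);
* `causal` when the fully adjusted score–outcome association survives
  (`p_b < α`) while conditioning on the exposure removes it (`p_c ≥ α`) —
  the mediation signature of a genuine exposure-mediated path;
* `indeterminate` otherwise, including exact boundary ties (`p = α`) and
  missing tiers.

Because published tables print p values at coarse precision, the comparison
of `p_b` against α is configurable (`strict` default, `rounded` to 3
decimals).

## Per-variant machinery

* **Association scans.**  Linear scans are exact OLS computed by the
  Frisch–Waugh–Lovell residualization route (the covariate design is shared
  across variants), which makes 500-replicate Monte-Carlo studies cheap; the
  suite checks bit-level agreement with the normal equations.  Logistic scans
  are per-variant maximum-likelihood fits via statsmodels; non-convergence
  and separation raise, never silently degrade.
* **HWE.**  The exact conditional test (probability of heterozygote counts no
  more probable than observed, given allele counts) computed in log space
  over the full support; verified against exact rational-arithmetic
  enumeration for every table with total ≤ 30.  A χ² variant exists for
  large-count use.  QC default: exclude leads with HWE p < 1e-6.
* **Lead selection.**  Greedy over candidates sorted by (p, position, id) —
  a total order, so results are independent of input order.  A candidate is
  kept iff its sample r² with every retained lead within 1 Mb stays below
  0.2.  The window is standard for "independent loci within 1 Mb"; the r²
  cutoff is the conventional clumping default and is configurable, since
  source analyses of this design typically state the window but not the
  cutoff.  Every removal is logged with a reason (`LD`, `HWE`, `weak`,
  `window` for unplaceable positions).
* **Cross-adjusted exclusion.**  Forward: drop lead `j` if
  `p(g_j → y | z, x) < 0.01`; reverse: drop if `p(g_j → x | z, y) < 0.01`.
  An empty survivor set raises a dedicated error and the bidirectional
  driver reports the direction as skipped with the reason — the honest
  outcome when a trait's entire panel is entangled with the other trait.

## Sensitivity estimators

Per-variant Wald ratios `r_j = β_Yj / β_Xj` carry first-order standard errors
`se_j = se_Yj / |β_Xj|` (a second-order delta option exists; the first-order
form is the default because source analyses rarely specify otherwise).
Variants are oriented so `β_Xj > 0` by flipping `(β_Xj, β_Yj)` jointly —
every estimator is invariant to the flip, but the Egger intercept is only
interpretable in this frame.

* **IVW**: inverse-variance-weighted mean; random-effects variant scales the
  SE by √φ with multiplicative overdispersion `φ = max(1, Q/(J−1))`.
  Multiplicative (rather than additive-τ²) dispersion is the stable choice at
  the small J of WGRS panels.
* **MR-Egger**: WLS of `β_Y` on `β_X` with weights `1/se_Y²` and a free
  intercept; with the ratio weighting above, the zero-intercept slope is
  *exactly* fixed-effect IVW, an identity the suite asserts.
* **Medians**: interpolated crossing of cumulative standardized weights at
  0.5; simple = equal weights; SE by seeded parametric bootstrap (1000
  replicates by default).
* **Heterogeneity**: Cochran's Q around IVW (J−1 df) and Rücker's Q′ around
  the Egger line (J−2 df) with shared weights, so `Q ≥ Q′` identically and
  the gap is the intercept's contribution.

## The synthetic cohort

The generator emulates exactly what the estimators assume, no more:

* independent variants drawn Binomial(2, maf) — HWE holds by construction;
  optional LD blocks from a two-haplotype Gaussian copula with
  block-constant latent ρ (closed-form target r² provided for testing LD
  pruning);
* covariates: age ~ U(30, 70) (a population-cohort recruitment range), sex ~
  Bernoulli(0.5), BMI ~ lognormal around 24 kg/m², smoking ~ Bernoulli(0.25);
  small documented effects on both traits;
* confounder `u ~ N(0,1)` loading on both traits;
* binary outcomes calibrated to a target prevalence by bisection on the
  intercept of the logistic mean — unattainable targets raise;
* reverse scenarios generate the risk-factor trait first from its own
  variants and give the exposure `reverse_beta ×` the trait.

Determinism: one global seed feeds a named substream per stage (specs,
covariates, confounder, genotypes, exposure noise, outcome noise), so adding
a stage never shifts another's draws and identical configurations are
byte-reproducible.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| panel size | 50 variants | the scale of lead-variant panels for lipid traits |
| heritability (continuous exposure) | 0.15 of covariate-free variance | a realistic share for a genome-wide-significant lipid panel; exposed as a free parameter because the attributable share is not identifiable from published summaries |
| reverse (binary-trait) panel | 16 variants, latent log-odds variance 0.5 | per-allele odds ratios ≈ 1.3, the magnitude at which common-disease lead variants actually reach 5×10⁻⁸ at these sample sizes |
| causal β (forward preset) | 0.5 | large enough for single-cohort power, small enough that logistic noncollapsibility stays visible rather than dominant |
| reverse β | 0.07 | exposure units per case, the order of magnitude seen in reverse lipid-MR summary rows |
| confounder loadings | 0.2 / 0.2 (0.5/0.5 in the `confounded` preset) | moderate confounding: observational bias ≈ 0.04, detectable at high power over 200 replicates, while the many-instrument 2SLS bias (≈ OLS bias × K/concentration ≈ 6×10⁻⁴) stays negligible |
| pleiotropic preset | δ = ±0.1 on 30% of the panel, oriented with the exposure-raising allele | see orientation note below |
| prevalence (binary outcomes) | 0.08 | diabetes-like |

Monte-Carlo problem sizes: the recovery study uses 200 replicates at
n = 20,000 with the 50-variant panel; calibration 500 replicates at
n = 10,000; exclusion 100 replicates at n = 10,000.  These sizes put the
Monte-Carlo SE of each summary well below the effects being measured while
keeping each study in the tens of seconds on one core.

### What the generator does **not** model

Real LD maps and imputation uncertainty, population stratification and
relatedness, assay noise in the lipid panel, selection into the cohort, and
time-varying exposures.  Passing tests therefore demonstrate the estimators'
correctness under the stated structural model — not robustness to those
real-data complications.

## Design notes from validation

Two behaviors surfaced while validating the pipeline and are properties of
the *design*, not implementation artifacts:

1. **The cross-adjusted exclusion rule is a collider filter under
   confounding.**  The rule regresses the outcome on each variant
   *conditioning on the exposure*.  The exposure is a collider between each
   variant and the confounder, so when confounding is active every valid
   variant acquires a cross-adjusted outcome association proportional to
   `−γ_j`: the filter preferentially removes the strongest instruments and
   its removals correlate with in-sample noise, which shifts the pooled 2SLS
   mean upward by a small amount (≈ +0.007 at n = 20,000, K = 50, loadings
   0.2/0.2).  Consequently the parameter-recovery and calibration studies
   take the valid panel as given, and the rule's operating characteristics
   (hit rate on planted violations ≈ 98%, false-exclusion ≈ 1%) are measured
   by a dedicated study.
2. **Directional pleiotropy must be planted in the oriented frame.**  A
   direct effect with fixed sign per *effect allele* averages to zero after
   the standard positive-β_X orientation (gamma signs are random), silencing
   the Egger intercept.  The generator therefore orients planted δ with the
   exposure-raising allele.  Even then, intercept power is capped by the
   zero/nonzero δ-mixture geometry and grows with panel size J and
   per-variant instrument strength — not with n alone — so the positive
   control runs on a 150-variant panel at n = 20,000, where detection is
   ≈ 85–90%.

Known limitations beyond these: predictor-substitution logistic 2SLS is
noncollapsible — the residual exposure variance acts as unmodeled
heterogeneity and attenuates large conditional log-odds ratios (about 10% at
β = ln 2 with unit residual variance; negligible at β ≤ 0.3); the Wald SE
ignores first-stage noise (O(1/F)); and one-sample weights estimated in the
analysis cohort carry the usual many-weak-instrument bias toward the
observational slope, of order K divided by the concentration parameter.

## Numerical choices

Quartile ties go to the lower quartile (deterministic, order-independent).
Negative derived RC values are retained and flagged rather than dropped, so
participant alignment for MR is preserved; log-scale analyses list-wise
delete non-positive values, consistent with the list-wise missing-data policy
used throughout.  Stepwise regression is forward-only with partial-F entry at
p < 0.05 and reports the R² increment at entry; exactly collinear candidates
are skipped.  Perfect first-stage fits report a +inf F sentinel.  Wald
scaling refuses `|β_GX|` below 1e-12.  The weighted-median bootstrap and all
simulation streams are seeded from the run configuration.
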