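# rcmr

Bidirectional **one-sample Mendelian randomization** (MR) with **weighted
genetic risk score (WGRS)** instruments, built around the kind of question a
lipid epidemiologist asks: does remnant cholesterol (RC = TC − HDL-C − LDL-C)
*cause* cardiometabolic risk factors such as diabetes, hypertension or fatty
liver disease, or do those conditions raise RC — or is the observational
association just confounding?

Because individual-level biobank data of this kind are access-controlled, the
package ships a first-class synthetic-cohort generator that reproduces the
statistical structure such an analysis assumes (and, for negative controls,
deliberately violates it), so the entire pipeline is testable end to end on a
laptop.

## The method

For exposure trait `T_A`, outcome trait `T_B` and a panel of lead variants
with per-allele exposure effects `w_j` from the cohort's own GWAS:

1. **GWAS** — per-variant additive association of dosage `g_j ∈ {0,1,2}` with
   the (log-scale) exposure, adjusted for age, sex, BMI and smoking;
   genome-wide significance at `p < 5×10⁻⁸`; Hardy–Weinberg exact-test QC; LD
   pruning of leads within a 1 Mb window at `r² ≥ 0.2`.
2. **Instrument construction** — drop any lead associated with the *other*
   trait after cross-adjustment (`p < 0.01`), the guard against horizontal
   pleiotropy; sum the survivors into the score `G_A = Σ_j w_j g_j`; require
   first-stage partial `F > 10`.
3. **Two-stage least squares** — stage 1: `T_A ~ G_A + covariates`; stage 2:
   `T_B` on the fitted exposure (logistic for binary outcomes). With the
   single composite instrument this equals the Wald ratio
   `β_IV = β(G_A→T_B) / β(G_A→T_A)`, with first-order
   `SE_IV = SE(G_A→T_B)/|β(G_A→T_A)|`.
   Adjustment tiers give `p_a` (base covariates), `p_b` (+ further
   confounders, e.g. LDL-C), `p_c` (+ the exposure itself); the
   Bonferroni verdict (`α = 0.002 = 0.05/11/2`) calls a direction *causal*
   when the association survives full adjustment (`p_b < α`) but vanishes
   once the exposure is conditioned on (`p_c ≥ α`).
4. **Sensitivity suite** — per-variant Wald ratios feed fixed/random-effects
   IVW, MR-Egger (intercept = directional pleiotropy test), simple and
   weighted medians, Cochran's Q and Rücker's Q′, plus funnel/scatter tables.

Both directions (forward: `T_A → T_B`; reverse: `T_B → T_A`) run with their
own independently selected instruments.

## Worked example

```python
import rcmr

cfg = rcmr.scenario("forward-causal", n=20_000, seed=7)   # truth: beta = 0.5, confounded
cohort = rcmr.simulate_cohort(cfg)
res = rcmr.run_bidirectional(cohort)
```

The forward direction prints (50-variant panel, 26 genome-wide-significant
leads retained after selection and exclusion):

```
instruments retained: 26
stage-one F:          3300.9
first stage  (G-T_A): beta=0.977 se=0.017
reduced form (G-T_B): beta=0.479 se=0.021 p=1.75e-114
IV estimate (IV-T_B): beta=0.490 se=0.021
observational (T_A-T_B): beta=0.537 se=0.007
p_b=1.75e-114  p_c=0.008  verdict=causal
IVW fixed: 0.490 (se 0.021); Egger slope 0.528, intercept p 0.51
weighted median: 0.502; Cochran Q p 0.94
```

Read it like a summary-table row: the first-stage coefficient is ≈1 because
the score is built from the exposure's own GWAS weights; the IV estimate
(0.490 ± 0.021) recovers the planted causal effect 0.5 while the
observational slope (0.537) carries the planted confounding; the verdict is
*causal* because the score–outcome association survives adjustment but
disappears once the exposure itself enters the model (`p_c = 0.008 ≥ 0.002`).
The reverse direction is skipped with an explicit reason — every candidate
instrument fails the cross-adjusted exclusion rule, as it should when the
genetics belong to the exposure.

The same pipeline is scriptable from a shell:

```sh
rcmr simulate --scenario forward-causal --n 20000 --seed 7 --out-prefix sim/cohort
rcmr gwas --vcf sim/cohort.vcf --phenotypes sim/cohort.phenotypes.tsv \
          --trait exposure --out sim/exposure.tsv
rcmr mr   --vcf sim/cohort.vcf --phenotypes sim/cohort.phenotypes.tsv \
          --direction both --out-prefix sim/run
```

## Layout

| module | contents |
|---|---|
| `rcmr.simulate` | variant/scenario specs, genotype–phenotype cohort generator, presets |
| `rcmr.phenotypes` | RC derivation, unit conversion, quartiles, logistic associations, stepwise regression |
| `rcmr.gwas` | per-variant scans, HWE exact test, significance, LD-aware lead selection, F statistics |
| `rcmr.instruments` | WGRS, cross-adjusted pleiotropy exclusion, stage-one strength |
| `rcmr.mr` | 2SLS/Wald engine, adjustment tiers, verdicts, bidirectional driver |
| `rcmr.sensitivity` | ratio bookkeeping, IVW, MR-Egger, medians, Q/Q′, funnel/scatter |
| `rcmr.evaluate` | Monte-Carlo recovery / calibration / exclusion studies |
| `rcmr.io`, `rcmr.cli` | VCF + TSV interchange, `rcmr` command group |

See `docs/methods.md` for the model, the generator's scope, and the design
decisions (including two subtleties found while validating: the collider
behavior of the cross-adjusted exclusion rule under confounding, and the
orientation convention required for planted directional pleiotropy).
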