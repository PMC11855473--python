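"""Synthetic genotype-phenotype cohorts for one-sample Mendelian randomization.

The generator produces cohorts with the statistical structure an MR analysis of
a log-scale lipid exposure assumes -- or deliberately violates, for negative
controls:

* independent biallelic variants drawn Binomial(2, maf), so Hardy-Weinberg
  equilibrium holds by construction; optional LD blocks are induced by a
  Gaussian copula on the haplotype latents with block-constant correlation;
* a continuous exposure generated directly on the analysis (log) scale as a
  linear function of dosages, covariates, a shared unobserved confounder U,
  and Gaussian noise;
* outcomes that are either linear or logistic in the exposure, with optional
  per-variant direct (horizontal-pleiotropy) effects and an intercept solved
  by bisection so a binary outcome attains a target prevalence;
* a reverse-causation variant in which the risk-factor trait is generated
  first from its own variants and the exposure receives ``reverse_beta`` times
  the trait.

Determinism contract: one global integer seed feeds a named stream per stage
(variant specs, covariates, confounder, genotypes, exposure noise, outcome
noise), so adding a stage never shifts the draws of another, and an identical
:class:`ScenarioConfig` reproduces the cohort bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, ndtri

from .exceptions import PrevalenceError, SimulationError

__all__ = [
    "VariantSpec",
    "ScenarioConfig",
    "SimulatedExposure",
    "Cohort",
    "SCENARIOS",
    "stream",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_exposure",
    "simulate_outcome",
    "simulate_reverse",
    "simulate_cohort",
    "scenario",
    "block_target_r2",
]

NUCLEOTIDES = frozenset("ACGT")


def stream(seed: int, name: str) -> np.random.Generator:
    """Named, seed-derived random stream.

    The stream key mixes the global seed with a CRC of the stage name, so each
    stage owns an independent substream and new stages can be added without
    perturbing existing ones.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf8"))])
    )


@dataclass(frozen=True)
class VariantSpec:
    """One simulated biallelic variant.

    ``gamma`` is the per-effect-allele additive effect on the exposure
    (exposure units per allele); ``delta`` is a direct effect on the outcome
    linear predictor, i.e. a planted exclusion-restriction violation.
    Variants sharing an ``ld_block`` label are correlated with the block's
    latent rho; variants with ``ld_block=None`` are independent.
    """

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf: float
    gamma: float = 0.0
    delta: float = 0.0
    ld_block: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise SimulationError(f"{self.id}: maf must be in (0, 0.5], got {self.maf}")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in NUCLEOTIDES:
                raise SimulationError(f"{self.id}: allele {allele!r} is not a single nucleotide")
        if self.effect_allele == self.other_allele:
            raise SimulationError(f"{self.id}: effect and other allele are identical")
        if self.pos < 1:
            raise SimulationError(f"{self.id}: positions are 1-based, got {self.pos}")


# default per-covariate effects; ages are centered at 50 years and BMI at
# 24 kg/m^2 before multiplying, so the trait intercept stays interpretable
_EXPOSURE_COV_EFFECTS = {"age": 0.003, "sex": -0.10, "bmi": 0.010, "smoking": 0.08}
_OUTCOME_COV_EFFECTS = {"age": 0.02, "sex": 0.20, "bmi": 0.05, "smoking": 0.25}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full generative description of a cohort; the seed determines the output.

    At most one of ``causal_beta`` (exposure -> outcome) and ``reverse_beta``
    (outcome -> exposure) may be nonzero in a preset scenario.  The exposure
    noise standard deviation may be given directly (``noise_sd``) or derived
    from ``heritability``, the share of the covariate-free exposure variance
    attributable to genetics.
    """

    n: int
    variants: tuple[VariantSpec, ...]
    seed: int = 0
    heritability: float | None = 0.15
    noise_sd: float | None = None
    confounder_exposure: float = 0.0
    confounder_outcome: float = 0.0
    causal_beta: float = 0.0
    reverse_beta: float = 0.0
    outcome_family: str = "gaussian"
    prevalence: float = 0.08
    outcome_noise_sd: float = 1.0
    block_rho: float = 0.9
    exposure_covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(_EXPOSURE_COV_EFFECTS)
    )
    outcome_covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(_OUTCOME_COV_EFFECTS)
    )
    smoking_rate: float = 0.25
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SimulationError("n must be >= 1")
        if not self.variants:
            raise SimulationError("at least one variant is required")
        if self.outcome_family not in ("gaussian", "binary"):
            raise SimulationError(f"unknown outcome family {self.outcome_family!r}")
        if self.outcome_family == "binary" and not (0.0 < self.prevalence < 1.0):
            raise SimulationError("prevalence must be in (0, 1)")
        if (self.heritability is None) == (self.noise_sd is None):
            raise SimulationError("exactly one of heritability and noise_sd must be set")
        if self.heritability is not None and not (0.0 < self.heritability < 1.0):
            raise SimulationError("heritability must be in (0, 1)")
        if self.causal_beta != 0.0 and self.reverse_beta != 0.0 and self.name != "custom":
            raise SimulationError("presets allow at most one nonzero causal direction")


@dataclass
class SimulatedExposure:
    """Exposure vector plus the realized share of variance explained by genetics."""

    values: np.ndarray
    genetic_variance_share: float


@dataclass
class Cohort:
    """Participant-aligned dosages, variant annotations and phenotype table."""

    dosages: np.ndarray  # (n, m) values in {0, 1, 2}
    variants: tuple[VariantSpec, ...]
    phenotypes: pd.DataFrame  # participant_id, age, sex, bmi, smoking, exposure, outcome
    confounder: np.ndarray  # the latent U -- never used by the analysis stages
    config: ScenarioConfig

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [v.id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "maf": [v.maf for v in self.variants],
                "ld_block": [v.ld_block for v in self.variants],
            }
        )


def simulate_genotypes(
    specs: list[VariantSpec] | tuple[VariantSpec, ...],
    n: int,
    seed_or_rng: int | np.random.Generator,
    block_rho: float = 0.9,
) -> np.ndarray:
    """Draw an (n, m) hard-call dosage matrix.

    Independent variants are Binomial(2, maf), so HWE holds exactly.  Variants
    in an LD block are generated from two haplotype layers of an equicorrelated
    Gaussian copula (shared factor sqrt(rho), idiosyncratic sqrt(1-rho)),
    thresholded at the allele-frequency quantile; marginals stay Binomial(2,
    maf) and the block attains the r^2 given by :func:`block_target_r2`.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    specs = tuple(specs)
    if not specs:
        raise SimulationError("specs must be nonempty")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else stream(seed_or_rng, "genotypes")
    m = len(specs)
    G = np.empty((n, m), dtype=np.int8)

    blocks: dict[int, list[int]] = {}
    independent: list[int] = []
    for j, spec in enumerate(specs):
        if spec.ld_block is None:
            independent.append(j)
        else:
            blocks.setdefault(spec.ld_block, []).append(j)

    if independent:
        mafs = np.array([specs[j].maf for j in independent])
        G[:, independent] = rng.binomial(2, mafs, size=(n, len(mafs))).astype(np.int8)

    for _, idx in sorted(blocks.items()):
        k = len(idx)
        thresholds = ndtri([specs[j].maf for j in idx])
        dos = np.zeros((n, k), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, k))
            z = np.sqrt(block_rho) * shared + np.sqrt(1.0 - block_rho) * noise
            dos += (z < thresholds).astype(np.int8)
        G[:, idx] = dos
    return G


def block_target_r2(maf_a: float, maf_b: float, rho: float) -> float:
    """Closed-form genotype r^2 for two copula-block variants with latent rho.

    The allele indicators are threshold exceedances of a bivariate normal, so
    their correlation is ``(Phi2(t_a, t_b; rho) - p_a p_b) / sqrt(p_a q_a p_b
    q_b)``; summing two independent haplotypes leaves the correlation
    unchanged, and r^2 is its square.
    """
    t_a, t_b = ndtri(maf_a), ndtri(maf_b)
    joint = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([t_a, t_b])
    r = (joint - maf_a * maf_b) / np.sqrt(
        maf_a * (1 - maf_a) * maf_b * (1 - maf_b)
    )
    return float(r**2)


def simulate_covariates(n: int, seed_or_rng: int | np.random.Generator, smoking_rate: float = 0.25) -> pd.DataFrame:
    """Age ~ U(30, 70), sex ~ Bernoulli(0.5), BMI ~ lognormal around 24, smoking ~ Bernoulli."""
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else stream(seed_or_rng, "covariates")
    return pd.DataFrame(
        {
            "age": rng.uniform(30.0, 70.0, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": np.exp(rng.normal(np.log(24.0), 0.15, n)),
            "smoking": (rng.random(n) < smoking_rate).astype(float),
        }
    )


def _covariate_term(covariates: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    term = np.zeros(len(covariates))
    centers = {"age": 50.0, "bmi": 24.0}
    for name, eff in effects.items():
        if eff == 0.0:
            continue
        if name not in covariates.columns:
            raise SimulationError(f"covariate {name!r} missing from table")
        term += eff * (covariates[name].to_numpy(float) - centers.get(name, 0.0))
    return term


def _genetic_variance(specs: tuple[VariantSpec, ...], which: str = "gamma") -> float:
    """Theoretical variance of the additive genetic score (independent variants)."""
    return float(
        sum(2.0 * s.maf * (1.0 - s.maf) * getattr(s, which) ** 2 for s in specs)
    )


def exposure_noise_sd(config: ScenarioConfig) -> float:
    """Noise sd implied by the heritability target (or the explicit noise_sd).

    Heritability is defined against the covariate-free part of the exposure
    variance: var_g / (var_g + c_U^2 + sigma^2) = h^2.
    """
    if config.noise_sd is not None:
        return float(config.noise_sd)
    var_g = _genetic_variance(config.variants, "gamma")
    h2 = float(config.heritability)  # type: ignore[arg-type]
    resid = var_g * (1.0 - h2) / h2 - config.confounder_exposure**2
    if resid <= 0:
        raise SimulationError(
            "heritability target unattainable with this confounder loading; "
            "lower confounder_exposure or heritability"
        )
    return float(np.sqrt(resid))


def simulate_exposure(
    dosages: np.ndarray,
    specs: list[VariantSpec] | tuple[VariantSpec, ...],
    covariates: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    confounder: np.ndarray | None = None,
) -> SimulatedExposure:
    """Linear-in-dosage exposure on the analysis (log) scale.

    ``x_i = sum_j gamma_j g_ij + covariate terms + c_U U_i + eps_i``.
    """
    specs = tuple(specs)
    G = np.asarray(dosages, dtype=float)
    if G.shape[1] != len(specs):
        raise SimulationError("dosage matrix and specs disagree on variant count")
    if G.shape[0] != len(covariates):
        raise SimulationError("dosage matrix and covariates disagree on participants")
    rng = rng if rng is not None else stream(config.seed, "exposure")
    if confounder is None:
        confounder = np.zeros(G.shape[0])
    gamma = np.array([s.gamma for s in specs])
    genetic = G @ gamma
    sd = exposure_noise_sd(config)
    x = (
        genetic
        + _covariate_term(covariates, config.exposure_covariate_effects)
        + config.confounder_exposure * confounder
        + (sd * rng.standard_normal(G.shape[0]) if sd > 0 else 0.0)
    )
    total_var = float(np.var(x))
    share = float(np.var(genetic) / total_var) if total_var > 0 else 0.0
    return SimulatedExposure(values=x, genetic_variance_share=share)


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept c with mean(expit(c + eta)) = prevalence, by bracketed root finding."""
    lo, hi = -40.0, 40.0
    f = lambda c: float(np.mean(expit(c + eta))) - prevalence
    if f(lo) > 0 or f(hi) < 0:
        raise PrevalenceError(
            f"target prevalence {prevalence} unattainable for this linear predictor"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def simulate_outcome(
    exposure: np.ndarray,
    dosages: np.ndarray,
    specs: list[VariantSpec] | tuple[VariantSpec, ...],
    covariates: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    confounder: np.ndarray | None = None,
) -> np.ndarray:
    """Outcome from the forward structural model.

    Linear predictor: ``causal_beta * x + sum_j delta_j g_ij + c_U U +
    covariates``.  Gaussian outcomes add N(0, outcome_noise_sd); binary
    outcomes are Bernoulli(expit(intercept + eta)) with the intercept solved
    so the expected prevalence matches the target.
    """
    specs = tuple(specs)
    G = np.asarray(dosages, dtype=float)
    rng = rng if rng is not None else stream(config.seed, "outcome")
    if confounder is None:
        confounder = np.zeros(G.shape[0])
    delta = np.array([s.delta for s in specs])
    eta = (
        config.causal_beta * np.asarray(exposure, dtype=float)
        + G @ delta
        + config.confounder_outcome * confounder
        + _covariate_term(covariates, config.outcome_covariate_effects)
    )
    if config.outcome_family == "binary":
        intercept = _solve_intercept(eta, config.prevalence)
        return (rng.random(G.shape[0]) < expit(intercept + eta)).astype(float)
    return eta + config.outcome_noise_sd * rng.standard_normal(G.shape[0])


def simulate_reverse(
    dosages: np.ndarray,
    specs: list[VariantSpec] | tuple[VariantSpec, ...],
    covariates: pd.DataFrame,
    config: ScenarioConfig,
    seed: int | None = None,
    confounder: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Outcome-first generation: the risk factor is genetic, the exposure receives it.

    The variant ``gamma`` coefficients act on the *risk factor* trait; the
    exposure is ``reverse_beta * trait + covariates + c_U U + noise`` with the
    same noise calibration as the forward generator (but no genetic term of its
    own).  Returns ``(exposure, outcome)`` in forward-role order.
    """
    specs = tuple(specs)
    G = np.asarray(dosages, dtype=float)
    seed = config.seed if seed is None else seed
    rng_out = stream(seed, "reverse-outcome")
    rng_exp = stream(seed, "reverse-exposure")
    if confounder is None:
        confounder = np.zeros(G.shape[0])
    gamma = np.array([s.gamma for s in specs])
    eta = (
        G @ gamma
        + config.confounder_outcome * confounder
        + _covariate_term(covariates, config.outcome_covariate_effects)
    )
    if config.outcome_family == "binary":
        intercept = _solve_intercept(eta, config.prevalence)
        outcome = (rng_out.random(G.shape[0]) < expit(intercept + eta)).astype(float)
    else:
        outcome = eta + config.outcome_noise_sd * rng_out.standard_normal(G.shape[0])
    sd = exposure_noise_sd(config)
    exposure = (
        config.reverse_beta * outcome
        + _covariate_term(covariates, config.exposure_covariate_effects)
        + config.confounder_exposure * confounder
        + sd * rng_exp.standard_normal(G.shape[0])
    )
    return exposure, outcome


def default_variants(
    n_variants: int = 50,
    seed: int = 0,
    heritability: float = 0.15,
    delta_fraction: float = 0.0,
    delta_value: float = 0.0,
) -> tuple[VariantSpec, ...]:
    """A panel of independent exposure variants.

    MAFs are U(0.05, 0.5); per-allele effects are drawn N(0, 1) and rescaled so
    the panel's additive variance equals ``heritability`` (the exposure's
    covariate-free variance is normalized to 1 by the noise calibration).
    Positions are spaced 2 Mb apart, i.e. outside the 1 Mb pruning window, so
    the panel is independent for lead selection too.  The first
    ``delta_fraction`` of variants receive a direct outcome effect of
    magnitude ``delta_value`` oriented with the exposure-increasing allele
    (``sign(gamma)``): directional horizontal pleiotropy is defined relative
    to the allele that raises the exposure, so a fixed sign per effect allele
    would wash out once instruments are oriented.
    """
    rng = stream(seed, "specs")
    mafs = rng.uniform(0.05, 0.5, n_variants)
    gammas = rng.standard_normal(n_variants)
    var_g = np.sum(2.0 * mafs * (1.0 - mafs) * gammas**2)
    gammas *= np.sqrt(heritability / var_g)
    alleles = np.array(list("ACGT"))
    n_pleio = int(round(delta_fraction * n_variants))
    specs = []
    for j in range(n_variants):
        ea, oa = rng.choice(4, size=2, replace=False)
        specs.append(
            VariantSpec(
                id=f"snp{j + 1:04d}",
                chrom="1",
                pos=1_000_000 + j * 2_000_000,
                effect_allele=str(alleles[ea]),
                other_allele=str(alleles[oa]),
                maf=float(mafs[j]),
                gamma=float(gammas[j]),
                delta=float(np.sign(gammas[j]) * delta_value) if j < n_pleio else 0.0,
            )
        )
    return tuple(specs)


def scenario(
    name: str,
    n: int = 20_000,
    seed: int = 0,
    n_variants: int | None = None,
    heritability: float | None = None,
    **overrides,
) -> ScenarioConfig:
    """Named preset configurations.

    ``null``            no causal effect, no confounding, no pleiotropy.
    ``forward-causal``  exposure -> outcome beta 0.5, confounder loadings 0.2/0.2.
    ``reverse-causal``  binary risk factor -> exposure, reverse beta 0.07.
    ``pleiotropic``     forward beta 0.5 plus common-sign direct effects on 30%
                        of the panel (exclusion-restriction violation).
    ``confounded``      no causal effect, strong confounder (0.5/0.5): the
                        observational estimate is biased, a valid MR is not.

    Panel defaults: 50 variants explaining 15% of the covariate-free exposure
    variance, except the reverse preset, whose instrumented trait is a binary
    risk factor: there the panel is 16 variants with a latent (log-odds)
    genetic variance of 0.5, i.e. per-allele odds ratios around 1.3 --
    the scale at which lead variants of a common metabolic disease actually
    reach genome-wide significance at these sample sizes.
    """
    if n_variants is None:
        n_variants = 16 if name == "reverse-causal" else 50
    if heritability is None:
        heritability = 0.5 if name == "reverse-causal" else 0.15
    presets: dict[str, dict] = {
        "null": dict(causal_beta=0.0),
        "forward-causal": dict(causal_beta=0.5, confounder_exposure=0.2, confounder_outcome=0.2),
        "reverse-causal": dict(
            reverse_beta=0.07,
            outcome_family="binary",
            prevalence=0.08,
            confounder_exposure=0.2,
            confounder_outcome=0.2,
        ),
        "pleiotropic": dict(causal_beta=0.5, confounder_exposure=0.2, confounder_outcome=0.2),
        "confounded": dict(causal_beta=0.0, confounder_exposure=0.5, confounder_outcome=0.5),
    }
    if name not in presets:
        raise SimulationError(f"unknown scenario {name!r}; choose from {sorted(presets)}")
    delta_fraction = 0.3 if name == "pleiotropic" else 0.0
    delta_value = 0.1 if name == "pleiotropic" else 0.0
    variants = overrides.pop("variants", None)
    if variants is None:
        variants = default_variants(
            n_variants=n_variants,
            seed=seed,
            heritability=heritability,
            delta_fraction=delta_fraction,
            delta_value=delta_value,
        )
    params = dict(presets[name])
    params.update(overrides)
    return ScenarioConfig(
        n=n, variants=tuple(variants), seed=seed, heritability=heritability, name=name, **params
    )


SCENARIOS = ("null", "forward-causal", "reverse-causal", "pleiotropic", "confounded")


def simulate_cohort(config: ScenarioConfig) -> Cohort:
    """Generate a full cohort from a configuration (forward or reverse order)."""
    rng_u = stream(config.seed, "confounder")
    covariates = simulate_covariates(config.n, stream(config.seed, "covariates"), config.smoking_rate)
    U = rng_u.standard_normal(config.n)
    G = simulate_genotypes(config.variants, config.n, stream(config.seed, "genotypes"), config.block_rho)
    if config.reverse_beta != 0.0:
        x, y = simulate_reverse(G, config.variants, covariates, config, confounder=U)
        share = float("nan")
    else:
        sim_x = simulate_exposure(
            G, config.variants, covariates, config, stream(config.seed, "exposure"), U
        )
        x = sim_x.values
        share = sim_x.genetic_variance_share
        y = simulate_outcome(
            x, G, config.variants, covariates, config, stream(config.seed, "outcome"), U
        )
    phenotypes = covariates.copy()
    phenotypes.insert(0, "participant_id", [f"P{i + 1:06d}" for i in range(config.n)])
    phenotypes["exposure"] = x
    phenotypes["outcome"] = y
    phenotypes.attrs["genetic_variance_share"] = share
    return Cohort(dosages=G, variants=config.variants, phenotypes=phenotypes, confounder=U, config=config)
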