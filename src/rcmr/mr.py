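"""Bidirectional one-sample Mendelian randomization by two-stage least squares.

One direction of the analysis produces four regressions sharing the covariate
adjustment set (age, sex, BMI, smoking by default):

* observational: outcome ~ exposure + covariates (logistic for binary
  outcomes) -- the confounded benchmark;
* first stage:   exposure ~ WGRS + covariates (always linear);
* reduced form:  outcome ~ WGRS + covariates (family of the outcome), in
  three adjustment tiers: the base set (p_a), base + further confounders such
  as LDL-C (p_b), and base + the exposure itself (p_c);
* instrumental:  the Wald-scaled estimate, reduced-form / first-stage, with
  first-order SE ``se_gy / |beta_gx|``.

With a single composite instrument and a linear outcome the Wald ratio equals
2SLS exactly; for binary outcomes the second stage substitutes the fitted
exposure into a logistic model.  The causal verdict applies the
Bonferroni-corrected rule (alpha = 0.002 = 0.05 / 11 traits / 2 directions):
causal iff the fully adjusted score-outcome association survives (p_b <
alpha) while adding the exposure removes it (p_c >= alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._regression import add_intercept, logit, ols
from .exceptions import EmptyInstrumentSetError, RcmrError, WeakInstrumentError
from . import gwas as gwas_mod
from . import instruments as instr_mod
from .sensitivity import SensitivityReport, make_ratios, sensitivity_report

__all__ = [
    "BONFERRONI_ALPHA",
    "Effect",
    "TwoStageResult",
    "MRConfig",
    "observational_fit",
    "first_stage",
    "reduced_form",
    "scale_to_iv",
    "two_stage",
    "causal_verdict",
    "or_per_unit",
    "run_direction",
    "run_bidirectional",
]

#: Bonferroni-corrected significance level: 0.05 / 11 outcomes / 2 directions.
BONFERRONI_ALPHA = 0.002

DEFAULT_COVARIATES = ("age", "sex", "bmi", "smoking")


@dataclass
class Effect:
    beta: float
    se: float
    p: float

    def __iter__(self):
        yield from (self.beta, self.se, self.p)


@dataclass
class TwoStageResult:
    """One MR direction: the Table-row bundle of estimates and the verdict."""

    direction: str
    exposure: str
    outcome: str
    n: int
    observational: Effect | None = None  # T_A - T_B
    first_stage: Effect | None = None  # G_A - T_A
    reduced_form: Effect | None = None  # G_A - T_B (tier a)
    iv: Effect | None = None  # IV_A - T_B
    second_stage: Effect | None = None  # fitted-exposure coefficient
    p_b: float | None = None
    p_c: float | None = None
    stage_one_f: float | None = None
    weak: bool = False
    n_instruments: int = 0
    verdict: str | None = None
    skip_reason: str | None = None
    sensitivity: SensitivityReport | None = None
    instrument_log: pd.DataFrame | None = None


def _fit_with_covariates(
    y: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | None,
    family: str,
    extra: np.ndarray | None = None,
) -> Effect:
    cols = [predictor]
    if extra is not None:
        cols.append(extra if extra.ndim == 2 else extra[:, None])
    base = add_intercept(covariates, n=len(y)) if covariates is None else add_intercept(covariates)
    X = np.column_stack([base, *cols])
    fit = logit(X, y) if family == "logistic" else ols(X, y)
    j = base.shape[1]  # first appended column = the predictor of interest
    return Effect(*fit.coef(j))


def _as_array(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(float)
    return np.asarray(covariates, dtype=float)


def observational_fit(exposure, outcome, covariates=None, family: str = "linear") -> Effect:
    """Direct (non-genetic) regression of the outcome on the exposure."""
    return _fit_with_covariates(
        np.asarray(outcome, float), np.asarray(exposure, float), _as_array(covariates), family
    )


def first_stage(exposure, score, covariates=None) -> tuple[Effect, np.ndarray]:
    """Linear regression of the exposure on the WGRS; returns fitted values too."""
    s = np.asarray(score, dtype=float)
    if np.all(s == s[0]):
        raise RcmrError("constant score cannot be an instrument")
    C = _as_array(covariates)
    base = add_intercept(C, n=len(s)) if C is None else add_intercept(C)
    X = np.column_stack([base, s])
    fit = ols(X, np.asarray(exposure, dtype=float))
    eff = Effect(*fit.coef(X.shape[1] - 1))
    return eff, fit.fitted


def reduced_form(
    outcome,
    score,
    covariates=None,
    family: str = "linear",
    extra_adjustments: np.ndarray | None = None,
) -> Effect:
    """Regression of the outcome on the WGRS under an adjustment tier.

    ``extra_adjustments`` selects the tier: none -> p_a; further confounder
    columns (e.g. LDL-C and nonlipid variables) -> p_b; the exposure vector
    itself -> p_c.
    """
    extra = None
    if extra_adjustments is not None:
        extra = np.asarray(extra_adjustments, dtype=float)
        if extra.ndim == 1:
            extra = extra[:, None]
    C = _as_array(covariates)
    base = add_intercept(C, n=len(np.asarray(score))) if C is None else add_intercept(C)
    X = np.column_stack([base, np.asarray(score, float)])
    if extra is not None:
        X = np.column_stack([X, extra])
    y = np.asarray(outcome, dtype=float)
    fit = logit(X, y) if family == "logistic" else ols(X, y)
    return Effect(*fit.coef(base.shape[1]))


def scale_to_iv(beta_gy: float, se_gy: float, beta_gx: float, tol: float = 1e-12) -> tuple[float, float]:
    """Wald scaling of the reduced form by the first stage.

    beta_iv = beta_gy / beta_gx and se_iv = se_gy / |beta_gx| (first-order
    delta method, ignoring first-stage noise).  A first-stage coefficient at
    or below ``tol`` in magnitude means the instrument is irrelevant and the
    ratio undefined.
    """
    if abs(beta_gx) <= tol:
        raise WeakInstrumentError(f"first-stage coefficient {beta_gx} too close to zero")
    return float(beta_gy / beta_gx), float(se_gy / abs(beta_gx))


def two_stage(
    outcome,
    exposure,
    score,
    covariates=None,
    family: str = "linear",
) -> TwoStageResult:
    """2SLS with the WGRS as the single instrument.

    Linear outcomes: the second stage regresses the outcome on the
    stage-one fitted exposure plus covariates, and the coefficient equals the
    Wald ratio reduced/first exactly (one instrument).  Binary outcomes use
    predictor substitution: the fitted exposure enters a logistic model.  The
    reported ``iv`` effect is the Wald-scaled one in both cases; a stage-one
    partial F <= 10 sets the ``weak`` flag rather than raising.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    s = np.asarray(score, dtype=float)
    C = _as_array(covariates)
    fs, fitted = first_stage(x, s, C)
    rf = reduced_form(y, s, C, family=family)
    beta_iv, se_iv = scale_to_iv(rf.beta, rf.se, fs.beta)
    iv = Effect(beta_iv, se_iv, rf.p)  # the Wald t ratio is the reduced-form t
    second = _fit_with_covariates(y, fitted, C, family)
    obs = observational_fit(x, y, C, family=family)
    f_stat, weak = instr_mod.stage_one_strength(s, x, C)
    return TwoStageResult(
        direction="forward",
        exposure="exposure",
        outcome="outcome",
        n=len(y),
        observational=obs,
        first_stage=fs,
        reduced_form=rf,
        iv=iv,
        second_stage=second,
        stage_one_f=f_stat,
        weak=weak,
    )


def causal_verdict(
    result: TwoStageResult,
    alpha: float = BONFERRONI_ALPHA,
    comparison: str = "strict",
) -> str:
    """Bonferroni causal verdict from the adjustment tiers.

    not_causal iff the base reduced-form association is absent (p_a >= alpha);
    causal iff the fully adjusted association survives (p_b < alpha) while
    conditioning on the exposure removes it (p_c >= alpha); indeterminate
    otherwise (including exact boundary ties and missing tiers).
    ``comparison="rounded"`` compares p_b after rounding to 3 decimals, for
    reports printed at that precision.
    """
    if result.reduced_form is None:
        result.verdict = "indeterminate"
        return result.verdict
    if result.p_b is None or result.p_c is None:
        result.verdict = "indeterminate" if result.reduced_form.p < alpha else "not_causal"
        return result.verdict
    p_b = round(result.p_b, 3) if comparison == "rounded" else result.p_b
    if result.reduced_form.p >= alpha:
        result.verdict = "not_causal"
    elif p_b < alpha and result.p_c >= alpha:
        result.verdict = "causal"
    else:
        result.verdict = "indeterminate"
    return result.verdict


def or_per_unit(beta_iv: float, se_iv: float, scale_factor: float = 1.0) -> tuple[float, tuple[float, float]]:
    """Odds ratio per reporting unit of the exposure, with a 95% CI.

    ``scale_factor`` converts the model (log-exposure) scale to the reporting
    scale -- for example, the derivative of the exposure transform at the
    cohort mean for a "per 1 mmol/L" report.  It is an explicit input, never
    inferred.
    """
    b = beta_iv * scale_factor
    half = 1.96 * se_iv * abs(scale_factor)
    return float(np.exp(b)), (float(np.exp(b - half)), float(np.exp(b + half)))


@dataclass
class MRConfig:
    """Run configuration for a bidirectional analysis on a cohort."""

    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    gw_threshold: float = gwas_mod.GENOME_WIDE_P
    window_bp: int = 1_000_000
    r2_threshold: float = 0.2
    hwe_min: float = 1e-6
    exclusion_p: float = instr_mod.CROSS_ADJUSTED_P
    alpha: float = BONFERRONI_ALPHA
    comparison: str = "strict"
    tier_b_columns: tuple[str, ...] = ()  # further confounders for the p_b tier
    exposure_col: str = "exposure"
    outcome_col: str = "outcome"


def _family_of(values: np.ndarray) -> str:
    u = np.unique(values[np.isfinite(values)])
    return "logistic" if u.size <= 2 and np.isin(u, (0.0, 1.0)).all() else "linear"


def run_direction(
    cohort,
    direction: str,
    config: MRConfig | None = None,
) -> TwoStageResult:
    """One direction of the MR on a simulated or loaded cohort.

    Pipeline: GWAS scan of the direction's exposure -> genome-wide
    significance -> LD/HWE lead selection -> cross-adjusted pleiotropy
    exclusion -> WGRS -> two-stage fit, adjustment tiers and verdict, plus the
    per-variant sensitivity report.  A direction with no usable instruments
    returns a skipped result carrying the reason instead of raising.
    """
    config = config or MRConfig()
    pheno = cohort.phenotypes
    cols = [config.exposure_col, config.outcome_col, *config.covariates]
    keep = pheno[cols].notna().all(axis=1).to_numpy()
    pheno = pheno.loc[keep]
    G = cohort.dosages[keep]
    C = pheno[list(config.covariates)]
    x_fwd = pheno[config.exposure_col].to_numpy(float)
    y_fwd = pheno[config.outcome_col].to_numpy(float)
    if direction == "forward":
        exp_vals, out_vals = x_fwd, y_fwd
        exp_name, out_name = config.exposure_col, config.outcome_col
    elif direction == "reverse":
        exp_vals, out_vals = y_fwd, x_fwd
        exp_name, out_name = config.outcome_col, config.exposure_col
    else:
        raise RcmrError(f"unknown direction {direction!r}")
    exp_family = _family_of(exp_vals)
    out_family = _family_of(out_vals)

    stats_exp = gwas_mod.scan(
        G, exp_vals, C, specs=cohort.variants, family=exp_family, trait=exp_name
    )
    significant = stats_exp[stats_exp["p"] < config.gw_threshold]
    result = TwoStageResult(
        direction=direction, exposure=exp_name, outcome=out_name, n=len(pheno)
    )
    if significant.empty:
        result.skip_reason = "no genome-wide-significant variants for the exposure"
        result.verdict = "indeterminate"
        return result
    leads = gwas_mod.select_leads(
        significant,
        G,
        cohort.variant_ids,
        window_bp=config.window_bp,
        r2_threshold=config.r2_threshold,
        hwe_min=config.hwe_min,
    )
    if leads.retained.empty:
        result.skip_reason = "no lead variants survived LD/HWE pruning"
        result.verdict = "indeterminate"
        return result
    try:
        iset = instr_mod.build_instrument_set(
            G,
            cohort.variant_ids,
            leads.retained,
            exp_vals,
            out_vals,
            C,
            direction=direction,
            exposure_name=exp_name,
            outcome_name=out_name,
            p_threshold=config.exclusion_p,
            outcome_family=out_family,
        )
    except EmptyInstrumentSetError as exc:
        result.skip_reason = str(exc)
        result.verdict = "indeterminate"
        return result

    ts = two_stage(out_vals, exp_vals, iset.score, C, family=out_family)
    ts.direction = direction
    ts.exposure = exp_name
    ts.outcome = out_name
    ts.n_instruments = iset.n_instruments
    ts.instrument_log = iset.weights

    extra_b = pheno[list(config.tier_b_columns)].to_numpy(float) if config.tier_b_columns else None
    eff_b = reduced_form(out_vals, iset.score, C, family=out_family, extra_adjustments=extra_b)
    ts.p_b = eff_b.p
    extra_c = exp_vals if extra_b is None else np.column_stack([extra_b, exp_vals])
    eff_c = reduced_form(out_vals, iset.score, C, family=out_family, extra_adjustments=extra_c)
    ts.p_c = eff_c.p
    causal_verdict(ts, alpha=config.alpha, comparison=config.comparison)

    # per-variant summary statistics for the sensitivity suite
    retained_ids = iset.variant_ids
    idx = [cohort.variant_ids.index(v) for v in retained_ids]
    sub_specs = [cohort.variants[j] for j in idx]
    exp_stats = stats_exp.set_index("variant_id").loc[retained_ids].reset_index()
    out_stats = gwas_mod.scan(
        G[:, idx], out_vals, C, specs=sub_specs, family=out_family, trait=out_name, hwe=False
    )
    if len(retained_ids) >= 3:
        ratios = make_ratios(exp_stats, out_stats)
        ts.sensitivity = sensitivity_report(ratios)
    return ts


def run_bidirectional(cohort, config: MRConfig | None = None) -> dict[str, TwoStageResult]:
    """Forward and reverse MR on the same cohort, sharing the report schema."""
    return {
        "forward": run_direction(cohort, "forward", config),
        "reverse": run_direction(cohort, "reverse", config),
    }


def result_table(results: dict[str, TwoStageResult]) -> pd.DataFrame:
    """Flatten direction results into a summary-table layout (one row each)."""
    rows = []
    for direction, r in results.items():
        row: dict = dict(
            direction=direction,
            exposure=r.exposure,
            outcome=r.outcome,
            n=r.n,
            n_instruments=r.n_instruments,
            stage_one_f=r.stage_one_f,
            verdict=r.verdict,
            skip_reason=r.skip_reason,
        )
        for label, eff in (
            ("obs", r.observational),
            ("first", r.first_stage),
            ("reduced", r.reduced_form),
            ("iv", r.iv),
        ):
            if eff is not None:
                row[f"{label}_beta"], row[f"{label}_se"], row[f"{label}_p"] = tuple(eff)
        row["p_b"] = r.p_b
        row["p_c"] = r.p_c
        rows.append(row)
    return pd.DataFrame(rows)
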