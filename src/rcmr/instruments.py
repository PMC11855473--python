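"""Weighted genetic risk scores (WGRS) as composite instrumental variables.

A WGRS is the per-participant sum of effect-allele dosages weighted by the
per-allele effect sizes from the exposure GWAS of the same cohort (one-sample
design).  Before scoring, lead variants that are associated with the *other*
trait of the MR direction after cross-adjustment (p < 0.01) are excluded --
the pipeline's guard against horizontal pleiotropy.  Weights keep their GWAS
sign rather than flipping alleles to make all weights positive: the sums are
algebraically identical and the orientation stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._regression import add_intercept, logit, ols, variant_scan
from .exceptions import EmptyInstrumentSetError, RcmrError

__all__ = [
    "InstrumentSet",
    "compute_wgrs",
    "exclude_pleiotropic",
    "stage_one_strength",
    "build_instrument_set",
]

CROSS_ADJUSTED_P = 0.01


@dataclass
class InstrumentSet:
    """Retained variants, their weights, the exclusion log, and the score."""

    direction: str  # 'forward' | 'reverse'
    exposure: str
    outcome: str
    weights: pd.DataFrame  # variant_id, effect_allele, weight, cross_adjusted_p, retained
    score: np.ndarray  # per-participant WGRS (G_A)
    stage_one_f: float
    weak: bool

    @property
    def variant_ids(self) -> list[str]:
        return list(self.weights.loc[self.weights["retained"], "variant_id"])

    @property
    def n_instruments(self) -> int:
        return int(self.weights["retained"].sum())


def compute_wgrs(
    G: np.ndarray,
    weights: np.ndarray | pd.Series,
    variant_ids: list[str] | None = None,
    weight_ids: list[str] | None = None,
    missing: str = "listwise",
) -> np.ndarray:
    """score_i = sum_j w_j * g_ij over the weighted variants.

    When ``weight_ids`` is given, each weight is matched to its dosage column
    by variant id; a weight whose variant is absent from the matrix is an
    error naming the variant.  Missing dosages either drop the participant
    from the score (NaN, list-wise, the default) or are mean-imputed per
    variant (``missing="mean"``) for sensitivity checks.
    """
    Gf = np.asarray(G, dtype=float)
    w = np.asarray(weights, dtype=float)
    if weight_ids is not None:
        if variant_ids is None:
            raise RcmrError("variant_ids required to match weight_ids")
        col = {vid: j for j, vid in enumerate(variant_ids)}
        absent = [vid for vid in weight_ids if vid not in col]
        if absent:
            raise RcmrError(f"weighted variants absent from dosage matrix: {absent}")
        Gf = Gf[:, [col[vid] for vid in weight_ids]]
    if Gf.shape[1] != w.size:
        raise RcmrError(f"{Gf.shape[1]} dosage columns vs {w.size} weights")
    if missing == "mean":
        col_mean = np.nanmean(Gf, axis=0)
        Gf = np.where(np.isnan(Gf), col_mean, Gf)
        return Gf @ w
    score = Gf @ w  # NaN dosages propagate -> participant excluded list-wise
    return score


def _cross_adjusted_p(
    G: np.ndarray,
    response: np.ndarray,
    covariates: np.ndarray,
    conditioning_trait: np.ndarray,
    family: str,
) -> np.ndarray:
    """p(variant -> response | covariates + conditioning trait), per variant."""
    C = add_intercept(np.column_stack([covariates, conditioning_trait]))
    if family == "linear":
        _, _, p = variant_scan(np.asarray(G, float), np.asarray(response, float), C)
        return p
    m = G.shape[1]
    p = np.empty(m)
    for j in range(m):
        X = np.column_stack([C, np.asarray(G[:, j], float)])
        fit = logit(X, np.asarray(response, float))
        p[j] = fit.p[-1]
    return p


def exclude_pleiotropic(
    G: np.ndarray,
    exposure: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | pd.DataFrame,
    direction: str = "forward",
    p_threshold: float = CROSS_ADJUSTED_P,
    outcome_family: str = "linear",
    variant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Apply the cross-adjusted exclusion rule to candidate instruments.

    forward: drop variant j iff p(variant -> outcome | covariates + exposure)
    < ``p_threshold``; reverse: drop iff p(variant -> exposure | covariates +
    outcome) < ``p_threshold``.  Returns a per-variant log with columns
    (variant_id, cross_adjusted_p, retained); raising if nothing survives is
    the caller's choice (see :func:`build_instrument_set`).
    """
    C = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
    if direction == "forward":
        p = _cross_adjusted_p(G, outcome, C, exposure, outcome_family)
    elif direction == "reverse":
        p = _cross_adjusted_p(G, exposure, C, outcome, "linear")
    else:
        raise RcmrError(f"unknown direction {direction!r}")
    ids = variant_ids if variant_ids is not None else [f"v{j}" for j in range(G.shape[1])]
    return pd.DataFrame(
        {"variant_id": ids, "cross_adjusted_p": p, "retained": p >= p_threshold}
    )


def stage_one_strength(
    score: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, bool]:
    """Partial F of the WGRS in the first-stage regression, and the weak flag.

    Regresses exposure on score + covariates; the partial F for one regressor
    is the squared t ratio.  A perfect fit reports +inf; F <= 10 flags a weak
    instrument.  Constant scores are rejected.
    """
    s = np.asarray(score, dtype=float)
    if np.all(s == s[0]):
        raise RcmrError("constant score cannot be an instrument")
    C = None
    if covariates is not None:
        C = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
    X = add_intercept(C, n=len(s)) if C is None else add_intercept(C)
    X = np.column_stack([X, s])
    x = np.asarray(exposure, dtype=float)
    fit = ols(X, x)
    beta, se, _ = fit.coef(X.shape[1] - 1)
    # a perfect (to rounding) fit reports the +inf sentinel
    if se == 0.0 or fit.sigma2 <= 1e-12 * max(float(np.var(x)), 1e-300):
        return float("inf"), False
    f = (beta / se) ** 2
    return float(f), bool(f <= 10.0)


def build_instrument_set(
    G: np.ndarray,
    variant_ids: list[str],
    lead_weights: pd.DataFrame,
    exposure: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | pd.DataFrame,
    direction: str = "forward",
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    p_threshold: float = CROSS_ADJUSTED_P,
    outcome_family: str = "linear",
) -> InstrumentSet:
    """Assemble the WGRS instrument for one MR direction.

    ``lead_weights`` carries the exposure-GWAS lead variants (columns
    variant_id, effect_allele, beta); the cross-adjusted exclusion rule is
    applied, the surviving weights are summed into the score, and the
    stage-one partial F is attached.  An empty retained set raises
    :class:`~rcmr.exceptions.EmptyInstrumentSetError`, mirroring MR directions
    that cannot be constructed at all.
    """
    col = {vid: j for j, vid in enumerate(variant_ids)}
    missing = [v for v in lead_weights["variant_id"] if v not in col]
    if missing:
        raise RcmrError(f"lead variants absent from dosage matrix: {missing}")
    cols = [col[v] for v in lead_weights["variant_id"]]
    G_lead = np.asarray(G, dtype=float)[:, cols]
    # ``exposure``/``outcome`` here are the *direction's* roles (the exposure is
    # the instrumented trait).  exclude_pleiotropic speaks in forward-role
    # names, where the rule for the reverse direction tests
    # variant -> forward-exposure | forward-outcome; under direction roles both
    # directions reduce to variant -> direction-outcome | direction-exposure.
    if direction == "forward":
        log = exclude_pleiotropic(
            G_lead,
            exposure,
            outcome,
            covariates,
            direction="forward",
            p_threshold=p_threshold,
            outcome_family=outcome_family,
            variant_ids=list(lead_weights["variant_id"]),
        )
    else:
        log = exclude_pleiotropic(
            G_lead,
            outcome,  # forward-role exposure (e.g. RC) = this direction's outcome
            exposure,  # forward-role outcome (risk factor) = this direction's exposure
            covariates,
            direction="reverse",
            p_threshold=p_threshold,
            variant_ids=list(lead_weights["variant_id"]),
        )
    weights = lead_weights[["variant_id", "effect_allele", "beta"]].rename(columns={"beta": "weight"})
    weights = weights.merge(log, on="variant_id")
    kept = weights["retained"].to_numpy()
    if not kept.any():
        raise EmptyInstrumentSetError(
            f"all candidate instruments excluded by the cross-adjusted p<{p_threshold} rule "
            f"({direction} direction, {exposure_name} -> {outcome_name})"
        )
    score = compute_wgrs(G_lead[:, kept], weights.loc[kept, "weight"].to_numpy())
    f_stat, weak = stage_one_strength(score, exposure, covariates)
    return InstrumentSet(
        direction=direction,
        exposure=exposure_name,
        outcome=outcome_name,
        weights=weights,
        score=score,
        stage_one_f=f_stat,
        weak=weak,
    )
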