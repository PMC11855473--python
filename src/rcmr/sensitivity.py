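"""Summary-statistics sensitivity estimators for multi-variant MR.

Given per-variant effects on the exposure (beta_x, se_x) and the outcome
(beta_y, se_y), each variant yields a Wald ratio beta_y/beta_x with
first-order SE se_y/|beta_x|.  Over the panel:

* IVW: inverse-variance-weighted mean of the ratios; the random-effects
  variant scales the SE by sqrt(phi) with multiplicative overdispersion
  phi = max(1, Q/(J-1));
* MR-Egger: WLS of beta_y on beta_x with weights 1/se_y^2 and a free
  intercept; a nonzero intercept indicates directional horizontal pleiotropy,
  and with the ratio weighting above the zero-intercept slope is exactly the
  fixed-effect IVW estimate;
* simple/weighted median: the interpolated crossing of the cumulative
  (standardized) weights at 0.5, SE by seeded parametric bootstrap --
  consistent while valid instruments carry at least half the weight;
* Cochran's Q around the IVW fit (J-1 df) and Ruecker's Q' around the Egger
  fit (J-2 df); Q >= Q' always, and the gap is the intercept's contribution.

Orientation convention: before any fit, variants are recoded so beta_x > 0 by
flipping (beta_x, beta_y) jointly; all estimators are invariant to the flip
and to variant order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import RcmrError

__all__ = [
    "RatioEstimate",
    "Estimate",
    "EggerFit",
    "HeterogeneityResult",
    "SensitivityReport",
    "make_ratios",
    "orient_positive",
    "ivw",
    "mr_egger",
    "median_estimators",
    "heterogeneity",
    "funnel_and_scatter",
    "sensitivity_report",
]


@dataclass
class RatioEstimate:
    """Per-variant Wald ratio with first-order precision weight."""

    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.beta_x == 0:
            raise RcmrError(f"{self.variant_id}: zero exposure effect, ratio undefined")
        if self.se_y <= 0:
            raise RcmrError(f"{self.variant_id}: se_y must be positive")

    @property
    def ratio(self) -> float:
        return self.beta_y / self.beta_x

    @property
    def ratio_se(self) -> float:
        return self.se_y / abs(self.beta_x)

    @property
    def weight(self) -> float:
        return 1.0 / self.ratio_se**2


@dataclass
class Estimate:
    beta: float
    se: float
    p: float
    model: str = "fixed"
    dispersion: float = 1.0


@dataclass
class EggerFit:
    intercept: float
    intercept_se: float
    intercept_p: float
    slope: float
    slope_se: float
    slope_p: float
    dispersion: float = 1.0


@dataclass
class HeterogeneityResult:
    q: float
    q_df: int
    q_p: float
    q_prime: float | None = None
    q_prime_df: int | None = None
    q_prime_p: float | None = None


@dataclass
class SensitivityReport:
    ivw_fixed: Estimate
    ivw_random: Estimate
    egger: EggerFit | None
    simple_median: Estimate | None
    weighted_median: Estimate | None
    heterogeneity: HeterogeneityResult
    funnel: pd.DataFrame
    scatter: pd.DataFrame


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _harmonized(exp_row, out_row) -> int | None:
    """+1 same orientation, -1 swapped alleles, None unharmonizable."""
    ea, oa = exp_row["effect_allele"], out_row["effect_allele"]
    eo, oo = exp_row["other_allele"], out_row["other_allele"]
    if (ea, eo) == (oa, oo):
        return 1
    if (ea, eo) == (oo, oa):
        return -1
    return None


def make_ratios(
    exposure_assocs: pd.DataFrame,
    outcome_assocs: pd.DataFrame,
    orient: bool = True,
) -> list[RatioEstimate]:
    """Pair exposure and outcome summary statistics into per-variant ratios.

    Variants are matched on id; outcome effects measured on the swapped allele
    are sign-flipped, and variants whose allele pairs cannot be reconciled are
    dropped (logged on the returned list's ``attrs`` is overkill -- callers
    get fewer ratios and can diff).  With ``orient=True`` the exposure effect
    is then recoded positive by flipping (beta_x, beta_y) jointly, which
    leaves every ratio unchanged.
    """
    out_by_id = outcome_assocs.set_index("variant_id")
    ratios: list[RatioEstimate] = []
    for _, erow in exposure_assocs.iterrows():
        vid = erow["variant_id"]
        if vid not in out_by_id.index:
            continue
        orow = out_by_id.loc[vid]
        sign = 1
        if "effect_allele" in erow and "effect_allele" in orow:
            h = _harmonized(erow, orow)
            if h is None:
                continue  # unharmonizable allele pair: dropped
            sign = h
        bx, by = float(erow["beta"]), sign * float(orow["beta"])
        sx, sy = float(erow["se"]), float(orow["se"])
        flipped = False
        if orient and bx < 0:
            bx, by, flipped = -bx, -by, True
        ratios.append(
            RatioEstimate(variant_id=vid, beta_x=bx, se_x=sx, beta_y=by, se_y=sy, flipped=flipped)
        )
    return ratios


def orient_positive(ratios: list[RatioEstimate]) -> list[RatioEstimate]:
    """Recode exposure effects positive (joint sign flip); ratios unchanged."""
    out = []
    for r in ratios:
        if r.beta_x < 0:
            out.append(
                RatioEstimate(r.variant_id, -r.beta_x, r.se_x, -r.beta_y, r.se_y, flipped=not r.flipped)
            )
        else:
            out.append(r)
    return out


def _arrays(ratios: list[RatioEstimate]):
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    return r, w


def ivw(ratios: list[RatioEstimate], model: str = "fixed") -> Estimate:
    """Inverse-variance-weighted pooled ratio.

    fixed: beta = sum(w r) / sum(w), se = 1/sqrt(sum w).  random: same point
    estimate with the SE scaled by sqrt(phi), phi = max(1, Q/(J-1)) the
    multiplicative overdispersion (J=1 keeps phi=1).
    """
    if not ratios:
        raise RcmrError("IVW needs at least one ratio")
    r, w = _arrays(ratios)
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    phi = 1.0
    if model == "random":
        if len(ratios) >= 2:
            q = float(np.sum(w * (r - beta) ** 2))
            phi = max(1.0, q / (len(ratios) - 1))
        se *= np.sqrt(phi)
    elif model != "fixed":
        raise RcmrError(f"unknown IVW model {model!r}")
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return Estimate(beta=beta, se=se, p=p, model=model, dispersion=phi)


def mr_egger(ratios: list[RatioEstimate]) -> EggerFit:
    """MR-Egger: WLS of beta_y on beta_x with a free intercept, weights 1/se_y^2.

    Exposure effects are oriented positive first (required for the intercept
    to be interpretable).  SEs carry the multiplicative overdispersion
    sqrt(max(1, Q'/(J-2))); intercept p tests directional pleiotropy.  J >= 3
    is required: with fewer variants the slope and intercept leave no
    meaningful residual.
    """
    if len(ratios) < 3:
        raise RcmrError("MR-Egger needs at least 3 variants")
    ratios = orient_positive(ratios)
    bx = np.array([r.beta_x for r in ratios])
    by = np.array([r.beta_y for r in ratios])
    w = np.array([1.0 / r.se_y**2 for r in ratios])
    if np.ptp(bx) == 0.0:
        raise RcmrError("MR-Egger needs variation in the exposure effects (constant beta_x)")
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    XtWy = WX.T @ by
    coef = np.linalg.solve(XtWX, XtWy)
    resid = by - X @ coef
    j = len(ratios)
    q_prime = float(np.sum(w * resid**2))
    phi = max(1.0, q_prime / (j - 2))
    cov = np.linalg.inv(XtWX) * phi
    se = np.sqrt(np.diag(cov))
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return EggerFit(
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_p=float(p[0]),
        slope=float(coef[1]),
        slope_se=float(se[1]),
        slope_p=float(p[1]),
        dispersion=float(phi),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: where cumulative standardized weights cross 0.5."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    s = np.cumsum(w) - 0.5 * w
    s = s / np.sum(w)
    if s[0] >= 0.5:
        return float(v[0])
    if s[-1] <= 0.5:
        return float(v[-1])
    k = int(np.searchsorted(s, 0.5))  # s[k-1] < 0.5 <= s[k]
    return float(v[k - 1] + (v[k] - v[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def median_estimators(
    ratios: list[RatioEstimate],
    kind: str = "weighted",
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> Estimate:
    """Simple or weighted median of the per-variant ratios.

    The weighted median interpolates the value at which the cumulative
    standardized inverse-variance weights cross one half; the simple median is
    the same procedure with equal weights.  The SE comes from a seeded
    parametric bootstrap redrawing each ratio from N(ratio_j, ratio_se_j).
    """
    if len(ratios) < 3:
        raise RcmrError("median estimators need at least 3 variants")
    if kind not in ("simple", "weighted"):
        raise RcmrError(f"unknown median kind {kind!r}")
    r, w = _arrays(ratios)
    if kind == "simple":
        w = np.ones_like(w)
    beta = _weighted_median(r, w)
    rng = np.random.default_rng(seed)
    ses = np.array([x.ratio_se for x in ratios])
    draws = rng.normal(r, ses, size=(bootstrap_reps, len(r)))
    boot = np.array([_weighted_median(d, w) for d in draws])
    se = float(np.std(boot, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else (0.0 if beta != 0 else 1.0)
    return Estimate(beta=beta, se=se, p=p, model=f"{kind}_median")


def heterogeneity(
    ratios: list[RatioEstimate],
    ivw_beta: float | None = None,
    egger_fit: EggerFit | None = None,
) -> HeterogeneityResult:
    """Cochran's Q around the IVW fit and Ruecker's Q' around the Egger fit.

    Q = sum_j w_j (ratio_j - beta_ivw)^2 ~ chi2(J-1) under homogeneity;
    Q' replaces the fit with the two-parameter Egger line and uses J-2 df.
    Both use the same weights (1/ratio_se^2, equivalently (beta_x/se_y)^2), so
    Q >= Q' holds identically.
    """
    j = len(ratios)
    if j < 2:
        raise RcmrError("Q needs at least 2 variants")
    if ivw_beta is None:
        ivw_beta = ivw(ratios).beta
    r, w = _arrays(ratios)
    q = float(np.sum(w * (r - ivw_beta) ** 2))
    q_p = float(stats.chi2.sf(q, j - 1))
    q_prime = q_prime_df = q_prime_p = None
    if j >= 3:
        if egger_fit is None:
            try:
                egger_fit = mr_egger(ratios)
            except RcmrError:
                egger_fit = None  # degenerate Egger design: report Q only
    if j >= 3 and egger_fit is not None:
        oriented = orient_positive(ratios)
        bx = np.array([x.beta_x for x in oriented])
        by = np.array([x.beta_y for x in oriented])
        wy = np.array([1.0 / x.se_y**2 for x in oriented])
        resid = by - egger_fit.intercept - egger_fit.slope * bx
        q_prime = float(np.sum(wy * resid**2))
        q_prime_df = j - 2
        q_prime_p = float(stats.chi2.sf(q_prime, q_prime_df))
    return HeterogeneityResult(
        q=q, q_df=j - 1, q_p=q_p, q_prime=q_prime, q_prime_df=q_prime_df, q_prime_p=q_prime_p
    )


def funnel_and_scatter(
    ratios: list[RatioEstimate],
    ivw_fit: Estimate | None = None,
    egger_fit: EggerFit | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables: funnel (ratio vs precision) and scatter with fitted lines.

    The scatter table carries the per-variant (beta_x, beta_y, se_x, se_y) and
    the fitted lines as ``attrs['lines']`` slope/intercept records.
    """
    funnel = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in ratios],
            "ratio": [r.ratio for r in ratios],
            "precision": [1.0 / r.ratio_se for r in ratios],
        }
    )
    oriented = orient_positive(ratios)
    scatter = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in oriented],
            "beta_x": [r.beta_x for r in oriented],
            "beta_y": [r.beta_y for r in oriented],
            "se_x": [r.se_x for r in oriented],
            "se_y": [r.se_y for r in oriented],
        }
    )
    lines = []
    if ivw_fit is not None:
        lines.append(dict(label="IVW", slope=ivw_fit.beta, intercept=0.0))
    if egger_fit is not None:
        lines.append(dict(label="MR-Egger", slope=egger_fit.slope, intercept=egger_fit.intercept))
    scatter.attrs["lines"] = lines
    return funnel, scatter


def sensitivity_report(ratios: list[RatioEstimate], seed: int = 0) -> SensitivityReport:
    """The full suite over one ratio panel (J >= 3)."""
    fixed = ivw(ratios, "fixed")
    random = ivw(ratios, "random")
    egger = mr_egger(ratios) if len(ratios) >= 3 else None
    simple = median_estimators(ratios, "simple", seed=seed) if len(ratios) >= 3 else None
    weighted = median_estimators(ratios, "weighted", seed=seed) if len(ratios) >= 3 else None
    het = heterogeneity(ratios, ivw_beta=fixed.beta, egger_fit=egger)
    funnel, scatter = funnel_and_scatter(ratios, fixed, egger)
    return SensitivityReport(
        ivw_fixed=fixed,
        ivw_random=random,
        egger=egger,
        simple_median=simple,
        weighted_median=weighted,
        heterogeneity=het,
        funnel=funnel,
        scatter=scatter,
    )
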