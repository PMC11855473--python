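"""Lipid trait derivation and observational association analyses.

Remnant cholesterol (RC) is defined arithmetically from the standard lipid
panel: RC = TC - HDL-C - LDL-C, in whatever concentration unit the panel
carries.  This module derives RC, converts between mg/dL and mmol/L, assigns
ascending quartiles, fits covariate-adjusted logistic trait associations, and
runs forward stepwise linear regression with a partial-F entry criterion --
the observational layer that motivates (but cannot establish) causality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import add_intercept, logit, ols
from .exceptions import RcmrError

__all__ = [
    "MGDL_PER_MMOL",
    "LipidPanel",
    "QuartileAssignment",
    "StepwiseRow",
    "AssociationResult",
    "derive_rc",
    "derive_rc_table",
    "convert_mgdl_mmol",
    "log_transform",
    "assign_quartiles",
    "trait_association",
    "stepwise_linear",
]

#: mg/dL per mmol/L for cholesterol (molar mass of cholesterol, 386.7 g/mol).
MGDL_PER_MMOL = 38.67


@dataclass(frozen=True)
class LipidPanel:
    """TC / HDL-C / LDL-C concentrations sharing one unit tag."""

    tc: float
    hdl: float
    ldl: float
    unit: str = "mmol/L"

    def __post_init__(self) -> None:
        if self.unit not in ("mmol/L", "mg/dL"):
            raise RcmrError(f"unknown concentration unit {self.unit!r}")

    @property
    def rc(self) -> float:
        return derive_rc(self)


def derive_rc(panel: LipidPanel) -> float:
    """RC = TC - HDL-C - LDL-C.

    Missing (NaN) components raise: the caller's record should be list-wise
    deleted rather than carry a silent NaN downstream.  Negative results are
    legal on raw input (measurement error in the Friedewald chain) and are the
    caller's to flag; see :func:`derive_rc_table`.
    """
    comps = (panel.tc, panel.hdl, panel.ldl)
    if any(c is None or not np.isfinite(c) for c in comps):
        raise RcmrError("lipid panel has a missing component; record must be excluded")
    return float(panel.tc - panel.hdl - panel.ldl)


def derive_rc_table(
    table: pd.DataFrame,
    tc: str = "tc",
    hdl: str = "hdl",
    ldl: str = "ldl",
    out: str = "rc",
) -> pd.DataFrame:
    """Vectorized RC derivation over a phenotype table.

    Rows with any missing lipid component are dropped (list-wise deletion) and
    counted in ``result.attrs['n_excluded_missing']``.  Negative derived RC
    values are retained but flagged in a boolean ``{out}_negative`` column so
    exclusion-sensitivity studies can filter on it without losing sample
    alignment for MR.
    """
    required = [tc, hdl, ldl]
    missing = table[required].isna().any(axis=1)
    result = table.loc[~missing].copy()
    result[out] = result[tc] - result[hdl] - result[ldl]
    result[f"{out}_negative"] = result[out] < 0
    result.attrs["n_excluded_missing"] = int(missing.sum())
    return result


def convert_mgdl_mmol(value, direction: str = "to_mmol"):
    """Convert cholesterol concentrations between mg/dL and mmol/L.

    ``direction`` is ``"to_mmol"`` (divide by 38.67) or ``"to_mgdl"``
    (multiply).  Round-trips are identity to floating tolerance.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise RcmrError("concentrations must be nonnegative and finite")
    if direction == "to_mmol":
        out = arr / MGDL_PER_MMOL
    elif direction == "to_mgdl":
        out = arr * MGDL_PER_MMOL
    else:
        raise RcmrError(f"unknown direction {direction!r}")
    return float(out) if np.isscalar(value) else out


def log_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Natural log of positive values; non-positive entries become NaN.

    NaNs mark records for list-wise deletion in log-scale analyses, matching
    the missing-data policy used everywhere else in the pipeline.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full_like(arr, np.nan)
    mask = arr > 0
    out[mask] = np.log(arr[mask])
    return out


@dataclass
class QuartileAssignment:
    """Ascending quartile labels Q1..Q4 with the three empirical cut points."""

    labels: np.ndarray  # strings 'Q1'..'Q4'
    cuts: tuple[float, float, float]

    @property
    def codes(self) -> np.ndarray:
        """Integer codes 1..4 matching the labels."""
        return np.char.lstrip(self.labels.astype(str), "Q").astype(int)


def assign_quartiles(values) -> QuartileAssignment:
    """Q1-Q4 in ascending order with cut points at the 25/50/75 percentiles.

    A value exactly equal to a cut point is assigned to the *lower* quartile,
    which makes the assignment deterministic and independent of input order.
    """
    full = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(full)) < 4:
        raise RcmrError("need at least 4 non-missing values for quartiles")
    finite = full[np.isfinite(full)]
    if np.all(finite == finite[0]):
        raise RcmrError("quartiles undefined for all-equal input")
    cuts = tuple(float(c) for c in np.percentile(finite, [25, 50, 75]))
    codes = np.full(full.shape, -1)
    mask = np.isfinite(full)
    # ties at a cut point fall to the lower quartile: count cuts strictly below
    codes[mask] = 1 + np.sum(full[mask, None] > np.array(cuts)[None, :], axis=1)
    labels = np.where(mask, np.char.add("Q", codes.astype(str)), "NA")
    return QuartileAssignment(labels=labels, cuts=cuts)  # type: ignore[arg-type]


@dataclass
class AssociationResult:
    """One regression coefficient with Wald inference and the OR scale."""

    term: str
    beta: float
    se: float
    p: float
    n: int
    family: str

    @property
    def odds_ratio(self) -> float:
        if self.family != "logistic":
            raise RcmrError("odds ratio defined for logistic fits only")
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        lo, hi = self.beta - 1.96 * self.se, self.beta + 1.96 * self.se
        return float(np.exp(lo)), float(np.exp(hi))


DEFAULT_COVARIATES = ("age", "sex", "bmi", "smoking")


def _design(table: pd.DataFrame, predictor: str, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [predictor, *covariates]
    X = add_intercept(table[cols].to_numpy(float))
    return X, ["intercept", *cols]


def trait_association(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=DEFAULT_COVARIATES,
    family: str = "logistic",
) -> AssociationResult:
    """Covariate-adjusted association of a binary trait with a predictor.

    Fits ``outcome ~ predictor + covariates`` by maximum-likelihood logistic
    regression (or OLS when ``family="linear"``); rows with any missing value
    are list-wise deleted.  Separation and non-convergence raise
    :class:`~rcmr.exceptions.ConvergenceError` -- never silently.
    """
    cols = [outcome, predictor, *covariates]
    data = table[cols].dropna()
    X, _ = _design(data, predictor, covariates)
    y = data[outcome].to_numpy(float)
    if family == "logistic":
        fit = logit(X, y)
    elif family == "linear":
        fit = ols(X, y)
    else:
        raise RcmrError(f"unknown family {family!r}")
    beta, se, p = fit.coef(1)
    return AssociationResult(term=predictor, beta=beta, se=se, p=p, n=len(data), family=family)


@dataclass
class StepwiseRow:
    """One retained term of a forward stepwise regression."""

    term: str
    beta: float
    se: float
    partial_r2: float  # increment in R^2 at entry
    p: float
    entry_order: int


def stepwise_linear(
    table: pd.DataFrame,
    response: str,
    candidates: list[str] | tuple[str, ...],
    entry_p: float = 0.05,
    r2_tol: float = 1e-12,
) -> list[StepwiseRow]:
    """Forward stepwise OLS with partial-F entry.

    At each step the candidate with the largest R^2 increment enters if its
    partial-F p value is below ``entry_p``; selection stops when no candidate
    qualifies.  ``partial_r2`` is the increment recorded at entry; the final
    coefficients, SEs and p values come from the full retained model.  Rows
    are returned sorted by descending partial R^2 (entry order is kept in
    ``entry_order``).  Candidates whose increment is below ``r2_tol``
    (collinear with the current model) are skipped.
    """
    data = table[[response, *candidates]].dropna()
    y = data[response].to_numpy(float)
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise RcmrError("response has zero variance")
    selected: list[str] = []
    entries: list[tuple[str, float]] = []
    remaining = list(candidates)
    current_r2 = 0.0
    while remaining:
        best = None
        dropped: list[str] = []
        for cand in remaining:
            X = add_intercept(data[[*selected, cand]].to_numpy(float))
            try:
                fit = ols(X, y)
            except np.linalg.LinAlgError:
                dropped.append(cand)  # exactly collinear with the current model
                continue
            r2 = 1.0 - float(fit.resid @ fit.resid) / tss
            inc = r2 - current_r2
            if best is None or inc > best[1]:
                best = (cand, inc, fit.df_resid, r2)
        for cand in dropped:
            remaining.remove(cand)
        if best is None:
            break
        cand, inc, df_full, r2 = best
        if inc < r2_tol:
            remaining.remove(cand)  # collinear with current model; skip and log
            continue
        # partial F for one added regressor
        f_stat = inc / ((1.0 - r2) / df_full) if r2 < 1.0 else np.inf
        p_entry = float(stats.f.sf(f_stat, 1, df_full)) if np.isfinite(f_stat) else 0.0
        if p_entry >= entry_p:
            break
        selected.append(cand)
        entries.append((cand, inc))
        remaining.remove(cand)
        current_r2 = r2
        if r2 >= 1.0 - r2_tol:
            break
    if not selected:
        return []
    X = add_intercept(data[selected].to_numpy(float))
    final = ols(X, y)
    rows = []
    for order, (term, inc) in enumerate(entries, start=1):
        j = selected.index(term) + 1  # +1 for intercept
        beta, se, p = final.coef(j)
        rows.append(
            StepwiseRow(term=term, beta=beta, se=se, partial_r2=float(inc), p=p, entry_order=order)
        )
    rows.sort(key=lambda r: -r.partial_r2)
    return rows
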