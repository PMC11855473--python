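"""Per-variant association scans, QC and lead-variant selection.

Additively coded dosages (0/1/2 of the effect allele) are regressed on a trait
with covariate adjustment, flagged for genome-wide significance (p < 5e-8,
strict), filtered on a Hardy-Weinberg exact test, and greedily pruned to an
LD-independent lead set within a 1 Mb window.  Instrument strength is the
single-regressor partial F, which for one added regressor equals the squared
Wald t ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy import stats

from ._regression import add_intercept, logit, ols, variant_scan
from .exceptions import MonomorphicVariantError, RcmrError
from .simulate import VariantSpec

__all__ = [
    "GENOME_WIDE_P",
    "VariantAssoc",
    "LeadSet",
    "fit_variant",
    "conditional_fit",
    "significance_flag",
    "hwe_exact_test",
    "hwe_chi2_test",
    "genotype_counts",
    "select_leads",
    "instrument_f",
    "scan",
]

#: genome-wide significance threshold (strict inequality).
GENOME_WIDE_P = 5e-8

DEFAULT_COVARIATES = ("age", "sex", "bmi", "smoking")


@dataclass
class VariantAssoc:
    """One variant's association with one trait under one adjustment set."""

    variant_id: str
    trait: str
    family: str  # 'linear' | 'logistic'
    beta: float
    se: float
    p: float
    n: int
    maf: float
    hwe_p: float
    f_stat: float
    effect_allele: str = "A"
    other_allele: str = "G"
    chrom: str = "1"
    pos: int = 0
    adjustments: tuple[str, ...] = field(default_factory=tuple)

    @property
    def genome_wide_significant(self) -> bool:
        return significance_flag(self.p)


def significance_flag(p: float) -> bool:
    """True iff p < 5e-8, with the inequality strict: p == 5e-8 is not significant."""
    if not (0.0 < p <= 1.0) and p != 0.0:
        raise RcmrError(f"p value out of range: {p}")
    return p < GENOME_WIDE_P


def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """(hom-effect, het, hom-other) counts from a hard-call dosage vector."""
    d = np.asarray(dosage)
    d = d[~np.isnan(np.asarray(d, dtype=float))]
    return int(np.sum(d == 2)), int(np.sum(d == 1)), int(np.sum(d == 0))


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    The p value is the probability, conditional on the observed allele counts,
    of heterozygote counts no more probable than the one observed.  For a
    sample of ``n`` genotypes with ``n_a`` copies of the rarer allele the
    conditional distribution of the heterozygote count ``h`` (same parity as
    ``n_a``) is

        P(h) = n! / (n_aa! h! n_bb!) * 2^h * n_a! n_b! / (2n)!

    computed here in log space over the full support, so it is valid at the
    small expected counts where the chi-square approximation fails.
    """
    counts = (n_hom_a, n_het, n_hom_b)
    if any(c < 0 or int(c) != c for c in counts):
        raise RcmrError("genotype counts must be nonnegative integers")
    n = sum(int(c) for c in counts)
    if n < 1:
        raise RcmrError("need at least one genotype")
    n_a = 2 * int(n_hom_a) + int(n_het)  # copies of allele a
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0  # monomorphic
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_a = (n_a - hets) // 2
    hom_b = (n_b - hets) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(hom_a + 1)
        - gammaln(hets + 1)
        - gammaln(hom_b + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == int(n_het)]
    if obs.size == 0:
        raise RcmrError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, prob[prob <= obs[0] * (1.0 + 1e-12)].sum()))


def hwe_chi2_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """One-df chi-square HWE test (config alternative to the exact test)."""
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise RcmrError("need at least one genotype")
    p = (2 * n_hom_a + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_a, n_het, n_hom_b], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, 1))


def _assoc_from_fit(
    beta: float,
    se: float,
    p: float,
    dosage: np.ndarray,
    spec: VariantSpec | None,
    variant_id: str,
    trait: str,
    family: str,
    n: int,
    adjustments: tuple[str, ...],
) -> VariantAssoc:
    freq = float(np.mean(dosage)) / 2.0
    maf = min(freq, 1.0 - freq)
    hwe_p = hwe_exact_test(*genotype_counts(dosage))
    f_stat = (beta / se) ** 2 if se > 0 else float("inf")
    kw = {}
    if spec is not None:
        kw = dict(
            effect_allele=spec.effect_allele,
            other_allele=spec.other_allele,
            chrom=spec.chrom,
            pos=spec.pos,
        )
    return VariantAssoc(
        variant_id=variant_id,
        trait=trait,
        family=family,
        beta=beta,
        se=se,
        p=p,
        n=n,
        maf=maf,
        hwe_p=hwe_p,
        f_stat=float(f_stat),
        adjustments=adjustments,
        **kw,
    )


def fit_variant(
    dosage: np.ndarray,
    trait_values: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    family: str = "linear",
    spec: VariantSpec | None = None,
    variant_id: str | None = None,
    trait: str = "trait",
) -> VariantAssoc:
    """Single-variant additive association fit.

    The dosage enters a Gaussian or binomial likelihood as one regressor next
    to the covariate design; MAF and the HWE exact p are computed from the
    same participants that enter the fit.  Monomorphic variants are declared
    untestable.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    keep = np.isfinite(d) & np.isfinite(y)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        keep &= np.all(np.isfinite(C), axis=1)
        C = C[keep]
    d, y = d[keep], y[keep]
    if np.all(d == d[0]):
        vid = variant_id or (spec.id if spec else "?")
        raise MonomorphicVariantError(f"variant {vid} is monomorphic in the fitted sample")
    X = add_intercept(C, n=len(d)) if C is None else add_intercept(C)
    X = np.column_stack([X, d])
    fit = logit(X, y) if family == "logistic" else ols(X, y)
    beta, se, p = fit.coef(X.shape[1] - 1)
    adj = tuple(covariates.columns) if isinstance(covariates, pd.DataFrame) else ()
    return _assoc_from_fit(
        beta, se, p, d, spec, variant_id or (spec.id if spec else "variant"), trait, family, len(d), adj
    )


def conditional_fit(
    dosage: np.ndarray,
    trait_values: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    conditioned: np.ndarray,
    family: str = "linear",
    spec: VariantSpec | None = None,
    variant_id: str | None = None,
    trait: str = "trait",
    conditioned_ids: tuple[str, ...] = (),
) -> VariantAssoc:
    """Association fit conditioning on other variants' dosages.

    The conditioned dosage columns are appended to the covariate design; the
    contract is otherwise :func:`fit_variant`'s.  Conditioning a variant on
    itself (a duplicate column) is rejected.
    """
    cond = np.asarray(conditioned, dtype=float)
    if cond.ndim == 1:
        cond = cond[:, None]
    d = np.asarray(dosage, dtype=float)
    for k in range(cond.shape[1]):
        if np.array_equal(cond[:, k], d):
            raise RcmrError("cannot condition a variant on itself")
    if covariates is None:
        C: np.ndarray | pd.DataFrame = cond
    elif isinstance(covariates, pd.DataFrame):
        C = covariates.to_numpy(float)
        C = np.column_stack([C, cond])
    else:
        C = np.column_stack([np.asarray(covariates, dtype=float), cond])
    assoc = fit_variant(d, trait_values, C, family=family, spec=spec, variant_id=variant_id, trait=trait)
    base = tuple(covariates.columns) if isinstance(covariates, pd.DataFrame) else ()
    assoc.adjustments = base + (conditioned_ids or tuple(f"conditioned_{k}" for k in range(cond.shape[1])))
    return assoc


def instrument_f(assoc_or_t: VariantAssoc | float) -> tuple[float, bool]:
    """(partial F, weak flag) for a single instrument.

    For one added regressor the partial F equals the squared t ratio
    ``(beta/se)^2``; the conventional weak-instrument bound flags F <= 10.
    """
    if isinstance(assoc_or_t, VariantAssoc):
        f = assoc_or_t.f_stat
    else:
        f = float(assoc_or_t) ** 2
    return float(f), bool(f <= 10.0)


def scan(
    G: np.ndarray,
    trait_values: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    variant_ids: list[str] | None = None,
    specs: list[VariantSpec] | tuple[VariantSpec, ...] | None = None,
    family: str = "linear",
    trait: str = "trait",
    hwe: bool = True,
) -> pd.DataFrame:
    """Genome-wide scan over all dosage columns.

    Linear scans are vectorized (exact OLS via residualization); logistic
    scans loop over per-variant maximum-likelihood fits.  Returns the
    summary-statistics table with columns (variant_id, chrom, pos,
    effect_allele, other_allele, trait, family, n, maf, beta, se, p, hwe_p,
    f_stat).
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    n, m = G.shape
    if specs is not None and variant_ids is None:
        variant_ids = [s.id for s in specs]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    if covariates is None:
        C = np.ones((n, 1))
    else:
        Craw = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
        C = add_intercept(Craw)
    if family == "linear":
        beta, se, p = variant_scan(G, y, C)
    elif family == "logistic":
        beta = np.empty(m)
        se = np.empty(m)
        p = np.empty(m)
        for j in range(m):
            X = np.column_stack([C, G[:, j]])
            fit = logit(X, y)
            beta[j], se[j], p[j] = fit.coef(X.shape[1] - 1)
    else:
        raise RcmrError(f"unknown family {family!r}")
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = np.ones(m)
    if hwe:
        for j in range(m):
            hwe_p[j] = hwe_exact_test(*genotype_counts(G[:, j]))
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(se > 0, (beta / se) ** 2, np.inf)
    out = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": [s.chrom for s in specs] if specs is not None else "1",
            "pos": [s.pos for s in specs] if specs is not None else np.arange(m),
            "effect_allele": [s.effect_allele for s in specs] if specs is not None else "A",
            "other_allele": [s.other_allele for s in specs] if specs is not None else "G",
            "trait": trait,
            "family": family,
            "n": n,
            "maf": maf,
            "beta": beta,
            "se": se,
            "p": p,
            "hwe_p": hwe_p,
            "f_stat": f_stat,
        }
    )
    return out


@dataclass
class LeadSet:
    """Retained lead variants plus a complete pruning log.

    Each removal records the variant, a reason in {LD, window, HWE, weak},
    the retained partner (for LD removals) and the offending r^2.
    """

    retained: pd.DataFrame
    pruning_log: pd.DataFrame

    @property
    def variant_ids(self) -> list[str]:
        return list(self.retained["variant_id"])


def select_leads(
    assocs: pd.DataFrame,
    G: np.ndarray,
    variant_ids: list[str],
    window_bp: int = 1_000_000,
    r2_threshold: float = 0.2,
    hwe_min: float = 1e-6,
    f_min: float | None = None,
) -> LeadSet:
    """Greedy LD-aware lead selection among genome-wide-significant variants.

    Candidates are sorted by (p, pos, variant_id) -- a total order, so the
    output is invariant to input row order.  A candidate is retained iff its
    sample dosage r^2 with every already-retained variant on the same
    chromosome within ``window_bp`` stays below ``r2_threshold``, its HWE
    exact p is >= ``hwe_min`` and (optionally) its F exceeds ``f_min``.
    Variants with missing positions cannot be windowed and are skipped with a
    logged reason.
    """
    col_of = {vid: j for j, vid in enumerate(variant_ids)}
    Gf = np.asarray(G, dtype=float)
    order = assocs.sort_values(["p", "pos", "variant_id"], kind="mergesort").reset_index(drop=True)
    retained_rows: list[int] = []
    log: list[dict] = []
    for i, row in order.iterrows():
        vid = row["variant_id"]
        if pd.isna(row.get("pos")):
            log.append(dict(variant_id=vid, reason="window", partner="", r2=np.nan))
            continue
        if row["hwe_p"] < hwe_min:
            log.append(dict(variant_id=vid, reason="HWE", partner="", r2=np.nan))
            continue
        if f_min is not None and row["f_stat"] <= f_min:
            log.append(dict(variant_id=vid, reason="weak", partner="", r2=np.nan))
            continue
        g = Gf[:, col_of[vid]]
        hit = None
        for k in retained_rows:
            kept = order.iloc[k]
            if kept["chrom"] != row["chrom"]:
                continue
            if abs(int(kept["pos"]) - int(row["pos"])) > window_bp:
                continue
            r = np.corrcoef(g, Gf[:, col_of[kept["variant_id"]]])[0, 1]
            if np.isfinite(r) and r**2 >= r2_threshold:
                hit = (kept["variant_id"], float(r**2))
                break
        if hit is not None:
            log.append(dict(variant_id=vid, reason="LD", partner=hit[0], r2=hit[1]))
        else:
            retained_rows.append(i)
    retained = order.iloc[retained_rows].reset_index(drop=True)
    pruning_log = pd.DataFrame(log, columns=["variant_id", "reason", "partner", "r2"])
    return LeadSet(retained=retained, pruning_log=pruning_log)
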