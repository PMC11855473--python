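"""Monte-Carlo evaluation harnesses for the MR pipeline.

These functions run the full estimation machinery over many freshly simulated
cohorts and summarize the behavior a valid one-sample MR design must show:
unbiased recovery of a planted causal effect where the observational estimate
is confounded, nominal type-I calibration under the null, and near-certain
exclusion of strongly pleiotropic variants by the cross-adjusted rule.

Replicate seeds are derived from a single base seed and kept below 2^31.

Problem sizes follow the presets (n = 20,000 participants, 50 instruments for
the recovery study; n = 10,000 for the calibration and exclusion studies)
-- large enough that the analytic approximations hold, small enough to run
hundreds of replicates on one core.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._regression import add_intercept, ols, variant_scan
from . import gwas as gwas_mod
from .instruments import exclude_pleiotropic
from .sensitivity import RatioEstimate, ivw
from .simulate import default_variants, scenario, simulate_cohort

__all__ = [
    "derive_seed",
    "ForwardReplicate",
    "forward_replicate",
    "recovery_study",
    "calibration_study",
    "exclusion_study",
]


def derive_seed(base: int, i: int) -> int:
    """Deterministic per-replicate seed below 2^31."""
    return int((int(base) * 1_000_003 + 7919 * i + 1) % (2**31 - 1))


@dataclass
class ForwardReplicate:
    """Estimates from one simulated forward-direction analysis."""

    beta_2sls: float
    se_2sls: float
    p_2sls: float
    beta_obs: float
    se_obs: float
    beta_ivw: float
    se_ivw: float
    p_ivw: float
    n_instruments: int
    first_stage_beta: float
    stage_one_f: float


def forward_replicate(
    config,
    seed: int,
    apply_exclusion: bool = True,
    select_significant: bool = True,
) -> ForwardReplicate:
    """One full forward MR pass on a fresh cohort.

    Runs the discovery pipeline with vectorized linear algebra: exposure scan
    -> genome-wide significance filter -> (optionally) the cross-adjusted
    pleiotropy exclusion -> WGRS -> first stage / reduced form / Wald-scaled
    2SLS, plus the per-variant IVW estimate and the observational fit.

    ``apply_exclusion=False`` isolates estimator calibration from the
    outcome-dependent exclusion filter (which is exercised by
    :func:`exclusion_study`); ``select_significant=False`` additionally keeps
    the full planted panel.
    """
    cohort = simulate_cohort(replace(config, seed=seed))
    ph = cohort.phenotypes
    x = ph["exposure"].to_numpy(float)
    y = ph["outcome"].to_numpy(float)
    C = add_intercept(ph[["age", "sex", "bmi", "smoking"]].to_numpy(float))
    G = cohort.dosages.astype(float)

    bx, sx, px = variant_scan(G, x, C)
    keep = px < gwas_mod.GENOME_WIDE_P if select_significant else np.ones(len(px), bool)
    if apply_exclusion and keep.any():
        Cx = np.column_stack([C, x])
        _, _, p_cross = variant_scan(G[:, keep], y, Cx)
        sub = np.flatnonzero(keep)
        keep = keep.copy()
        keep[sub[p_cross < 0.01]] = False
    if not keep.any():
        raise RuntimeError("no instruments retained in replicate")

    w = bx[keep]
    score = G[:, keep] @ w

    Xs = np.column_stack([C, score])
    fs = ols(Xs, x)
    fs_beta, fs_se, _ = fs.coef(Xs.shape[1] - 1)
    rf = ols(Xs, y)
    rf_beta, rf_se, rf_p = rf.coef(Xs.shape[1] - 1)
    beta_2sls = rf_beta / fs_beta
    se_2sls = rf_se / abs(fs_beta)

    Xo = np.column_stack([C, x])
    obs = ols(Xo, y)
    obs_beta, obs_se, _ = obs.coef(Xo.shape[1] - 1)

    by, sy, _ = variant_scan(G[:, keep], y, C)
    ratios = [
        RatioEstimate(variant_id=str(j), beta_x=float(b), se_x=float(s),
                      beta_y=float(b2), se_y=float(s2))
        for j, (b, s, b2, s2) in enumerate(zip(w, sx[keep], by, sy))
    ]
    est = ivw(ratios, "fixed")

    f_stat = (fs_beta / fs_se) ** 2 if fs_se > 0 else float("inf")
    return ForwardReplicate(
        beta_2sls=float(beta_2sls),
        se_2sls=float(se_2sls),
        p_2sls=float(rf_p),
        beta_obs=float(obs_beta),
        se_obs=float(obs_se),
        beta_ivw=est.beta,
        se_ivw=est.se,
        p_ivw=est.p,
        n_instruments=int(keep.sum()),
        first_stage_beta=float(fs_beta),
        stage_one_f=float(f_stat),
    )


def recovery_study(
    base_seed: int,
    reps: int = 200,
    n: int = 20_000,
    n_variants: int = 50,
) -> dict:
    """Parameter recovery under the forward-causal preset.

    Returns Monte-Carlo means and SEs for the 2SLS and observational
    estimates; truth is the preset's causal beta (0.5) with an active
    confounder biasing the observational slope upward.
    """
    cfg = scenario("forward-causal", n=n, seed=0, n_variants=n_variants)
    b2, bo, nins = [], [], []
    for i in range(reps):
        # the panel is valid by construction, and the study measures estimator
        # bias: the instruments are taken as given.  Discovery selection and
        # the cross-adjusted exclusion filter are characterized separately
        # (the latter conditions on the exposure, a collider between the
        # variants and the confounder, so under active confounding it
        # preferentially removes strong instruments and would fold its own
        # small selection bias into this measurement).
        rep = forward_replicate(
            cfg, derive_seed(base_seed, i), apply_exclusion=False, select_significant=False
        )
        b2.append(rep.beta_2sls)
        bo.append(rep.beta_obs)
        nins.append(rep.n_instruments)
    b2 = np.asarray(b2)
    bo = np.asarray(bo)
    return dict(
        truth=cfg.causal_beta,
        reps=reps,
        n=n,
        mean_2sls=float(b2.mean()),
        mc_se_2sls=float(b2.std(ddof=1) / np.sqrt(reps)),
        mean_obs=float(bo.mean()),
        mc_se_obs=float(bo.std(ddof=1) / np.sqrt(reps)),
        mean_instruments=float(np.mean(nins)),
    )


def calibration_study(
    base_seed: int,
    reps: int = 500,
    n: int = 10_000,
    n_variants: int = 50,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of IVW and 2SLS under the null preset.

    The exclusion filter is deliberately off: instrument selection then
    depends only on the exposure scan, which is independent of the outcome
    under the null, so the nominal level is the exact benchmark.
    """
    cfg = scenario("null", n=n, seed=0, n_variants=n_variants)
    rej_ivw = rej_2sls = 0
    for i in range(reps):
        rep = forward_replicate(cfg, derive_seed(base_seed + 17, i), apply_exclusion=False)
        rej_ivw += rep.p_ivw < alpha
        rej_2sls += rep.p_2sls < alpha
    return dict(
        reps=reps,
        n=n,
        alpha=alpha,
        ivw_rejection_rate=rej_ivw / reps,
        twostage_rejection_rate=rej_2sls / reps,
    )


def exclusion_study(
    base_seed: int,
    reps: int = 100,
    n: int = 10_000,
    n_variants: int = 50,
    delta: float = 0.1,
) -> dict:
    """Power of the cross-adjusted p<0.01 exclusion rule.

    One variant of the panel carries a direct outcome effect ``delta`` (an
    exclusion-restriction violation); the study reports how often the rule
    removes it, and how often valid variants are removed by chance.
    """
    excluded = 0
    false_excl = total_valid = 0
    for i in range(reps):
        seed = derive_seed(base_seed + 31, i)
        variants = default_variants(
            n_variants=n_variants, seed=seed, heritability=0.15,
            delta_fraction=1.0 / n_variants, delta_value=delta,
        )
        cfg = scenario("forward-causal", n=n, seed=seed, variants=variants)
        cohort = simulate_cohort(cfg)
        ph = cohort.phenotypes
        log = exclude_pleiotropic(
            cohort.dosages.astype(float),
            ph["exposure"].to_numpy(float),
            ph["outcome"].to_numpy(float),
            ph[["age", "sex", "bmi", "smoking"]],
        )
        retained = log["retained"].to_numpy()
        excluded += not retained[0]  # the planted variant is first in the panel
        false_excl += int((~retained[1:]).sum())
        total_valid += n_variants - 1
    return dict(
        reps=reps,
        n=n,
        delta=delta,
        planted_exclusion_rate=excluded / reps,
        valid_exclusion_rate=false_excl / total_valid,
    )
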