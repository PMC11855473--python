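"""Ratio bookkeeping, IVW/Egger/median estimators and Q statistics against
hand-computed fixtures and cross-checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

import rcmr
from rcmr.exceptions import RcmrError
from rcmr.sensitivity import (
    RatioEstimate,
    funnel_and_scatter,
    heterogeneity,
    ivw,
    make_ratios,
    median_estimators,
    mr_egger,
    sensitivity_report,
)


def ratio(vid, bx, by, sy, sx=0.01):
    return RatioEstimate(variant_id=vid, beta_x=bx, se_x=sx, beta_y=by, se_y=sy)


def stats_frame(rows):
    return pd.DataFrame(
        rows, columns=["variant_id", "effect_allele", "other_allele", "beta", "se"]
    )


class TestMakeRatios:
    def test_arithmetic(self):
        exp = stats_frame([("v1", "A", "G", 0.5, 0.05)])
        out = stats_frame([("v1", "A", "G", 1.0, 0.2)])
        (r,) = make_ratios(exp, out)
        assert r.ratio == pytest.approx(2.0)
        assert r.ratio_se == pytest.approx(0.4)

    def test_negative_bx_flip_invariance(self):
        exp = stats_frame([("v1", "A", "G", -0.5, 0.05)])
        out = stats_frame([("v1", "A", "G", -1.0, 0.2)])
        (r,) = make_ratios(exp, out)
        assert r.flipped and r.beta_x > 0
        assert r.ratio == pytest.approx(2.0)  # unchanged by the joint flip

    def test_swapped_alleles_harmonized(self):
        exp = stats_frame([("v1", "A", "G", 0.5, 0.05)])
        out = stats_frame([("v1", "G", "A", -1.0, 0.2)])  # measured on the other allele
        (r,) = make_ratios(exp, out)
        assert r.ratio == pytest.approx(2.0)

    def test_unharmonizable_dropped(self):
        exp = stats_frame([("v1", "A", "G", 0.5, 0.05)])
        out = stats_frame([("v1", "C", "T", 1.0, 0.2)])
        assert make_ratios(exp, out) == []

    def test_panel_centers_on_truth(self):
        cfg = rcmr.scenario("forward-causal", n=15_000, seed=61)
        c = rcmr.simulate_cohort(cfg)
        ph = c.phenotypes
        C = ph[["age", "sex", "bmi", "smoking"]]
        exp_stats = rcmr.scan(c.dosages, ph["exposure"].to_numpy(), C, specs=c.variants, hwe=False)
        out_stats = rcmr.scan(c.dosages, ph["outcome"].to_numpy(), C, specs=c.variants, hwe=False)
        strong = exp_stats["p"] < 5e-8
        ratios = make_ratios(exp_stats[strong.to_numpy()], out_stats[strong.to_numpy()])
        est = ivw(ratios)
        assert est.beta == pytest.approx(0.5, abs=3 * est.se)


class TestIVW:
    def test_all_equal(self):
        rs = [ratio(f"v{i}", 1.0, 0.3, s) for i, s in enumerate((0.1, 0.2, 0.3))]
        est = ivw(rs)
        assert est.beta == pytest.approx(0.3)
        het = heterogeneity(rs, est.beta)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert ivw(rs, "random").dispersion == 1.0

    def test_single_ratio(self):
        est = ivw([ratio("v", 0.5, 1.0, 0.2)])
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.4)

    def test_three_ratio_hand_computed(self):
        rs = [ratio("a", 1.0, 1.0, 0.5), ratio("b", 1.0, 2.0, 1.0), ratio("c", 1.0, 0.5, 0.25)]
        w = [1 / 0.25, 1 / 1.0, 1 / 0.0625]
        expected = (w[0] * 1.0 + w[1] * 2.0 + w[2] * 0.5) / sum(w)
        est = ivw(rs)
        assert est.beta == pytest.approx(expected, rel=1e-12)
        assert est.se == pytest.approx(sum(w) ** -0.5, rel=1e-12)

    def test_matches_statsmodels_wls_through_origin(self, rng):
        rs = [ratio(f"v{i}", rng.uniform(0.1, 1), rng.normal(), rng.uniform(0.1, 0.5)) for i in range(20)]
        bx = np.array([r.beta_x for r in rs])
        by = np.array([r.beta_y for r in rs])
        w = np.array([1 / r.se_y**2 for r in rs])
        ref = sm.WLS(by, bx, weights=w).fit().params[0]
        assert ivw(rs).beta == pytest.approx(ref, rel=1e-10)

    def test_random_effects_inflates_only(self, rng):
        rs = [ratio(f"v{i}", 1.0, rng.normal(0.5, 1.0), 0.1) for i in range(15)]
        fixed, random = ivw(rs), ivw(rs, "random")
        assert random.beta == fixed.beta
        assert random.se >= fixed.se
        assert random.dispersion >= 1.0


class TestEgger:
    def test_zero_intercept_slope_equals_ivw(self, rng):
        """Constraining the Egger intercept to zero recovers fixed IVW exactly
        (same 1/se_y^2 weights); checked by comparing the free fit on data
        generated with no pleiotropy and the algebraic identity via WLS."""
        rs = [ratio(f"v{i}", rng.uniform(0.2, 1), 0.0, rng.uniform(0.1, 0.3)) for i in range(12)]
        rs = [
            RatioEstimate(r.variant_id, r.beta_x, r.se_x, 0.5 * r.beta_x, r.se_y)
            for r in rs
        ]
        bx = np.array([r.beta_x for r in rs])
        by = np.array([r.beta_y for r in rs])
        w = np.array([1 / r.se_y**2 for r in rs])
        slope0 = float(np.sum(w * bx * by) / np.sum(w * bx * bx))  # zero-intercept WLS
        assert ivw(rs).beta == pytest.approx(slope0, rel=1e-12)

    def test_needs_three(self):
        with pytest.raises(RcmrError):
            mr_egger([ratio("a", 1, 1, 0.1), ratio("b", 1, 1, 0.1)])

    def test_null_intercept(self, rng):
        rs = [
            ratio(f"v{i}", bx, 0.5 * bx + rng.normal(0, 0.1), 0.1)
            for i, bx in enumerate(rng.uniform(0.2, 1.0, 25))
        ]
        fit = mr_egger(rs)
        assert abs(fit.intercept) < 3 * fit.intercept_se
        assert fit.slope == pytest.approx(0.5, abs=3 * fit.slope_se)

    def test_matches_statsmodels_wls(self, rng):
        rs = [ratio(f"v{i}", rng.uniform(0.1, 1), rng.normal(), rng.uniform(0.1, 0.4)) for i in range(15)]
        fit = mr_egger(rs)
        bx = np.array([r.beta_x for r in rs])
        by = np.array([r.beta_y for r in rs])
        w = np.array([1 / r.se_y**2 for r in rs])
        ref = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-10)
        assert fit.slope == pytest.approx(ref.params[1], rel=1e-10)

    def test_generator_pleiotropy_positive_control(self):
        """End-to-end: 30% of a simulated panel carries exposure-allele-
        oriented direct effects; the Egger intercept flags it in most
        replicates.  Intercept power grows with panel size (the zero/nonzero
        delta mixture caps the per-variant signal), hence the 150-variant
        panel."""
        detected = 0
        reps = 12
        for s in range(reps):
            # n large enough that per-variant weak-instrument noise does not
            # blur the intercept (orientation + regression dilution)
            cfg = rcmr.scenario("pleiotropic", n=20_000, seed=3000 + s, n_variants=150)
            c = rcmr.simulate_cohort(cfg)
            ph = c.phenotypes
            C = ph[["age", "sex", "bmi", "smoking"]]
            es = rcmr.scan(c.dosages, ph["exposure"].to_numpy(), C, specs=c.variants, hwe=False)
            os_ = rcmr.scan(c.dosages, ph["outcome"].to_numpy(), C, specs=c.variants, hwe=False)
            fit = mr_egger(make_ratios(es, os_))
            detected += fit.intercept_p < 0.05
        assert detected >= 0.6 * reps

    def test_directional_pleiotropy_detected(self):
        """Common-sign direct effects: intercept nonzero, slope closer to the
        truth than IVW in most replicates."""
        detected = closer = 0
        reps = 25
        for s in range(reps):
            rng = np.random.default_rng(9000 + s)
            bx = rng.uniform(0.2, 1.0, 40)
            sy = np.full(40, 0.08)
            pleio = 0.12  # common-sign intercept-like effect
            by = 0.5 * bx + pleio + rng.normal(0, sy)
            rs = [ratio(f"v{i}", bx[i], by[i], sy[i]) for i in range(40)]
            fit = mr_egger(rs)
            detected += fit.intercept_p < 0.05
            closer += abs(fit.slope - 0.5) < abs(ivw(rs).beta - 0.5)
        assert detected >= 0.8 * reps
        assert closer >= 0.8 * reps


class TestMedians:
    def test_equal_weights_identity(self, rng):
        rs = [ratio(f"v{i}", 1.0, rng.normal(), 0.2) for i in range(9)]
        simple = median_estimators(rs, "simple", seed=3)
        weighted = median_estimators(rs, "weighted", seed=3)
        assert weighted.beta == pytest.approx(simple.beta)

    def test_three_ratio_interpolation_hand_worked(self):
        """Unequal weights with the 0.5 crossing inside the middle interval."""
        rs = [ratio("a", 1.0, 1.0, 0.5), ratio("b", 1.0, 2.0, 0.5 / np.sqrt(2)), ratio("c", 1.0, 3.0, 0.5)]
        # weights 4, 8, 4; order a,b,c; S_j = cum - w/2 -> 2, 8, 14; /16 ->
        # 0.125, 0.5, 0.875: crossing exactly at the middle ratio
        est = median_estimators(rs, "weighted", bootstrap_reps=50, seed=1)
        assert est.beta == pytest.approx(2.0)
        # now make the crossing interpolate between a and b
        rs2 = [ratio("a", 1.0, 1.0, 0.25), ratio("b", 1.0, 2.0, 0.5), ratio("c", 1.0, 3.0, 1.0)]
        # weights 16, 4, 1; S = 8, 18, 20.5; /21 -> 0.381, 0.857, 0.976
        # interpolate between 1.0 and 2.0 at (0.5-0.381)/(0.857-0.381)
        expected = 1.0 + (2.0 - 1.0) * (0.5 - 8 / 21) / (18 / 21 - 8 / 21)
        est2 = median_estimators(rs2, "weighted", bootstrap_reps=50, seed=1)
        assert est2.beta == pytest.approx(expected, rel=1e-12)

    def test_breakdown_resistance(self):
        """<=50% invalid variants with wild ratios: medians beat IVW."""
        wins = 0
        reps = 20
        for s in range(reps):
            rng = np.random.default_rng(400 + s)
            bx = rng.uniform(0.3, 1.0, 21)
            by = 0.5 * bx + rng.normal(0, 0.05, 21)
            by[:8] += 1.5  # 8/21 invalid, large common offset
            rs = [ratio(f"v{i}", bx[i], by[i], 0.05) for i in range(21)]
            med = median_estimators(rs, "weighted", bootstrap_reps=100, seed=s)
            wins += abs(med.beta - 0.5) < abs(ivw(rs).beta - 0.5)
        assert wins >= 0.8 * reps

    def test_needs_three(self):
        with pytest.raises(RcmrError):
            median_estimators([ratio("a", 1, 1, 0.1)] * 2)

    def test_bootstrap_seeded(self):
        rs = [ratio(f"v{i}", 1.0, float(i), 0.3) for i in range(5)]
        a = median_estimators(rs, "weighted", seed=9)
        b = median_estimators(rs, "weighted", seed=9)
        assert a.se == b.se


class TestHeterogeneity:
    def test_homogeneous_zero(self):
        rs = [ratio(f"v{i}", 1.0, 0.7, s) for i, s in enumerate((0.1, 0.2, 0.4))]
        het = heterogeneity(rs)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.q_p == pytest.approx(1.0)

    def test_two_point_closed_form(self):
        r1, r2 = ratio("a", 1.0, 1.0, 0.5), ratio("b", 1.0, 2.0, 0.5)
        # equal weights w=4: ivw beta = 1.5; Q = 4*(0.5^2)*2 = 2
        het = heterogeneity([r1, r2])
        assert het.q == pytest.approx(2.0, rel=1e-12)
        assert het.q_df == 1

    def test_q_geq_qprime_and_decomposition(self, rng):
        for s in range(10):
            r = np.random.default_rng(s)
            rs = [
                ratio(f"v{i}", r.uniform(0.1, 1), r.normal(), r.uniform(0.05, 0.5))
                for i in range(8)
            ]
            het = heterogeneity(rs)
            assert het.q >= het.q_prime >= 0
            assert het.q_df == 7 and het.q_prime_df == 6

    def test_planted_heterogeneity_detected(self):
        sig = 0
        reps = 20
        for s in range(reps):
            rng = np.random.default_rng(50 + s)
            bx = rng.uniform(0.3, 1.0, 30)
            by = 0.5 * bx + rng.normal(0, 0.3, 30)  # spread ≫ se_y
            rs = [ratio(f"v{i}", bx[i], by[i], 0.05) for i in range(30)]
            sig += heterogeneity(rs).q_p < 0.05
        assert sig >= 0.9 * reps


class TestFunnelScatter:
    def test_row_counts_and_symmetry(self, rng):
        rs = [
            ratio(f"v{i}", bx, 0.5 * bx + rng.normal(0, 0.1), 0.1)
            for i, bx in enumerate(rng.uniform(0.2, 1.0, 40))
        ]
        funnel, scatter = funnel_and_scatter(rs, ivw(rs), mr_egger(rs))
        assert len(funnel) == len(scatter) == 40
        # symmetric panel: ratio ~ precision regression slope near 0
        fit = sm.OLS(funnel["ratio"], sm.add_constant(funnel["precision"])).fit()
        assert abs(fit.params.iloc[1]) < 3 * fit.bse.iloc[1]
        assert {d["label"] for d in scatter.attrs["lines"]} == {"IVW", "MR-Egger"}


class TestInvariances:
    @given(st.integers(min_value=0, max_value=500))
    def test_order_and_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        j = 7
        rs = [
            ratio(f"v{i}", rng.uniform(0.1, 1) * rng.choice([-1, 1]), rng.normal(), rng.uniform(0.1, 0.4))
            for i in range(j)
        ]
        perm = list(rng.permutation(j))
        rs_perm = [rs[k] for k in perm]
        for estimator in (lambda r: ivw(r).beta, lambda r: mr_egger(r).slope):
            assert estimator(rs) == pytest.approx(estimator(rs_perm), rel=1e-9)
        assert heterogeneity(rs).q == pytest.approx(heterogeneity(rs_perm).q, rel=1e-9)

    def test_estimators_agree_on_valid_panel(self):
        """J=50 valid instruments: all five estimators within 2x the largest SE."""
        cfg = rcmr.scenario("forward-causal", n=20_000, seed=91)
        c = rcmr.simulate_cohort(cfg)
        ph = c.phenotypes
        C = ph[["age", "sex", "bmi", "smoking"]]
        exp_stats = rcmr.scan(c.dosages, ph["exposure"].to_numpy(), C, specs=c.variants, hwe=False)
        out_stats = rcmr.scan(c.dosages, ph["outcome"].to_numpy(), C, specs=c.variants, hwe=False)
        ratios = make_ratios(exp_stats, out_stats)
        rep = sensitivity_report(ratios, seed=5)
        betas = [
            rep.ivw_fixed.beta,
            rep.ivw_random.beta,
            rep.egger.slope,
            rep.simple_median.beta,
            rep.weighted_median.beta,
        ]
        ses = [rep.ivw_fixed.se, rep.ivw_random.se, rep.egger.slope_se,
               rep.simple_median.se, rep.weighted_median.se]
        assert max(betas) - min(betas) < 2 * max(ses)
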