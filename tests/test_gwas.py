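"""Association fits against closed-form OLS, HWE exact test against exact
Fraction-arithmetic enumeration, lead selection against subset search."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import rcmr
from rcmr.exceptions import MonomorphicVariantError, RcmrError
from rcmr.gwas import (
    conditional_fit,
    fit_variant,
    genotype_counts,
    hwe_chi2_test,
    hwe_exact_test,
    instrument_f,
    select_leads,
    significance_flag,
)
from rcmr.simulate import VariantSpec, simulate_genotypes


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact-rational HWE p: enumerate every heterozygote count compatible
    with the observed allele counts and sum the conditional probabilities no
    larger than the observed one.  Independent of the package's log-space
    implementation."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n - na
    rare = min(na, nb)
    denom = comb(2 * n, na)

    def prob(h: int) -> Fraction:
        haa = (na - h) // 2
        hbb = (nb - h) // 2
        multinom = Fraction(
            comb(n, haa) * comb(n - haa, h), 1
        )  # n!/(haa! h! hbb!)
        return multinom * Fraction(2**h, denom)

    hs = range(rare % 2, rare + 1, 2)
    probs = {h: prob(h) for h in hs}
    obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= obs)


class TestHWE:
    def test_monomorphic_is_one(self):
        for n in (1, 5, 40):
            assert hwe_exact_test(n, 0, 0) == 1.0
            assert hwe_exact_test(0, 0, n) == 1.0

    def test_matches_enumeration_all_small_tables(self):
        """Every genotype table with total count <= 30."""
        worst = 0.0
        for total in range(1, 31):
            for n_aa in range(total + 1):
                for n_ab in range(total - n_aa + 1):
                    n_bb = total - n_aa - n_ab
                    got = hwe_exact_test(n_aa, n_ab, n_bb)
                    want = float(hwe_enumeration_oracle(n_aa, n_ab, n_bb))
                    worst = max(worst, abs(got - want))
        assert worst < 1e-9

    def test_uniform_under_hwe(self):
        spec = VariantSpec(
            id="v", chrom="1", pos=100, effect_allele="A", other_allele="G", maf=0.3
        )
        ps = [
            hwe_exact_test(*genotype_counts(simulate_genotypes([spec], 2000, s)[:, 0]))
            for s in range(300)
        ]
        # discrete conservatism allowed; gross non-uniformity is not
        assert 0.3 < np.mean(np.asarray(ps) < 0.5) < 0.7
        assert np.mean(np.asarray(ps) < 0.05) < 0.10

    def test_chi2_agrees_at_large_counts(self):
        assert hwe_chi2_test(4900, 4200, 900) == pytest.approx(
            hwe_exact_test(4900, 4200, 900), abs=0.02
        )

    def test_invalid_counts(self):
        with pytest.raises(RcmrError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(RcmrError):
            hwe_exact_test(-1, 2, 3)


class TestSignificance:
    @pytest.mark.parametrize(
        "p,flag", [(1e-9, True), (5e-8, False), (0.05, False), (4.999e-8, True)]
    )
    def test_strict_threshold(self, p, flag):
        assert significance_flag(p) is flag


class TestFitVariant:
    def test_closed_form_ols_oracle(self, tiny_table):
        """8-row fixture: beta must equal the normal-equations solution."""
        t = tiny_table
        X = np.column_stack([np.ones(8), t["age"], t["sex"], t["g"]])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ t["y"].to_numpy())
        assoc = fit_variant(t["g"].to_numpy(), t["y"].to_numpy(), t[["age", "sex"]])
        assert assoc.beta == pytest.approx(beta_oracle[-1], rel=1e-10)
        # f_stat invariant for linear fits
        assert assoc.f_stat == pytest.approx((assoc.beta / assoc.se) ** 2, rel=1e-12)

    def test_null_variant(self, null_cohort):
        ph = null_cohort.phenotypes
        hits = 0
        for j in range(null_cohort.dosages.shape[1]):
            a = fit_variant(
                null_cohort.dosages[:, j],
                ph["outcome"].to_numpy(),
                ph[["age", "sex", "bmi", "smoking"]],
            )
            hits += abs(a.beta) > 3 * a.se
        assert hits <= 2

    def test_planted_effect_recovered(self):
        cfg = rcmr.scenario("null", n=20_000, seed=9, n_variants=5)
        v0 = cfg.variants[0]
        gamma = 0.3
        variants = (v0.__class__(**{**v0.__dict__, "gamma": gamma}),) + cfg.variants[1:]
        cfg2 = cfg.__class__(**{**cfg.__dict__, "variants": variants})
        cohort = rcmr.simulate_cohort(cfg2)
        a = fit_variant(
            cohort.dosages[:, 0],
            cohort.phenotypes["exposure"].to_numpy(),
            cohort.phenotypes[["age", "sex", "bmi", "smoking"]],
        )
        assert abs(a.beta - gamma) < 3 * a.se

    def test_monomorphic_rejected(self):
        with pytest.raises(MonomorphicVariantError):
            fit_variant(np.zeros(50), np.random.default_rng(0).normal(size=50), None)

    def test_allele_flip_negates_beta(self, tiny_table):
        t = tiny_table
        a = fit_variant(t["g"].to_numpy(), t["y"].to_numpy(), t[["age", "sex"]])
        b = fit_variant(2 - t["g"].to_numpy(), t["y"].to_numpy(), t[["age", "sex"]])
        assert b.beta == pytest.approx(-a.beta, rel=1e-10)
        assert b.se == pytest.approx(a.se, rel=1e-10)
        assert b.p == pytest.approx(a.p, rel=1e-10)
        assert b.f_stat == pytest.approx(a.f_stat, rel=1e-10)

    def test_logistic_family(self, rng):
        n = 4000
        g = rng.binomial(2, 0.3, n).astype(float)
        eta = -2.0 + 0.4 * g
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        a = fit_variant(g, y, None, family="logistic")
        assert abs(a.beta - 0.4) < 3 * a.se


class TestConditionalFit:
    def test_self_conditioning_rejected(self, tiny_table):
        g = tiny_table["g"].to_numpy(float)
        with pytest.raises(RcmrError):
            conditional_fit(g, tiny_table["y"].to_numpy(), None, g)

    def test_independent_conditioning_harmless(self, small_cohort):
        ph = small_cohort.phenotypes
        y = ph["exposure"].to_numpy()
        C = ph[["age", "sex", "bmi", "smoking"]]
        a = fit_variant(small_cohort.dosages[:, 0], y, C)
        b = conditional_fit(small_cohort.dosages[:, 0], y, C, small_cohort.dosages[:, 1])
        assert abs(b.beta - a.beta) < 3 * a.se

    def test_proxy_signal_absorbed_by_causal_partner(self, rng):
        """A variant associated only through LD loses its signal once the
        causal partner is conditioned on."""
        n = 20_000
        specs = [
            VariantSpec(id=a, chrom="1", pos=p, effect_allele="A", other_allele="G",
                        maf=0.4, ld_block=1)
            for a, p in (("causal", 1000), ("tag", 2000))
        ]
        G = simulate_genotypes(specs, n, 17, block_rho=0.97).astype(float)
        y = 0.5 * G[:, 0] + rng.normal(size=n)
        marginal = fit_variant(G[:, 1], y, None)
        assert marginal.beta > 0.3  # tag variant looks strongly associated
        b = conditional_fit(G[:, 1], y, None, G[:, 0])
        assert abs(b.beta) < 3 * b.se

    def test_two_variant_closed_form(self, rng):
        n = 500
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = np.clip(g1 + rng.binomial(1, 0.3, n) - rng.binomial(1, 0.3, n), 0, 2).astype(float)
        y = 0.3 * g1 - 0.2 * g2 + rng.normal(size=n)
        X = np.column_stack([np.ones(n), g2, g1])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        b = conditional_fit(g1, y, None, g2)
        assert b.beta == pytest.approx(oracle[-1], rel=1e-10)


class TestInstrumentF:
    def test_f_equals_t_squared(self):
        f, weak = instrument_f(4.0)
        assert f == 16.0 and not weak
        f, weak = instrument_f(3.0)
        assert f == 9.0 and weak

    def test_f_matches_r2_closed_form(self, rng):
        n = 20_000
        g = rng.binomial(2, 0.3, n).astype(float)
        r2 = 0.018
        sd_g = g.std()
        y = np.sqrt(r2) * (g - g.mean()) / sd_g + np.sqrt(1 - r2) * rng.normal(size=n)
        a = fit_variant(g, y, None)
        r2_hat = np.corrcoef(g, y)[0, 1] ** 2
        assert a.f_stat == pytest.approx((n - 2) * r2_hat / (1 - r2_hat), rel=1e-10)
        assert a.f_stat == pytest.approx((n - 2) * r2 / (1 - r2), rel=0.35)


def greedy_oracle(order, corr_ok):
    """Independent re-statement of the greedy rule by subset enumeration:
    the greedy result is the unique subset S (in the candidate order) such
    that each candidate is in S iff compatible with all earlier members of S."""
    best: list[int] = []
    for i in order:
        if all(corr_ok(i, k) for k in best):
            best.append(i)
    return best


class TestSelectLeads:
    def _frame(self, specs, ps, G):
        n = G.shape[0]
        return pd.DataFrame(
            {
                "variant_id": [s.id for s in specs],
                "chrom": [s.chrom for s in specs],
                "pos": [s.pos for s in specs],
                "p": ps,
                "hwe_p": 1.0,
                "f_stat": 100.0,
                "beta": 0.1,
                "se": 0.01,
                "n": n,
                "maf": [s.maf for s in specs],
                "effect_allele": [s.effect_allele for s in specs],
                "other_allele": [s.other_allele for s in specs],
                "trait": "t",
                "family": "linear",
            }
        )

    def _specs(self, k, block=None, spacing=1000):
        return [
            VariantSpec(
                id=f"v{j}",
                chrom="1",
                pos=1000 + j * spacing,
                effect_allele="A",
                other_allele="G",
                maf=0.3,
                ld_block=block if (block and j < 5) else None,
            )
            for j in range(k)
        ]

    def test_independent_all_retained(self):
        specs = self._specs(6)
        G = simulate_genotypes(specs, 4000, 3)
        assocs = self._frame(specs, np.linspace(1e-12, 1e-9, 6), G)
        leads = select_leads(assocs, G, [s.id for s in specs])
        assert len(leads.retained) == 6
        assert leads.pruning_log.empty

    def test_duplicate_column_smaller_p_wins(self):
        specs = self._specs(2)
        G0 = simulate_genotypes(specs[:1], 3000, 5)
        G = np.column_stack([G0, G0])  # r^2 = 1
        assocs = self._frame(specs, [1e-10, 1e-12], G)
        leads = select_leads(assocs, G, [s.id for s in specs])
        assert leads.variant_ids == ["v1"]  # the smaller p
        log = leads.pruning_log
        assert list(log["reason"]) == ["LD"] and log.iloc[0]["partner"] == "v1"

    def test_matches_bruteforce_on_ld_block(self):
        """5-variant rho=0.95 block + 3 independents, vs the enumeration oracle."""
        specs = self._specs(8, block=1)
        G = simulate_genotypes(specs, 30_000, 8, block_rho=0.95)
        ps = [1e-20, 1e-15, 1e-12, 1e-10, 1e-9, 1e-14, 1e-13, 1e-11]
        assocs = self._frame(specs, ps, G)
        leads = select_leads(assocs, G, [s.id for s in specs])
        order = np.argsort(ps)
        R2 = np.corrcoef(G.astype(float).T) ** 2

        def ok(i, k):
            if abs(specs[i].pos - specs[k].pos) > 1_000_000:
                return True
            return R2[i, k] < 0.2

        expect = sorted(f"v{j}" for j in greedy_oracle(list(order), ok))
        assert sorted(leads.variant_ids) == expect
        assert len(leads.variant_ids) == 4  # one from the block + 3 independents

    def test_row_order_invariance(self):
        specs = self._specs(7, block=1)
        G = simulate_genotypes(specs, 10_000, 2, block_rho=0.9)
        ps = [1e-9, 1e-11, 1e-10, 1e-12, 1e-8 / 2, 1e-13, 1e-14]
        assocs = self._frame(specs, ps, G)
        a = select_leads(assocs, G, [s.id for s in specs])
        b = select_leads(assocs.iloc[::-1].reset_index(drop=True), G, [s.id for s in specs])
        assert a.variant_ids == b.variant_ids

    def test_hwe_filter_logged(self):
        specs = self._specs(2, spacing=5_000_000)
        G = simulate_genotypes(specs, 3000, 4)
        assocs = self._frame(specs, [1e-10, 1e-9], G)
        assocs.loc[0, "hwe_p"] = 1e-9
        leads = select_leads(assocs, G, [s.id for s in specs])
        assert leads.variant_ids == ["v1"]
        assert list(leads.pruning_log["reason"]) == ["HWE"]

    def test_outside_window_not_pruned(self):
        specs = self._specs(2, spacing=2_000_000)
        G0 = simulate_genotypes(specs[:1], 3000, 5)
        G = np.column_stack([G0, G0])  # perfectly correlated but 2 Mb apart
        assocs = self._frame(specs, [1e-10, 1e-12], G)
        leads = select_leads(assocs, G, [s.id for s in specs])
        assert len(leads.retained) == 2
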