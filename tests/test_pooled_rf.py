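"""Pooled recombination-frequency model: oracles, examples and properties."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from bsamap import (
    MixingModel,
    PoolObservation,
    analyze_snv,
    estimate_rf,
    genotype_class_probs,
    improbable_ratio_test,
    pmf_G,
    read_likelihood,
    snv_log_likelihood,
)
from bsamap.pooled_rf import estimate_rf_table, log_read_likelihood_vector


def _gamete_pairing_probs(alpha, pool_class):
    """Oracle for the per-plant genotype distribution: enumerate the 16
    equiprobable gamete pairings and condition on the phenotype class.

    A gamete carries (causal allele, marker allele); with the mutant-parent
    alleles in coupling it is parental with probability 1 - alpha.
    """
    gametes = [  # (causal mutant?, marker mutant?, probability)
        (1, 1, (1 - alpha) / 2),
        (1, 0, alpha / 2),
        (0, 0, (1 - alpha) / 2),
        (0, 1, alpha / 2),
    ]
    per_copy = np.zeros(3)
    total = 0.0
    for (c1, m1, p1), (c2, m2, p2) in itertools.product(gametes, repeat=2):
        recessive = (c1 + c2) == 2
        if (pool_class == "recessive") == recessive:
            per_copy[m1 + m2] += p1 * p2
            total += p1 * p2
    return per_copy / total  # indexed by marker allele copies 0/1/2


class TestGenotypeClassProbs:
    @pytest.mark.parametrize("alpha,expected", [
        (0.0, (1.0, 0.0, 0.0)),
        (0.5, (0.25, 0.5, 0.25)),
        (0.1, (0.81, 0.18, 0.01)),
    ])
    def test_recessive_closed_form(self, alpha, expected):
        p = genotype_class_probs(alpha, "recessive")
        assert (p.p_LL, p.p_Ll, p.p_ll) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha,expected", [
        (0.0, (0.0, 2 / 3, 1 / 3)),   # no recombinants among carriers
        (0.5, (0.25, 0.5, 0.25)),     # independence
    ])
    def test_dominant_limits(self, alpha, expected):
        p = genotype_class_probs(alpha, "dominant")
        assert (p.p_LL, p.p_Ll, p.p_ll) == pytest.approx(expected)

    @pytest.mark.parametrize("pool_class", ["recessive", "dominant"])
    @pytest.mark.parametrize("alpha", [0.0, 0.05, 0.17, 0.33, 0.5])
    def test_matches_gamete_pairing_oracle(self, alpha, pool_class):
        oracle = _gamete_pairing_probs(alpha, pool_class)
        p = genotype_class_probs(alpha, pool_class).per_copy()
        np.testing.assert_allclose(p, oracle, atol=1e-12)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            genotype_class_probs(0.6, "recessive")


def _pmf_G_trinomial(n, per_copy):
    """Direct trinomial sum over (k LL-plants, h Ll-plants) with 2k + h = g."""
    p0, p1, p2 = per_copy
    out = np.zeros(2 * n + 1)
    for k in range(n + 1):
        for h in range(n - k + 1):
            g = 2 * k + h
            coef = math.factorial(n) / (
                math.factorial(k) * math.factorial(h) * math.factorial(n - k - h))
            out[g] += coef * p2**k * p1**h * p0**(n - k - h)
    return out


class TestPmfG:
    @pytest.mark.parametrize("alpha,expected", [
        (0.0, {2: 1.0}),
        (0.5, {0: 0.25, 1: 0.5, 2: 0.25}),
    ])
    def test_single_plant_recessive(self, alpha, expected):
        pmf = pmf_G(1, genotype_class_probs(alpha, "recessive"))
        for g, p in expected.items():
            assert pmf[g] == pytest.approx(p)

    def test_two_plants_recessive_alpha_01(self):
        # hand-derived: P(G=4) = 0.81^2, P(G=3) = 2 * 0.81 * 0.18
        pmf = pmf_G(2, genotype_class_probs(0.1, "recessive"))
        assert pmf[4] == pytest.approx(0.6561, abs=1e-10)
        assert pmf[3] == pytest.approx(0.2916, abs=1e-10)

    @pytest.mark.parametrize("pool_class", ["recessive", "dominant"])
    @pytest.mark.parametrize("n", [1, 2, 5])
    def test_convolution_equals_trinomial_sum(self, n, pool_class):
        probs = genotype_class_probs(0.23, pool_class)
        np.testing.assert_allclose(
            pmf_G(n, probs), _pmf_G_trinomial(n, probs.per_copy()), atol=1e-10)

    @given(alpha=st.floats(0.0, 0.5), n=st.integers(1, 8),
           cls=st.sampled_from(["recessive", "dominant"]))
    @settings(max_examples=60, deadline=None)
    def test_normalisation(self, alpha, n, cls):
        pmf = pmf_G(n, genotype_class_probs(alpha, cls))
        assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
        assert (pmf >= -1e-15).all()


class TestReadLikelihood:
    def test_boundary_G_point_mass(self):
        assert read_likelihood(100, 100, 10, 5) == 1.0
        assert read_likelihood(99, 100, 10, 5) == 0.0
        assert read_likelihood(0, 50, 0, 5) == 1.0
        assert read_likelihood(1, 50, 0, 5) == 0.0

    def test_large_xi_converges_to_binomial(self):
        # Gamma concentrates at G/(2n) = 0.5
        val = read_likelihood(5, 10, 5, 5, MixingModel(xi=1e6))
        assert val == pytest.approx(binom.pmf(5, 10, 0.5), abs=1e-3)

    @pytest.mark.parametrize("G", range(11))
    def test_single_read_probability_is_beta_mean(self, G):
        # with c = 1, P(m=1) = E[Gamma] = G/(2n) for any xi
        assert read_likelihood(1, 1, G, 5, MixingModel(xi=3.7)) == pytest.approx(
            G / 10, abs=1e-12)

    @given(n=st.integers(1, 4), c=st.integers(0, 30),
           xi=st.floats(0.5, 50), data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_normalisation_over_reads(self, n, c, xi, data):
        G = data.draw(st.integers(0, 2 * n))
        total = sum(read_likelihood(m, c, G, n, MixingModel(xi=xi))
                    for m in range(c + 1))
        assert total == pytest.approx(1.0, abs=1e-9)


def _enumeration_oracle(alpha, pools, xi):
    """Exhaustive 3^n oracle: sum over every pool genotype configuration."""
    total = 0.0
    for p in pools:
        per = genotype_class_probs(alpha, p.phenotype_class).per_copy()
        prob_m = 0.0
        for config in itertools.product(range(3), repeat=p.n):
            w = np.prod([per[g] for g in config])
            G = sum(config)
            prob_m += w * read_likelihood(p.m, p.c, G, p.n, MixingModel(xi=xi))
        total += math.log(prob_m) if prob_m > 0 else -math.inf
    return total


class TestSnvLogLikelihood:
    def test_perfect_linkage_is_certain(self):
        pools = [PoolObservation("M1", "recessive", 5, 80, 80)]
        assert snv_log_likelihood(0.0, pools) == pytest.approx(0.0, abs=1e-12)

    def test_single_plant_single_read_hand_sum(self):
        # P = (1-a)^2 * 1 + 2a(1-a) * 0.5 + a^2 * 0 = (1-a)^2 + a(1-a)
        pools = [PoolObservation("M1", "recessive", 1, 1, 1)]
        assert snv_log_likelihood(0.1, pools) == pytest.approx(
            math.log(0.9), abs=1e-12)

    @pytest.mark.parametrize("n,pools_spec", [
        (2, [("M1", "recessive", 2, 15, 20), ("W1", "dominant", 2, 7, 20)]),
        (3, [("M1", "recessive", 3, 28, 30)]),
        (4, [("M1", "recessive", 4, 35, 40), ("M2", "recessive", 4, 40, 40)]),
    ])
    @pytest.mark.parametrize("alpha", [0.0, 0.07, 0.3, 0.5])
    def test_matches_exhaustive_enumeration(self, n, pools_spec, alpha):
        pools = [PoolObservation(*s) for s in pools_spec]
        xi = 10.0
        ours = snv_log_likelihood(alpha, pools, xi)
        oracle = _enumeration_oracle(alpha, pools, xi)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_monotone_decreasing_for_fully_linked_counts(self):
        pools = [PoolObservation(f"M{i}", "recessive", 5, 100, 100)
                 for i in range(4)]
        grid = np.linspace(0.001, 0.5, 200)
        vals = [snv_log_likelihood(a, pools) for a in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestEstimateRf:
    def test_complete_linkage_counts(self):
        pools = ([PoolObservation(f"M{i}", "recessive", 5, 100, 100)
                  for i in range(4)]
                 + [PoolObservation(f"W{i}", "dominant", 6, 40, 120)
                    for i in range(2)])
        est = estimate_rf(pools)
        assert est.alpha_hat == 0.0
        assert est.ci[0] == 0.0
        assert est.lod > 3

    def test_independence_counts(self):
        # recessive pools at m/c = 1/2 and dominant at 1/2: exactly the
        # alpha = 0.5 expectation
        pools = ([PoolObservation(f"M{i}", "recessive", 5, 50, 100)
                  for i in range(4)]
                 + [PoolObservation("W1", "dominant", 6, 60, 120)])
        est = estimate_rf(pools)
        assert est.alpha_hat == pytest.approx(0.5, abs=1e-6)
        assert est.lod == pytest.approx(0.0, abs=1e-6)

    def test_pool_order_invariance(self):
        pools = [PoolObservation("M1", "recessive", 5, 93, 100),
                 PoolObservation("M2", "recessive", 5, 100, 100),
                 PoolObservation("W1", "dominant", 6, 45, 120)]
        a = estimate_rf(pools).alpha_hat
        b = estimate_rf(pools[::-1]).alpha_hat
        assert a == pytest.approx(b, abs=1e-9)

    def test_zero_coverage_pool_is_inert(self):
        pools = [PoolObservation("M1", "recessive", 5, 93, 100),
                 PoolObservation("W1", "dominant", 6, 45, 120)]
        with_dummy = pools + [PoolObservation("M9", "recessive", 5, 0, 0)]
        assert estimate_rf(pools).alpha_hat == pytest.approx(
            estimate_rf(with_dummy).alpha_hat, abs=1e-6)

    def test_all_zero_coverage_flagged_undefined(self):
        est = estimate_rf([PoolObservation("M1", "recessive", 5, 0, 0)])
        assert not est.defined
        assert math.isnan(est.alpha_hat)

    def test_ci_contains_estimate_and_respects_bounds(self):
        pools = [PoolObservation(f"M{i}", "recessive", 5, 88 + i, 100)
                 for i in range(4)]
        est = estimate_rf(pools)
        assert 0.0 <= est.ci[0] <= est.alpha_hat <= est.ci[1] <= 0.5


class TestImprobableRatioTest:
    def test_contradictory_pools_excluded(self):
        # one all-wild-type pool among fully-linked pools: no alpha can
        # reconcile a recessive pool with m = 0 alongside m = c pools
        pools = ([PoolObservation("M1", "recessive", 5, 0, 200)]
                 + [PoolObservation(f"M{i}", "recessive", 5, 200, 200)
                    for i in (2, 3, 4)])
        excluded, tails = improbable_ratio_test(pools)
        assert excluded
        assert tails["M1"] < 1e-3

    def test_expected_counts_not_excluded(self):
        alpha = 0.1
        m = round(100 * (1 - alpha))
        pools = [PoolObservation(f"M{i}", "recessive", 5, m, 100)
                 for i in range(4)]
        excluded, tails = improbable_ratio_test(pools)
        assert not excluded
        assert all(t > 1e-3 for t in tails.values())

    def test_analyze_snv_attaches_flag_and_tails(self):
        pools = [PoolObservation("M1", "recessive", 5, 95, 100),
                 PoolObservation("W1", "dominant", 6, 40, 120)]
        est = analyze_snv(pools)
        assert est.excluded is False
        assert set(est.pool_tails) == {"M1", "W1"}


class TestEstimateRfTable:
    def test_sorted_ascending_with_lod_tiebreak(self):
        import pandas as pd

        rows = []
        for snv, m in [("near", 100), ("mid", 90), ("far", 55)]:
            for i in range(4):
                rows.append((snv, f"M{i}", "recessive", 5, m, 100))
        counts = pd.DataFrame(
            rows, columns=["snv_id", "pool_id", "phenotype_class", "n", "m", "c"])
        out = estimate_rf_table(counts)
        assert list(out["snv_id"]) == ["near", "mid", "far"]
        assert out["alpha_hat"].is_monotonic_increasing

    def test_missing_column_raises(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing columns"):
            estimate_rf_table(pd.DataFrame({"snv_id": []}))
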