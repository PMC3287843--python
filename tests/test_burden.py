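"""Unit and oracle tests for the four burden tests and the permutation engine."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rvbench.burden import (
    PermutationPlan,
    cmat_statistic,
    cmat_stratified,
    cmc_collapse,
    hotelling_t2,
    permute_p,
    pr_statistic,
    run_gene,
    ws_statistic,
)


# ---------------------------------------------------------------------------
# CMC
# ---------------------------------------------------------------------------


class TestCmcCollapse:
    def test_mixed_mafs_two_columns(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, (10, 3))
        design = cmc_collapse(calls, [0.005, 0.002, 0.03])
        assert design.shape == (10, 2)
        np.testing.assert_array_equal(design[:, 0], calls[:, :2].max(axis=1))
        np.testing.assert_array_equal(design[:, 1], calls[:, 2])

    def test_all_rare_single_indicator(self):
        calls = np.array([[0, 0], [1, 0], [1, 1]])
        design = cmc_collapse(calls, [0.005, 0.001])
        np.testing.assert_array_equal(design, [[0], [1], [1]])

    def test_no_rare_identity(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, (8, 3))
        design = cmc_collapse(calls, [0.02, 0.03, 0.4])
        np.testing.assert_array_equal(design, calls.astype(float))


class TestHotelling:
    def test_identical_means_zero(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        t2, p, _, status = hotelling_t2(X, X)
        assert t2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_k1_equals_squared_pooled_t(self):
        """For one column, T^2 must equal the squared two-sample t."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            x1 = rng.integers(0, 2, rng.integers(4, 20)).astype(float)
            x2 = rng.integers(0, 2, rng.integers(4, 20)).astype(float)
            if x1.var() == 0 and x2.var() == 0:
                continue
            t, p_t = stats.ttest_ind(x1, x2, equal_var=True)
            t2, p_f, _, status = hotelling_t2(x1[:, None], x2[:, None])
            assert t2 == pytest.approx(t**2, rel=1e-12)
            assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_zero_pooled_variance_degenerate(self):
        cases = np.ones((3, 1))
        controls = np.zeros((3, 1))
        _, p, _, status = hotelling_t2(cases, controls)
        assert status == "degenerate" and p == 1.0

    def test_too_many_columns_degenerate(self):
        rng = np.random.default_rng(2)
        cases = rng.random((3, 8))
        controls = rng.random((3, 8))
        *_, status = hotelling_t2(cases, controls)
        assert status == "degenerate"


# ---------------------------------------------------------------------------
# WS
# ---------------------------------------------------------------------------


class TestWeightedSum:
    def test_all_zero_calls_gives_midrank_sum(self):
        calls = np.zeros((6, 2))
        pheno = np.array([1, 1, 0, 0, 0, 1])
        # all scores tie -> every rank is (n+1)/2
        assert ws_statistic(calls, pheno) == pytest.approx(3 * 7 / 2)

    def test_affected_only_carrier_maximal(self):
        pheno = np.array([1, 1, 0, 0, 0, 0])
        calls = np.array([[1], [1], [0], [0], [0], [0]])
        x = ws_statistic(calls, pheno)
        assert x == pytest.approx(5 + 6)  # affected occupy the top ranks

    def test_weight_formula_hand_computed(self):
        """One SNP, one unaffected carrier of four unaffected: q = 2/10."""
        pheno = np.array([1, 0, 0, 0, 0])
        calls = np.array([[1], [1], [0], [0], [0]])
        n = 5
        q = (1 + 1) / (2 * (4 + 1))
        w = np.sqrt(n * q * (1 - q))
        scores = calls[:, 0] / w
        ranks = stats.rankdata(scores)
        assert ws_statistic(calls, pheno) == pytest.approx(ranks[0])
        assert q == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# PR
# ---------------------------------------------------------------------------


class TestProportionRegression:
    def test_predictor_is_site_fraction(self):
        from rvbench.burden import pr_predictor

        calls = np.array([[1, 0, 0, 0]])
        assert pr_predictor(calls)[0] == pytest.approx(0.25)

    def test_constant_predictor_degenerate(self):
        calls = np.ones((6, 2))
        pheno = np.array([1, 0, 1, 0, 1, 0])
        z, p, status = pr_statistic(calls, pheno)
        assert status == "degenerate" and p == 1.0

    def test_orthogonal_predictor_flat_slope(self):
        """Balanced design where x carries no signal: slope ~ 0, p ~ 1.

        Cross-checked against a likelihood grid search over the slope.
        """
        # x in {0, 0.5}; each x value has one case and one control
        calls = np.array([[0, 0], [0, 0], [1, 0], [1, 0]])
        pheno = np.array([1, 0, 1, 0])
        z, p, status = pr_statistic(calls, pheno)
        assert status == "ok"
        assert abs(z) < 1e-6
        assert p == pytest.approx(1.0, abs=1e-6)
        # independent oracle: profile log-likelihood over slope grid
        x = calls.mean(axis=1)
        slopes = np.linspace(-5, 5, 2001)

        def loglik(b1):
            b0 = np.linspace(-5, 5, 401)
            eta = b0[:, None] + b1 * x[None, :]
            ll = (pheno * eta - np.log1p(np.exp(eta))).sum(axis=1)
            return ll.max()

        lls = np.array([loglik(b) for b in slopes])
        assert abs(slopes[np.argmax(lls)]) <= 0.01

    def test_strong_signal_small_p(self):
        n = 60
        pheno = np.array([1] * 30 + [0] * 30)
        calls = np.zeros((n, 2), dtype=int)
        calls[:20, 0] = 1  # 20 of 30 cases carry
        calls[30:35, 0] = 1  # 5 of 30 controls carry
        z, p, status = pr_statistic(calls, pheno)
        assert status == "ok" and p < 0.01 and z > 0

    def test_quasi_separation_degenerate(self):
        # every carrier is a case: slope diverges under IRLS
        pheno = np.array([1] * 5 + [0] * 5)
        calls = np.array([[1]] * 5 + [[0]] * 5)
        z, p, status = pr_statistic(calls, pheno)
        assert status == "degenerate" and p == 1.0


# ---------------------------------------------------------------------------
# CMAT
# ---------------------------------------------------------------------------


class TestCmat:
    def test_no_rare_alleles_zero(self):
        calls = np.zeros((4, 3))
        pheno = np.array([1, 1, 0, 0])
        assert cmat_statistic(calls, pheno) == 0.0

    def test_table_oracle(self):
        """10 cases, 10 controls, 5 loci, a=8, b=2 -> [[8,42],[2,48]]."""
        calls = np.zeros((20, 5), dtype=int)
        # 8 carried loci among cases, 2 among controls
        calls[0, :5] = 1
        calls[1, :3] = 1
        calls[10, :2] = 1
        pheno = np.array([1] * 10 + [0] * 10)
        chi2 = cmat_statistic(calls, pheno)
        obs = np.array([[8, 42], [2, 48]], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        oracle = ((obs - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(oracle, rel=1e-12)
        sp = stats.chi2_contingency(obs, correction=False)
        assert chi2 == pytest.approx(sp.statistic, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_label_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        calls = rng.integers(0, 2, (n, int(rng.integers(1, 4))))
        pheno = np.zeros(n, dtype=int)
        pheno[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if pheno.all() or not pheno.any():
            return
        assert cmat_statistic(calls, pheno) == pytest.approx(
            cmat_statistic(calls, 1 - pheno), rel=1e-12
        )


class TestCmatStratified:
    def test_single_stratum_matches_unstratified_p(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 2, (12, 3))
        pheno = np.array([1, 0] * 6)
        strata = np.array(["s1"] * 12)
        plan = PermutationPlan(B=300, seed=4)
        out_plain = run_gene("CMAT", calls, [0.01] * 3, pheno, plan=plan)
        out_strat = run_gene("CMAT_STRAT", calls, [0.01] * 3, pheno,
                             strata=strata, plan=plan)
        assert out_strat.p_value == pytest.approx(out_plain.p_value)

    def test_no_within_stratum_effect_cancels(self):
        """Each stratum's case carrier rate equals its overall rate, so
        a_s = E_s in both strata and the pooled statistic vanishes, while
        the marginal (unstratified) 2x2 still shows association."""
        # stratum 1: 4 ind, 2 cases, 2 carriers; cases carry exactly 1
        s1_calls = [[1], [0], [1], [0]]
        s1_pheno = [1, 1, 0, 0]
        # stratum 2: 12 ind, 8 cases, 9 carriers; cases carry exactly 6
        s2_calls = [[1]] * 6 + [[0]] * 2 + [[1]] * 3 + [[0]]
        s2_pheno = [1] * 8 + [0] * 4
        calls = np.array(s1_calls + s2_calls)
        pheno = np.array(s1_pheno + s2_pheno)
        strata = np.array(["s1"] * 4 + ["s2"] * 12)
        stat, usable, status = cmat_stratified(calls, pheno, strata)
        assert status == "ok" and usable == ["s1", "s2"]
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert cmat_statistic(calls, pheno) > 0.0

    def test_hypergeom_moments_match_enumeration(self):
        """Pooled-statistic E_s, V_s match brute-force enumeration."""
        calls = np.array([[1, 1], [1, 0], [0, 0], [0, 0], [1, 0], [0, 0]])
        pheno = np.array([1, 0, 1, 0, 1, 0])
        strata = np.array(["s1"] * 6)
        loci = 2
        burden = calls.sum(axis=1)
        n_case = 3
        # enumerate all case assignments: distribution of a = carried loci in cases
        a_vals = [
            burden[list(comb)].sum()
            for comb in itertools.combinations(range(6), n_case)
        ]
        a_vals = np.array(a_vals, dtype=float)
        A = loci * n_case
        N = loci * 6
        t = burden.sum()
        E = A * t / N
        V = A * (N - A) * t * (N - t) / (N**2 * (N - 1))
        assert a_vals.mean() == pytest.approx(E)
        # hypergeometric variance is exact for draws of loci slots, while a
        # is drawn per individual; enumeration mean must match E exactly
        stat, _, status = cmat_stratified(calls, pheno, strata)
        a_obs = burden[pheno == 1].sum()
        assert stat == pytest.approx((a_obs - E) ** 2 / V)

    def test_all_cases_one_stratum_degenerate(self):
        calls = np.ones((4, 1))
        pheno = np.array([1, 1, 0, 0])
        strata = np.array(["s1", "s1", "s2", "s2"])
        stat, usable, status = cmat_stratified(calls, pheno, strata)
        assert status == "degenerate" and usable == []


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


class TestPermuteP:
    def test_strict_maximum_gives_min_p(self):
        calls = np.array([[1], [1], [0], [0]])
        pheno = np.array([1, 1, 0, 0])
        count = {"v": 0}

        def stat(c, ph):
            # observed call gets a value above anything later
            count["v"] += 1
            return 1.0 if count["v"] == 1 else 0.0

        p = permute_p(stat, calls, pheno, PermutationPlan(B=19, seed=0))
        assert p == pytest.approx(1 / 20)

    def test_constant_statistic_p_one(self):
        calls = np.zeros((4, 1))
        pheno = np.array([1, 0, 1, 0])
        p = permute_p(lambda c, ph: 3.0, calls, pheno, PermutationPlan(B=50, seed=1))
        assert p == 1.0

    @pytest.mark.parametrize("statistic", [cmat_statistic, ws_statistic])
    def test_exhaustive_enumeration_oracle(self, statistic):
        """MC permutation p converges to the exact label-arrangement p."""
        rng = np.random.default_rng(21)
        calls = rng.integers(0, 2, (6, 2))
        pheno = np.array([1, 1, 1, 0, 0, 0])
        observed = statistic(calls, pheno)
        exact_ge = 0
        arrangements = list(itertools.combinations(range(6), 3))
        for comb in arrangements:
            ph = np.zeros(6, dtype=int)
            ph[list(comb)] = 1
            if statistic(calls, ph) >= observed - 1e-12:
                exact_ge += 1
        p_exact = exact_ge / len(arrangements)
        B = 20_000
        p_mc = permute_p(statistic, calls, pheno, PermutationPlan(B=B, seed=2))
        se = np.sqrt(p_exact * (1 - p_exact) / B)
        assert p_mc == pytest.approx(p_exact, abs=max(3 * se, 2 / B))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 30))
    def test_p_bounds(self, seed, B):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 2, (6, 2))
        pheno = np.array([1, 0, 1, 0, 1, 0])
        p = permute_p(cmat_statistic, calls, pheno, PermutationPlan(B=B, seed=seed))
        assert 1 / (B + 1) <= p <= 1.0


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


class TestRunGene:
    def test_unknown_method_errors(self):
        with pytest.raises(ValueError, match="method"):
            run_gene("XX", np.zeros((4, 1)), [0.01], np.array([1, 0, 1, 0]))

    def test_cmc_single_snp_k1(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, (30, 1))
        pheno = np.array([1, 0] * 15)
        out = run_gene("CMC", calls, [0.02], pheno)
        assert out.method == "CMC" and out.df_or_B == 1

    def test_ws_p_on_permutation_lattice(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 2, (20, 2))
        pheno = np.array([1, 0] * 10)
        out = run_gene("WS", calls, [0.01, 0.02], pheno, plan=PermutationPlan(B=1000, seed=5))
        k = round(out.p_value * 1001)
        assert 1 <= k <= 1001 and out.p_value == pytest.approx(k / 1001)

    def test_determinism(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 2, (20, 3))
        pheno = np.array([1, 0] * 10)
        plan = PermutationPlan(B=200, seed=77)
        a = run_gene("CMAT", calls, [0.01] * 3, pheno, plan=plan)
        b = run_gene("CMAT", calls, [0.01] * 3, pheno, plan=plan)
        assert a == b

    def test_constant_phenotype_degenerate(self):
        calls = np.ones((4, 1))
        out = run_gene("WS", calls, [0.01], np.array([1, 1, 1, 1]))
        assert out.status == "degenerate" and out.p_value == 1.0
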