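"""Design-effect formulas, allocation-level forms and the matrix oracle."""

from itertools import combinations_with_replacement

import numpy as np
import pytest

from partclus import (
    AllocationTable,
    ClusterSizeDistribution,
    ConfigurationError,
    DesignSpec,
    deff_closed_form,
    deff_expected_individual,
    deff_general_exchangeable,
    deff_general_independence,
    deff_matrix_oracle,
    expected_allocation_weights,
    h_term,
)


def spec(rand, working, outcome="continuous", rho=0.5, link=None, pi_i=None, pi_c=None):
    return DesignSpec(
        randomization=rand,
        working_correlation=working,
        outcome=outcome,
        rho=rho,
        link=link,
        pi_i=pi_i,
        pi_c=pi_c,
    )


class TestHTerm:
    def test_equal_prevalences(self):
        assert h_term(0.3, 0.3) == pytest.approx(0.5, abs=1e-12)

    def test_complementary_prevalences(self):
        assert h_term(0.7, 0.3) == pytest.approx(0.5, abs=1e-12)

    def test_reference_value(self):
        # sqrt(0.3*0.4*0.7*0.6) / 0.45
        assert h_term(0.3, 0.4) == pytest.approx(np.sqrt(0.0504) / 0.45, rel=1e-12)
        assert h_term(0.3, 0.4) == pytest.approx(0.49889, abs=5e-6)

    def test_log_link_denominator(self):
        assert h_term(0.3, 0.4, link="log") == pytest.approx(np.sqrt(0.0504) / 0.46, rel=1e-12)

    def test_range(self):
        for pi_i in (0.05, 0.3, 0.6, 0.95):
            for pi_c in (0.05, 0.4, 0.9):
                assert 0.0 < h_term(pi_i, pi_c) <= 0.5 + 1e-12

    def test_boundary_rejected(self):
        with pytest.raises(ConfigurationError):
            h_term(0.0, 0.4)


class TestClosedForm:
    def test_cluster_independence_neonatal(self, dist_neonatal):
        value = deff_closed_form(spec("cluster", "independence"), dist_neonatal)
        assert value == pytest.approx(1.175, abs=1e-12)
        assert round(value, 2) == 1.18

    def test_individual_exchangeable_rerand(self, dist_rerand):
        value = deff_closed_form(spec("individual", "exchangeable"), dist_rerand)
        assert round(value, 2) == 0.73

    def test_cluster_exchangeable_equal_high_icc(self, dist_equal):
        value = deff_closed_form(spec("cluster", "exchangeable", rho=0.8), dist_equal)
        assert round(value, 2) == 2.25

    @pytest.mark.parametrize("rand", ["cluster", "individual"])
    @pytest.mark.parametrize("working", ["independence", "exchangeable"])
    def test_rho_zero_gives_one(self, rand, working, dist_unequal):
        assert deff_closed_form(spec(rand, working, rho=0.0), dist_unequal) == pytest.approx(
            1.0, abs=1e-12
        )
        binary = spec(rand, working, outcome="binary", rho=0.0, pi_i=0.3, pi_c=0.4)
        assert deff_closed_form(binary, dist_unequal) == pytest.approx(1.0, abs=1e-12)

    def test_all_singletons_gives_one(self):
        d = ClusterSizeDistribution.from_gamma([1.0])
        for rand in ("cluster", "individual"):
            for working in ("independence", "exchangeable"):
                assert deff_closed_form(spec(rand, working, rho=0.6), d) == pytest.approx(
                    1.0, abs=1e-12
                )

    def test_binary_cluster_equals_continuous(self, dist_unequal):
        for working in ("independence", "exchangeable"):
            cont = deff_closed_form(spec("cluster", working, rho=0.3), dist_unequal)
            binary = deff_closed_form(
                spec("cluster", working, outcome="binary", rho=0.3, pi_i=0.25, pi_c=0.45),
                dist_unequal,
            )
            assert binary == pytest.approx(cont, rel=1e-12)

    def test_binary_equals_continuous_when_h_half(self, dist_equal):
        # pi_i == pi_c makes the h-term 1/2 and the forms coincide exactly
        for working in ("independence", "exchangeable"):
            cont = deff_closed_form(spec("individual", working, rho=0.4), dist_equal)
            binary = deff_closed_form(
                spec("individual", working, outcome="binary", rho=0.4, pi_i=0.35, pi_c=0.35),
                dist_equal,
            )
            assert binary == pytest.approx(cont, rel=1e-12)

    def test_cluster_independence_dominates_exchangeable(self, dist_unequal):
        gap_prev = 0.0
        for rho in np.linspace(0.05, 0.95, 10):
            ind = deff_closed_form(spec("cluster", "independence", rho=rho), dist_unequal)
            exch = deff_closed_form(spec("cluster", "exchangeable", rho=rho), dist_unequal)
            assert ind >= exch
            assert ind - exch > gap_prev  # difference grows with the ICC
            gap_prev = ind - exch

    def test_individual_exchangeable_below_one_decreasing(self, dist_equal):
        prev = 1.0
        for rho in np.linspace(0.05, 0.9, 8):
            val = deff_closed_form(spec("individual", "exchangeable", rho=rho), dist_equal)
            assert val <= 1.0
            assert val < prev
            prev = val

    def test_exchangeable_rejects_rho_one(self, dist_unequal):
        with pytest.raises(ConfigurationError):
            deff_closed_form(spec("cluster", "exchangeable", rho=1.0), dist_unequal)

    def test_negative_rho_rejected(self, dist_unequal):
        with pytest.raises(ConfigurationError):
            deff_closed_form(spec("cluster", "independence", rho=-0.2), dist_unequal)

    def test_binary_requires_prevalences(self):
        with pytest.raises(ConfigurationError):
            DesignSpec("individual", "independence", "binary", 0.5)


class TestExpectedAllocationWeights:
    def test_pairs(self):
        np.testing.assert_allclose(expected_allocation_weights(2), [0.25, 0.5, 0.25])

    def test_singleton(self):
        np.testing.assert_allclose(expected_allocation_weights(1), [0.5, 0.5])

    def test_size_four(self):
        np.testing.assert_allclose(
            expected_allocation_weights(4), np.array([1, 4, 6, 4, 1]) / 16.0
        )

    @pytest.mark.parametrize("k", range(1, 8))
    def test_sums_to_one(self, k):
        assert expected_allocation_weights(k).sum() == pytest.approx(1.0, abs=1e-12)


class TestGeneralForms:
    def test_independence_all_singletons(self):
        alloc = AllocationTable(n=np.ones(10, dtype=int), t=np.array([1] * 5 + [0] * 5))
        for rho in (0.0, 0.3, 0.9):
            assert deff_general_independence(alloc, rho) == pytest.approx(1.0, abs=1e-12)

    def test_independence_two_opposite_pairs(self):
        alloc = AllocationTable(n=np.array([2, 2]), t=np.array([2, 0]))
        assert deff_general_independence(alloc, 0.5) == pytest.approx(1.5, abs=1e-12)

    def test_exchangeable_all_singletons(self):
        alloc = AllocationTable(n=np.ones(8, dtype=int), t=np.array([1, 0] * 4))
        for rho in (0.0, 0.4, 0.8):
            assert deff_general_exchangeable(alloc, rho) == pytest.approx(1.0, abs=1e-12)

    def test_cluster_randomized_match_closed_forms(self, dist_unequal):
        # balanced cluster-randomised allocation: half the clusters of each
        # size on each arm reproduces the Table 1 cluster forms exactly
        counts = np.array([280, 60, 40, 20])
        sizes = np.repeat([1, 2, 3, 4], counts)
        treat = np.concatenate([np.tile([1, 0], c // 2) for c in counts])
        alloc = AllocationTable(n=sizes, t=sizes * np.repeat(treat, 1))
        for rho in (0.2, 0.8):
            ind = deff_general_independence(alloc, rho)
            exch = deff_general_exchangeable(alloc, rho)
            assert ind == pytest.approx(
                deff_closed_form(spec("cluster", "independence", rho=rho), dist_unequal),
                rel=1e-12,
            )
            assert exch == pytest.approx(
                deff_closed_form(spec("cluster", "exchangeable", rho=rho), dist_unequal),
                rel=1e-12,
            )

    def test_table3_cluster_values(self, dist_equal, dist_unequal):
        counts_eq = np.repeat([60], 4)
        sizes = np.repeat([1, 2, 3, 4], counts_eq)
        treat = np.concatenate([np.tile([1, 0], 30) for _ in range(4)])
        alloc = AllocationTable(n=sizes, t=sizes * treat)
        assert round(deff_general_exchangeable(alloc, 0.8), 2) == 2.25
        counts_un = np.array([280, 60, 40, 20])
        sizes = np.repeat([1, 2, 3, 4], counts_un)
        treat = np.concatenate([np.tile([1, 0], c // 2) for c in counts_un])
        alloc = AllocationTable(n=sizes, t=sizes * treat)
        assert round(deff_general_independence(alloc, 0.2), 2) == 1.20


def _balanced_allocations(max_m=4, max_k=3):
    """All multisets of (n, t) clusters with both arms present and N_I == N_C."""
    pairs = [(n, t) for n in range(1, max_k + 1) for t in range(n + 1)]
    for m in range(1, max_m + 1):
        for combo in combinations_with_replacement(pairs, m):
            n = np.array([p[0] for p in combo])
            t = np.array([p[1] for p in combo])
            c = n - t
            if t.sum() == 0 or c.sum() == 0 or t.sum() != c.sum():
                continue
            yield AllocationTable(n=n, t=t)


class TestMatrixOracle:
    @pytest.mark.parametrize("rho", [0.2, 0.8])
    def test_general_forms_equal_oracle(self, rho):
        for alloc in _balanced_allocations(max_m=4, max_k=3):
            ind = deff_matrix_oracle(alloc, spec("cluster", "independence", rho=rho))
            assert ind == pytest.approx(deff_general_independence(alloc, rho), abs=1e-10)
            exch = deff_matrix_oracle(alloc, spec("cluster", "exchangeable", rho=rho))
            assert exch == pytest.approx(deff_general_exchangeable(alloc, rho), abs=1e-10)

    def test_exchangeable_rho_zero_is_independence(self):
        alloc = AllocationTable(n=np.array([3, 2, 1, 2]), t=np.array([2, 0, 1, 1]))
        a = deff_matrix_oracle(alloc, spec("individual", "exchangeable", rho=0.0))
        b = deff_matrix_oracle(alloc, spec("individual", "independence", rho=0.0))
        assert a == pytest.approx(b, abs=1e-12)

    def test_binary_equal_prevalence_matches_continuous(self):
        alloc = AllocationTable(n=np.array([3, 2, 1, 2]), t=np.array([2, 0, 1, 1]))
        for working in ("independence", "exchangeable"):
            cont = deff_matrix_oracle(alloc, spec("individual", working, rho=0.4))
            binary = deff_matrix_oracle(
                alloc,
                spec("individual", working, outcome="binary", rho=0.4, pi_i=0.3, pi_c=0.3),
            )
            assert binary == pytest.approx(cont, abs=1e-10)

    def test_negative_rho_accepted_within_bound(self):
        alloc = AllocationTable(n=np.array([2, 2]), t=np.array([2, 0]))
        val = deff_matrix_oracle(alloc, spec("cluster", "independence", rho=-0.4))
        assert val == pytest.approx(1.0 - 0.4, abs=1e-10)

    def test_oracle_beyond_pd_bound_rejected(self):
        alloc = AllocationTable(n=np.array([4, 4]), t=np.array([4, 0]))
        with pytest.raises(ConfigurationError):
            deff_matrix_oracle(alloc, spec("cluster", "independence", rho=-0.5))


class TestExpectedIndividualMixture:
    """Closed forms equal the expected-proportions mixture of oracle matrices."""

    @pytest.mark.parametrize("working", ["independence", "exchangeable"])
    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
    def test_continuous(self, working, rho, dist_unequal, dist_equal, dist_rerand):
        for dist in (dist_unequal, dist_equal, dist_rerand):
            closed = deff_closed_form(spec("individual", working, rho=rho), dist)
            mixture = deff_expected_individual(spec("individual", working, rho=rho), dist)
            assert closed == pytest.approx(mixture, abs=1e-8)

    @pytest.mark.parametrize("working", ["independence", "exchangeable"])
    @pytest.mark.parametrize("link", ["logit", "log"])
    @pytest.mark.parametrize("rho", [0.2, 0.8])
    def test_binary(self, working, link, rho, dist_unequal, dist_equal):
        for dist in (dist_unequal, dist_equal):
            s = spec("individual", working, outcome="binary", rho=rho, link=link, pi_i=0.3, pi_c=0.4)
            assert deff_closed_form(s, dist) == pytest.approx(
                deff_expected_individual(s, dist), abs=1e-8
            )

    def test_pairs_reduce_to_size_two_forms(self):
        # K = 2 sanity: mixture equals closed form for a twin/singleton mix
        dist = ClusterSizeDistribution.from_gamma([0.737, 0.263])
        for working in ("independence", "exchangeable"):
            s = spec("individual", working, rho=0.5)
            assert deff_closed_form(s, dist) == pytest.approx(
                deff_expected_individual(s, dist), abs=1e-10
            )
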