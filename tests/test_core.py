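import numpy as np
import pytest
from hypothesis import given, strategies as st

from sparcc import (
    CountTable,
    FractionTable,
    VariationMatrix,
    baseline_correlations,
    basis_correlations,
    component_variation,
    sample_posterior_fractions,
    solve_basis_variances,
    sparcc_estimate,
    sparcc_iterative,
    variation_matrix,
)
from sparcc.core import BasisVariances, _basic_estimate


def _fractions(abund):
    abund = np.asarray(abund, dtype=float)
    return FractionTable(abund / abund.sum(axis=1, keepdims=True))


class TestVariationMatrix:
    def test_constant_ratio_gives_zero_entry(self, rng):
        # proportional components have constant log-ratio, hence zero variance
        base = np.exp(rng.standard_normal((20, 3)))
        abund = np.column_stack([base, 2.0 * base[:, 0]])
        T = variation_matrix(_fractions(abund))
        assert T.t[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_identical_samples_give_zero_matrix(self):
        f = FractionTable(np.tile([0.2, 0.3, 0.5], (4, 1)))
        np.testing.assert_allclose(variation_matrix(f).t, 0.0, atol=1e-12)

    def test_two_sample_hand_value(self):
        # log-ratios are (0, ln 4); unbiased two-point variance (ln 4)^2 / 2
        f = FractionTable(np.array([[0.5, 0.5], [0.8, 0.2]]))
        T = variation_matrix(f)
        assert T.t[0, 1] == pytest.approx(np.log(4) ** 2 / 2, rel=1e-12)

    def test_uses_unbiased_divisor(self, random_fractions):
        T = variation_matrix(random_fractions)
        logf = np.log(random_fractions.fractions)
        manual = np.var(logf[:, 0] - logf[:, 1], ddof=1)
        assert T.t[0, 1] == pytest.approx(manual, rel=1e-12)

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError):
            variation_matrix(FractionTable(np.array([[0.5, 0.5]])))

    @given(st.integers(min_value=0, max_value=5))
    def test_subcompositional_coherence(self, drop):
        # t_ij for a retained pair is unchanged by dropping any third component
        rng = np.random.default_rng(42)
        abund = np.exp(rng.standard_normal((30, 6)))
        full = variation_matrix(_fractions(abund)).t
        keep = [k for k in range(6) if k != drop]
        sub = variation_matrix(_fractions(abund[:, keep])).t
        np.testing.assert_allclose(
            sub, full[np.ix_(keep, keep)], rtol=1e-10, atol=1e-12
        )

    def test_per_sample_scaling_invariance(self, rng):
        # multiplying a sample's counts by a constant does not move fractions
        abund = np.exp(rng.standard_normal((15, 5)))
        scaled = abund * rng.uniform(0.5, 20.0, size=(15, 1))
        np.testing.assert_allclose(
            variation_matrix(_fractions(abund)).t,
            variation_matrix(_fractions(scaled)).t,
            rtol=1e-10, atol=1e-12,
        )


class TestComponentVariation:
    def _uniform_T(self, D, val):
        t = np.full((D, D), float(val))
        np.fill_diagonal(t, 0.0)
        return VariationMatrix(t)

    def test_no_exclusions(self):
        t_vec, counts = component_variation(self._uniform_T(4, 2.0))
        np.testing.assert_allclose(t_vec, 6.0)
        np.testing.assert_array_equal(counts, 3)

    def test_excluded_pair_reduces_both_members(self):
        t_vec, counts = component_variation(self._uniform_T(4, 2.0), {(0, 1)})
        np.testing.assert_allclose(t_vec, [4.0, 4.0, 6.0, 6.0])
        np.testing.assert_array_equal(counts, [2, 2, 3, 3])

    def test_zero_matrix(self):
        t_vec, _ = component_variation(self._uniform_T(5, 0.0))
        np.testing.assert_allclose(t_vec, 0.0)


class TestSolveBasisVariances:
    def test_uniform_independent_case(self):
        # t_ij = 2 for all pairs is consistent with rho=0, omega^2=1
        t_vec = np.full(4, 6.0)
        v = solve_basis_variances(t_vec, np.full(4, 3), 4)
        np.testing.assert_allclose(v.omega_sq, 1.0, rtol=1e-12)

    @pytest.mark.parametrize("c", [0.5, 1.0, 3.7])
    def test_scales_linearly(self, c):
        D = 5
        t_vec = np.full(D, (D - 1) * 2 * c)
        v = solve_basis_variances(t_vec, np.full(D, D - 1), D)
        np.testing.assert_allclose(v.omega_sq, c, rtol=1e-12)

    def test_permutation_equivariance(self, rng):
        D = 6
        t_vec = rng.uniform(1, 5, D) * (D - 1)
        perm = rng.permutation(D)
        v = solve_basis_variances(t_vec, np.full(D, D - 1), D)
        vp = solve_basis_variances(t_vec[perm], np.full(D, D - 1), D)
        np.testing.assert_allclose(vp.omega_sq, v.omega_sq[perm], rtol=1e-10)

    def test_fewer_than_four_components_rejected(self):
        with pytest.raises(ValueError, match="4 components"):
            solve_basis_variances(np.full(3, 4.0), np.full(3, 2), 3)

    @pytest.mark.parametrize("D", [4, 5, 6, 7, 8])
    def test_matches_brute_force_dense_solve(self, D, rng):
        # oracle: build the linear system coefficient-by-coefficient in loops
        excl = {(0, 1)} if D > 4 else set()
        t_vec = rng.uniform(1.0, 10.0, D)
        A = np.zeros((D, D))
        for i in range(D):
            for j in range(D):
                if i == j:
                    continue
                if (min(i, j), max(i, j)) in excl:
                    continue
                A[i, i] += 1.0
                A[i, j] += 1.0
        expected = np.linalg.solve(A, t_vec)
        counts = np.diag(A).astype(int)
        got = solve_basis_variances(t_vec, counts, D, excl)
        np.testing.assert_allclose(got.omega_sq, np.clip(expected, 1e-10, None),
                                   rtol=1e-8)


class TestBasisCorrelations:
    def _T(self, t01, D=4):
        t = np.full((D, D), 2.0)
        np.fill_diagonal(t, 0.0)
        t[0, 1] = t[1, 0] = t01
        return VariationMatrix(t)

    @pytest.mark.parametrize("t01, expected", [(0.0, 1.0), (2.0, 0.0), (4.0, -1.0)])
    def test_closed_form_cases_at_unit_variance(self, t01, expected):
        corr = basis_correlations(self._T(t01), BasisVariances(np.ones(4)))
        assert corr.rho[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_raw_value_is_clipped_and_recorded(self):
        corr = basis_correlations(self._T(5.0), BasisVariances(np.ones(4)))
        assert corr.rho[0, 1] == -1.0
        assert (0, 1) in corr.clipped

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            basis_correlations(self._T(2.0), BasisVariances(np.array([0, 1, 1, 1.0])))

    def test_round_trip_recovery_on_independent_truth(self, rng):
        # noiseless T built from known omega^2 with rho = I is inverted exactly
        D = 7
        w2 = rng.uniform(0.5, 4.0, D)
        t = w2[:, None] + w2[None, :]
        np.fill_diagonal(t, 0.0)
        T = VariationMatrix(t)
        t_vec, counts = component_variation(T)
        v = solve_basis_variances(t_vec, counts, D)
        np.testing.assert_allclose(v.omega_sq, w2, rtol=1e-8)
        corr = basis_correlations(T, v)
        np.testing.assert_allclose(corr.rho, np.eye(D), atol=1e-8)


class TestIterativeSparcc:
    def test_no_strong_pairs_terminates_immediately(self, random_fractions):
        res = sparcc_iterative(random_fractions, exclusion_threshold=0.999)
        basic, _ = _basic_estimate(random_fractions.fractions)
        assert res.iterations_run == 1
        assert res.excluded_pairs == frozenset()
        assert res.excluded_components == frozenset()
        np.testing.assert_allclose(res.correlations.rho, basic.rho)

    def test_planted_pair_is_first_excluded(self):
        rng = np.random.default_rng(3)
        base = np.exp(rng.standard_normal((120, 20)))
        dup = base[:, -1] * np.exp(0.05 * rng.standard_normal(120))
        abund = np.column_stack([base, dup])
        f = _fractions(abund)
        basic, _ = _basic_estimate(f.fractions)
        mag = np.abs(basic.rho.copy())
        mag[np.tril_indices_from(mag)] = -np.inf
        oracle_pair = np.unravel_index(np.argmax(mag), mag.shape)
        res = sparcc_iterative(f, exclusion_threshold=0.1)
        assert oracle_pair == (19, 20)
        assert tuple(sorted(oracle_pair)) in res.excluded_pairs

    def test_shared_factor_exhausts_components_without_crashing(self):
        # one dominant factor makes every pair strongly correlated
        rng = np.random.default_rng(9)
        g = rng.standard_normal((60, 1))
        abund = np.exp(g + 0.01 * rng.standard_normal((60, 4)))
        res = sparcc_iterative(_fractions(abund), exclusion_threshold=0.1)
        assert res.iterations_run >= 1
        assert len(res.excluded_pairs) + len(res.excluded_components) > 0
        D = 4
        # undefined rows only for excluded components
        for c in range(D):
            row_nan = np.isnan(res.correlations.rho[c]).all()
            assert row_nan == (c in res.excluded_components)

    def test_excluded_pairs_never_reference_excluded_components(self):
        rng = np.random.default_rng(9)
        g = rng.standard_normal((60, 1))
        abund = np.exp(g + 0.05 * rng.standard_normal((60, 6)))
        res = sparcc_iterative(_fractions(abund), exclusion_threshold=0.1)
        for i, j in res.excluded_pairs:
            assert i not in res.excluded_components
            assert j not in res.excluded_components

    def test_fewer_than_four_components_rejected(self):
        f = FractionTable(np.full((5, 3), 1 / 3))
        with pytest.raises(ValueError):
            sparcc_iterative(f)


class TestSparccEstimate:
    def test_single_resample_equals_one_iterative_run(self, toy_counts):
        res = sparcc_estimate(toy_counts, n_resamples=1,
                              rng=np.random.default_rng(5))
        stream = np.random.default_rng(5).spawn(1)[0]
        f = sample_posterior_fractions(toy_counts, stream)
        direct = sparcc_iterative(f)
        np.testing.assert_allclose(res.correlations.rho, direct.correlations.rho)

    def test_seeded_determinism(self, toy_counts):
        r1 = sparcc_estimate(toy_counts, n_resamples=5, rng=11)
        r2 = sparcc_estimate(toy_counts, n_resamples=5, rng=11)
        np.testing.assert_array_equal(r1.correlations.rho, r2.correlations.rho)

    def test_output_is_valid_correlation_matrix(self, rng):
        counts = rng.integers(0, 50, size=(30, 8))
        t = CountTable(counts, [f"s{i}" for i in range(30)],
                       [f"c{j}" for j in range(8)])
        res = sparcc_estimate(t, n_resamples=10, rng=rng)
        rho = res.correlations.rho
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        finite = rho[np.isfinite(rho)]
        assert ((finite >= -1) & (finite <= 1)).all()
        assert res.spread is not None and res.spread.shape == rho.shape


class TestBaselineCorrelations:
    def test_two_component_composition_is_perfectly_anticorrelated(self, rng):
        f1 = rng.uniform(0.1, 0.9, 25)
        f = FractionTable(np.column_stack([f1, 1 - f1]))
        corr = baseline_correlations(f, "pearson")
        assert corr.rho[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_clr_rows_sum_to_zero(self, random_fractions):
        from sparcc.core import clr_transform

        z = clr_transform(random_fractions.fractions)
        np.testing.assert_allclose(z.sum(axis=1), 0.0, atol=1e-10)

    @pytest.mark.parametrize("method", ["pearson", "spearman", "clr"])
    def test_duplicated_column_has_unit_correlation(self, rng, method):
        base = np.exp(rng.standard_normal((30, 4)))
        abund = np.column_stack([base, base[:, 0]])
        corr = baseline_correlations(_fractions(abund), method)
        assert corr.rho[0, 4] == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_flagged_undefined(self, rng):
        others = np.exp(rng.standard_normal((20, 3)))
        others = 0.8 * others / others.sum(axis=1, keepdims=True)
        f = FractionTable(np.column_stack([np.full(20, 0.2), others]))
        corr = baseline_correlations(f, "pearson")
        assert np.isnan(corr.rho[0, 1])
        assert corr.rho[0, 0] == 1.0

    def test_unknown_method_rejected(self, random_fractions):
        with pytest.raises(ValueError):
            baseline_correlations(random_fractions, "kendall")
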