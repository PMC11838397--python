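import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

from scbsp import (
    DegenerateFitError,
    NullModel,
    ValidationError,
    compute_pvalues,
    compute_variance_ratio,
    fit_lognormal_null,
    permutation_null,
    run_scbsp,
)
from scbsp.neighborhoods import build_spatial_index, compute_patch_matrix
from scbsp.preprocessing import scale_expression_maxabs

from conftest import make_coords, make_expr


def line5_patches(r1=1.5, r2=3.5):
    """5 spots on a line at x = 0..4 (already rescaled), y constant."""
    coords = make_coords([[x, 0.0] for x in range(5)], rescaled=True)
    index = build_spatial_index(coords)
    return compute_patch_matrix(index, r1), compute_patch_matrix(index, r2)


class TestComputeVarianceRatio:
    def test_hand_computed_line_example(self):
        # feature [0,0,1,0,0]; small patches (R=1.5): {1},{0,2},{1,3},{2,4},{3}
        # small local means [0,.5,0,.5,0] -> var 0.06
        # big patches (R=3.5): leave-one-out sets; big local means
        # [1/3,1/4,0,1/4,1/3] -> var 27/1800 = 0.015; w=1 (single feature)
        small, big = line5_patches()
        raw = make_expr([[0, 0, 1, 0, 0]])
        scaled, _ = scale_expression_maxabs(raw)
        raw_var, weight, ratio, degen = compute_variance_ratio(raw, scaled, small, big)
        assert weight[0] == pytest.approx(1.0)  # single feature: forced
        assert raw_var[0] == pytest.approx(0.16)
        assert ratio[0] == pytest.approx(0.25, abs=1e-12)
        assert not degen[0]

    def test_identical_features_identical_triples(self):
        small, big = line5_patches()
        raw = make_expr([[0, 1, 3, 1, 0], [0, 1, 3, 1, 0]], ids=["a", "b"])
        scaled, _ = scale_expression_maxabs(raw)
        raw_var, weight, ratio, _ = compute_variance_ratio(raw, scaled, small, big)
        assert raw_var[0] == raw_var[1]
        assert weight[0] == weight[1] == 1.0
        assert ratio[0] == ratio[1]

    def test_mismatched_feature_sets_rejected(self):
        small, big = line5_patches()
        raw = make_expr([[0, 1, 3, 1, 0]], ids=["a"])
        scaled = make_expr([[0, 1, 1, 1, 0]], ids=["b"])
        with pytest.raises(ValidationError, match="different features"):
            compute_variance_ratio(raw, scaled, small, big)

    def test_weight_below_one_for_less_variable_feature(self):
        small, big = line5_patches()
        raw = make_expr([[0, 1, 3, 1, 0], [0, 0, 1, 0, 0]], ids=["a", "b"])
        scaled, _ = scale_expression_maxabs(raw)
        _, weight, _, _ = compute_variance_ratio(raw, scaled, small, big)
        assert weight[0] == 1.0 and 0 < weight[1] < 1


class TestLognormalNull:
    def test_degenerate_all_equal(self):
        with pytest.raises(DegenerateFitError, match="identical"):
            fit_lognormal_null(np.full(50, 2.0))

    def test_too_few_ratios(self):
        with pytest.raises(DegenerateFitError, match="permutation"):
            fit_lognormal_null(np.array([1.0, 2.0, 3.0]))

    def test_log_space_arithmetic(self):
        ratios = np.exp(np.arange(12, dtype=float))  # e^0 .. e^11
        null = fit_lognormal_null(ratios)
        assert null.mu == pytest.approx(np.mean(np.arange(12)))
        assert null.sigma == pytest.approx(np.std(np.arange(12)))

    def test_mle_recovers_parameters(self, rng):
        draws = rng.lognormal(0.3, 0.7, size=10_000)
        null = fit_lognormal_null(draws)
        # standard errors: sigma/sqrt(n) and sigma/sqrt(2n)
        assert null.mu == pytest.approx(0.3, abs=3 * 0.7 / 100)
        assert null.sigma == pytest.approx(0.7, abs=3 * 0.7 / np.sqrt(2) / 100)

    def test_nonpositive_ratios_dropped_before_fit(self):
        ratios = np.concatenate([np.zeros(5), np.exp(np.arange(12, dtype=float))])
        null = fit_lognormal_null(ratios)
        assert null.mu == pytest.approx(np.mean(np.arange(12)))


class TestComputePvalues:
    def test_median_ratio_gives_half(self):
        null = NullModel(kind="lognormal", mu=0.4, sigma=1.2)
        assert compute_pvalues(np.array([np.exp(0.4)]), null)[0] == pytest.approx(0.5)

    def test_upper_quantile_closed_form(self):
        null = NullModel(kind="lognormal", mu=0.4, sigma=1.2)
        r = np.exp(0.4 + 1.6449 * 1.2)
        assert compute_pvalues(np.array([r]), null)[0] == pytest.approx(0.05, abs=5e-5)

    def test_permutation_add_one_tail(self):
        null = NullModel(kind="permutation", null_ratios=np.array([1.0, 2.0, 3.0, 4.0]))
        p = compute_pvalues(np.array([5.0, 2.5, 0.5]), null)
        assert p[0] == pytest.approx(1 / 5)
        assert p[1] == pytest.approx(3 / 5)  # null >= 2.5: {3,4} -> (1+2)/5
        assert p[2] == pytest.approx(1.0)

    def test_nonpositive_ratio_gets_one(self):
        null = NullModel(kind="lognormal", mu=0.0, sigma=1.0)
        assert compute_pvalues(np.array([0.0]), null)[0] == 1.0

    def test_monotone_nonincreasing_in_ratio(self, rng):
        ratios = np.sort(rng.lognormal(0, 1, size=200))
        for null in (
            NullModel(kind="lognormal", mu=0.1, sigma=0.8),
            NullModel(kind="permutation", null_ratios=rng.lognormal(0, 1, size=500)),
        ):
            p = compute_pvalues(ratios, null)
            assert np.all(np.diff(p) <= 1e-15)


class TestPermutationNull:
    def _inputs(self, rng, n=30, m=60):
        coords = make_coords(rng.uniform(0, 8, size=(m, 2)), rescaled=True)
        index = build_spatial_index(coords)
        small = compute_patch_matrix(index, 1.0)
        big = compute_patch_matrix(index, 3.0)
        raw = make_expr(rng.poisson(2.0, size=(n, m)).astype(float))
        scaled, _ = scale_expression_maxabs(raw)
        return raw, scaled, small, big

    def test_seed_reproducibility(self, rng):
        raw, scaled, small, big = self._inputs(rng)
        a = permutation_null(raw, scaled, small, big, n_perm=150, seed=11)
        b = permutation_null(raw, scaled, small, big, n_perm=150, seed=11)
        np.testing.assert_array_equal(a.null_ratios, b.null_ratios)
        c = permutation_null(raw, scaled, small, big, n_perm=150, seed=12)
        assert not np.array_equal(a.null_ratios, c.null_ratios)

    def test_minimum_permutations_enforced(self, rng):
        raw, scaled, small, big = self._inputs(rng)
        with pytest.raises(ValidationError, match="at least 100"):
            permutation_null(raw, scaled, small, big, n_perm=50)

    def test_nulls_rank_agreement_with_lognormal(self, rng):
        # both nulls are monotone in the ratio, so null-feature rank order
        # must agree almost perfectly
        raw, scaled, small, big = self._inputs(rng, n=60, m=120)
        _, _, ratio, degen = compute_variance_ratio(raw, scaled, small, big)
        ratio = ratio[~degen]
        log_p = compute_pvalues(ratio, fit_lognormal_null(ratio))
        perm = permutation_null(raw, scaled, small, big, n_perm=2000, seed=5)
        perm_p = compute_pvalues(ratio, perm)
        rho = stats.spearmanr(log_p, perm_p).statistic
        assert rho >= 0.99


class TestRunScbsp:
    def test_radius_order_validated(self, random_instance):
        expr, coords = random_instance
        with pytest.raises(ValidationError, match="small radius"):
            run_scbsp(expr, coords, r1=3.0, r2=1.0)

    def test_rows_in_input_order_with_exclusions(self, rng):
        m = 50
        coords = make_coords(rng.uniform(0, 7, size=(m, 2)))
        rows = rng.poisson(2.0, size=(12, m)).astype(float)
        rows[4] = 3.0  # constant -> excluded
        expr = make_expr(rows)
        res = run_scbsp(expr, coords)
        np.testing.assert_array_equal(res.feature_ids, expr.feature_ids)
        assert res.excluded[4]
        assert res.p_value[4] == 1.0 and res.ratio[4] == 0.0
        assert not res.excluded[[0, 1, 2, 3, 5]].any()
        assert np.all((res.p_value > 0) & (res.p_value <= 1))
        assert res.weight.max() == pytest.approx(1.0)

    def test_spot_permutation_equivariance(self, random_instance, rng):
        expr, coords = random_instance
        base = run_scbsp(expr, coords)
        perm = rng.permutation(coords.n_spots)
        expr2 = make_expr(expr.values.toarray()[:, perm])
        coords2 = make_coords(coords.positions[perm])
        moved = run_scbsp(expr2, coords2)
        np.testing.assert_allclose(moved.p_value, base.p_value, atol=1e-12)
        np.testing.assert_allclose(moved.ratio, base.ratio, atol=1e-12)

    def test_feature_permutation_equivariance(self, random_instance, rng):
        expr, coords = random_instance
        base = run_scbsp(expr, coords)
        perm = rng.permutation(expr.n_features)
        expr2 = make_expr(expr.values.toarray()[perm],
                          ids=[expr.feature_ids[j] for j in perm])
        moved = run_scbsp(expr2, coords)
        np.testing.assert_allclose(moved.p_value, base.p_value[perm], atol=1e-12)

    def test_bh_adjustment_column(self, random_instance):
        expr, coords = random_instance
        res = run_scbsp(expr, coords, adjust="bh")
        assert res.q_value is not None
        assert np.all(res.q_value >= res.p_value - 1e-15)
        # BH is order preserving
        order = np.argsort(res.p_value)
        assert np.all(np.diff(res.q_value[order]) >= -1e-15)

    def test_permutation_null_end_to_end_deterministic(self, random_instance):
        expr, coords = random_instance
        a = run_scbsp(expr, coords, null_kind="permutation", n_perm=200, seed=3)
        b = run_scbsp(expr, coords, null_kind="permutation", n_perm=200, seed=3)
        np.testing.assert_array_equal(a.p_value, b.p_value)
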