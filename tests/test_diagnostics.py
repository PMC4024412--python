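import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pkresample import (
    ClassicalMDS,
    RunScaler,
    bootstrap_design,
    cdd_design,
    classical_mds,
    design_check,
    distribution_check,
    ebe_variance,
    influence_flags,
    normalize_runs,
)
from pkresample.resample import ResampleMatrix


def make_matrix(values, pop_estimates=None, parameter="CL"):
    values = np.asarray(values, dtype=float)
    n, r = values.shape
    return ResampleMatrix(
        parameter_name=parameter,
        values=values,
        subject_ids=list(range(1, n + 1)),
        run_labels=[f"run{j}" for j in range(1, r + 1)],
        pop_estimates=(np.full(r, np.nan) if pop_estimates is None
                       else np.asarray(pop_estimates, dtype=float)),
        run_status=["converged"] * r,
    )


class TestNormalizeRuns:
    def test_direct_arithmetic(self):
        m = make_matrix(np.array([[2.0], [4.0], [6.0]]))
        s = normalize_runs(m)
        np.testing.assert_allclose(s.values[:, 0], [0.0, 0.5, 1.0])
        assert s.col_min[0] == 2.0 and s.col_max[0] == 6.0

    def test_constant_column_maps_to_half(self):
        m = make_matrix(np.array([[5.0], [5.0], [5.0]]))
        np.testing.assert_allclose(normalize_runs(m).values[:, 0], 0.5)

    def test_unit_length_per_run(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(12, 7)) * 3 + 1
        vals[2, 3] = np.nan
        s = normalize_runs(make_matrix(vals))
        for j in range(7):
            col = s.values[:, j]
            col = col[~np.isnan(col)]
            assert np.nanmax(col) - np.nanmin(col) == pytest.approx(1.0)
            assert col.min() >= 0.0 and col.max() <= 1.0

    def test_missing_preserved(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0], [3.0, 5.0]])
        s = normalize_runs(make_matrix(vals))
        assert np.isnan(s.values[0, 1])
        assert np.isfinite(s.values[:, 0]).all()

    @given(
        scale=st.floats(min_value=0.01, max_value=100),
        shift=st.floats(min_value=-50, max_value=50),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance(self, scale, shift):
        # positive-slope affine maps leave the scaled output unchanged
        base = np.array([[0.1, 3.0], [1.2, -1.0], [0.7, 2.0], [2.0, 0.5]])
        s0 = normalize_runs(make_matrix(base))
        s1 = normalize_runs(make_matrix(base * scale + shift))
        np.testing.assert_allclose(s1.values, s0.values, atol=1e-9)

    def test_sklearn_transformer_protocol(self):
        X = np.array([[2.0, 1.0], [4.0, 1.0], [6.0, 1.0]])
        scaler = RunScaler().fit(X)
        out = scaler.transform(X)
        np.testing.assert_allclose(out[:, 0], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(out[:, 1], 0.5)
        assert scaler.get_params() == {"global_scale": False}


class TestClassicalMDS:
    def test_right_triangle_distances_recovered(self):
        # legs 3 and 4 -> pairwise distances {3, 4, 5}, exactly preserved
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        emb = classical_mds(pts, k=2, labels=[1, 2, 3])
        d = np.linalg.norm(emb.points[:, None] - emb.points[None, :], axis=2)
        expected = np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], dtype=float)
        np.testing.assert_allclose(np.sort(d.ravel()),
                                   np.sort(expected.ravel()), atol=1e-9)

    def test_identical_rows_collapse_to_origin(self):
        X = np.ones((4, 3)) * 2.5
        emb = classical_mds(X, k=2)
        np.testing.assert_allclose(emb.points, 0.0, atol=1e-9)

    def test_full_rank_exact_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        emb = classical_mds(X, k=4)
        d_in = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d_out = np.linalg.norm(emb.points[:, None] - emb.points[None, :],
                               axis=2)
        np.testing.assert_allclose(d_out, d_in, atol=1e-9)

    def test_matches_pca_scores_distances(self):
        # on complete data classical MDS = PCA scores up to rotation/sign:
        # embedding distances equal centered-data score distances
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 5))
        emb = classical_mds(X, k=5)
        Xc = X - X.mean(axis=0)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = u * s
        d_mds = np.linalg.norm(emb.points[:, None] - emb.points[None, :],
                               axis=2)
        d_pca = np.linalg.norm(scores[:, None] - scores[None, :], axis=2)
        np.testing.assert_allclose(d_mds, d_pca, atol=1e-9)

    def test_missing_imputed_with_row_mean(self):
        X = np.array([[1.0, 1.0, np.nan], [2.0, 2.0, 2.0], [5.0, 4.0, 3.0]])
        emb = classical_mds(X, k=2)
        assert np.isfinite(emb.points).all()

    def test_all_missing_row_rejected(self):
        X = np.array([[np.nan, np.nan], [1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="0"):
            classical_mds(X, k=1)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(7, 3))
        a = ClassicalMDS(n_components=2).fit_transform(X)
        b = ClassicalMDS(n_components=2).fit_transform(X)
        np.testing.assert_array_equal(a, b)
        for c in range(2):
            assert a[np.argmax(np.abs(a[:, c])), c] >= 0


class TestInfluenceFlags:
    def test_matches_brute_force_percentiles(self):
        rng = np.random.default_rng(1)
        est = np.concatenate([rng.normal(0, 1, 99), [10.0]])
        design = cdd_design(list(range(1, 101)), perturb_period=0)
        report = influence_flags({"CL": est}, design)
        lo, hi = np.percentile(est, [5, 95])
        expected = {i for i, v in enumerate(est) if v < lo or v > hi}
        got = {i for i, f in enumerate(report.table["flagged"]) if f}
        assert got == expected
        assert 99 in got  # the extreme run is always among the flags
        assert report.table.iloc[99]["deleted_subject"] == 100

    def test_all_equal_no_flags(self):
        est = np.full(30, 2.5)
        design = cdd_design(list(range(1, 31)), perturb_period=0)
        report = influence_flags({"CL": est}, design)
        assert not report.table["flagged"].any()

    def test_full_envelope_never_flags(self):
        rng = np.random.default_rng(2)
        est = rng.normal(size=50)
        design = cdd_design(list(range(1, 51)), perturb_period=0)
        report = influence_flags({"CL": est}, design, lower=0, upper=100)
        assert not report.table["flagged"].any()

    def test_failed_runs_excluded_and_warned_when_few(self):
        est = np.array([1.0, 2.0, np.nan, 1.5, 1.2, 0.9] + [1.1] * 4)
        design = cdd_design(list(range(1, 11)), perturb_period=0)
        with pytest.warns(UserWarning, match="unstable"):
            report = influence_flags({"CL": est}, design)
        assert not report.table.iloc[2]["flagged"]


class TestEbeVariance:
    def test_small_examples(self):
        m = make_matrix(np.array([[1.0, 1.0, 1.0], [0.0, 2.0, np.nan]]))
        df = ebe_variance(m).set_index("ID")
        assert df.loc[1, "variance"] == 0.0
        assert df.loc[2, "variance"] == 2.0  # n-1 denominator

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(5, 20))
        df = ebe_variance(make_matrix(vals)).set_index("ID")
        for i in range(5):
            row = vals[i]
            mean = sum(row) / 20
            brute = sum((x - mean) ** 2 for x in row) / 19
            assert df.loc[i + 1, "variance"] == pytest.approx(brute, abs=1e-12)

    def test_single_run_subject_warns(self):
        vals = np.array([[1.0, 2.0], [3.0, np.nan]])
        with pytest.warns(UserWarning, match="< 2 runs"):
            df = ebe_variance(make_matrix(vals)).set_index("ID")
        assert np.isnan(df.loc[2, "variance"])


class TestDesignCheck:
    def test_sequential_cdd_detected(self):
        d = cdd_design(list(range(1, 6)), perturb_period=0)
        out = design_check(d)
        assert out["is_strictly_sequential"] is True
        perturbed = cdd_design(list(range(1, 30)), perturb_period=2, seed=1)
        assert design_check(perturbed)["is_strictly_sequential"] is False

    def test_equal_counts_give_zero_chi2(self):
        # a constructed design where every subject appears once per run
        from pkresample.resample import Run, RunDesign

        ids = (1, 2, 3, 4)
        runs = tuple(
            Run(run_id=f"boot_{r}", included=ids, excluded=())
            for r in range(3)
        )
        d = RunDesign(runs=runs, kind="bootstrap", subject_ids=ids)
        out = design_check(d)
        assert out["chi2"] == 0.0
        assert out["p_value"] == 1.0

    def test_seeded_bootstrap_passes_uniformity(self):
        d = bootstrap_design(list(range(1, 101)), n_reps=50, seed=17)
        out = design_check(d)
        assert out["p_value"] > 0.001
        table = out["inclusion_counts"]
        assert (table.sum(axis=1) == 100).all()


class TestDistributionCheck:
    def test_identical_run_has_zero_statistic(self):
        ref = np.arange(30.0)
        out = distribution_check({"r1": ref.copy()}, ref)
        row = out["table"].iloc[0]
        assert row["ks_statistic"] == 0.0
        assert row["p_value"] == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(0, 1, 80)
        shifted = ref + 10.0
        out = distribution_check({"r1": shifted, "r2": ref.copy()}, ref)
        t = out["table"].set_index("run")
        assert t.loc["r1", "p_adjusted"] < 0.01
        assert t.loc["r2", "p_adjusted"] > 0.5

    def test_statistic_matches_brute_force_cdf_distance(self):
        a = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        b = np.array([2.0, 3.5, 4.0, 8.0, 12.0])
        out = distribution_check({"r": a}, b)
        grid = np.concatenate([a, b])
        ecdf_a = np.array([(a <= x).mean() for x in grid])
        ecdf_b = np.array([(b <= x).mean() for x in grid])
        brute = np.abs(ecdf_a - ecdf_b).max()
        assert out["table"].iloc[0]["ks_statistic"] == pytest.approx(
            brute, abs=1e-12)

    def test_densities_returned_on_common_grid(self):
        rng = np.random.default_rng(9)
        out = distribution_check(
            {"r1": rng.normal(size=40), "r2": rng.normal(size=40)},
            rng.normal(size=60),
        )
        g1, d1 = out["densities"]["r1"]
        g2, _ = out["densities"]["r2"]
        np.testing.assert_array_equal(g1, g2)
        assert np.all(d1 >= 0)

    def test_tiny_run_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = distribution_check(
                {"r1": [1.0], "r2": [1.0, 2.0, 3.0]}, [0.0, 1.0, 2.0])
        assert list(out["table"]["run"]) == ["r2"]
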