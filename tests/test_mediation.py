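"""Two-level mediation: path algebra, bootstrap, clustering, SVC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from mlmed.mediation import (MediationMaps, PathMatrix, ThresholdSpec,
                             bootstrap_inference, classify_mediation,
                             fit_subject_paths, group_decompose,
                             prepare_mediation_inputs, small_volume_correct,
                             threshold_and_cluster, voxelwise_mediation)
from mlmed.volumes import isotropic_grid


def _random_paths(rng, n=10):
    a = rng.normal(0.5, 0.3, n)
    b = rng.normal(0.4, 0.3, n)
    cprime = rng.normal(0.1, 0.1, n)
    return PathMatrix(np.column_stack([a, b, cprime + a * b, cprime, a * b]))


class TestFitSubjectPaths:
    def test_perfect_mediation(self):
        """m carries all of x's effect: a=1, b=1, c=1, c'=0."""
        x = np.tile([-1.0, 1.0], 20)
        e = np.tile([0.1, 0.1, -0.1, -0.1], 10)  # orthogonal to 1 and x
        m = x + e
        row = fit_subject_paths(x, m, m.copy())
        assert np.allclose(row, [1, 1, 1, 0, 1], atol=1e-12)

    def test_c_equals_cprime_plus_ab(self, rng):
        """Exact OLS decomposition with shared covariates."""
        for _ in range(100):
            n = int(rng.integers(12, 60))
            x = rng.normal(size=n)
            m = rng.normal(size=n)
            y = rng.normal(size=n)
            cov = rng.normal(size=(n, int(rng.integers(0, 3)))) if rng.random() > 0.3 else None
            row = fit_subject_paths(x, m, y, cov)
            assert abs(row[2] - (row[3] + row[4])) < 1e-10

    def test_null_mediator(self, rng):
        n = 4000
        x = rng.choice([-1.0, 1.0], n)
        m = rng.normal(size=n)  # independent of x and y
        y = 0.5 * x + rng.normal(size=n)
        row = fit_subject_paths(x, m, y)
        assert abs(row[0]) < 3 / np.sqrt(n)       # a ~ 0
        assert abs(row[4]) < 3 / np.sqrt(n)       # ab ~ 0

    def test_constant_mediator_raises(self):
        x = np.tile([-1.0, 1.0], 10)
        with pytest.raises(ValueError, match="degenerate"):
            fit_subject_paths(x, np.ones(20), x.copy())

    def test_constant_x_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_subject_paths(np.ones(20), np.arange(20.0), np.arange(20.0))


class TestGroupDecompose:
    def test_hand_computed_example(self):
        pm = PathMatrix(np.column_stack(
            [[1, 2, 3], [1, 2, 3], [2, 5, 10], [1, 1, 1], [1, 4, 9]]).astype(float))
        mean_ab, ma_mb, cov = group_decompose(pm)
        assert mean_ab == pytest.approx(14 / 3)
        assert ma_mb == pytest.approx(4.0)
        assert cov == pytest.approx(2 / 3)
        assert mean_ab == pytest.approx(ma_mb + cov, abs=1e-12)

    def test_constant_b_zero_covariance(self, rng):
        a = rng.normal(size=6)
        b = np.full(6, 0.7)
        pm = PathMatrix(np.column_stack([a, b, a * b, np.zeros(6), a * b]))
        mean_ab, ma_mb, cov = group_decompose(pm)
        assert cov == pytest.approx(0.0, abs=1e-14)
        assert mean_ab == pytest.approx(a.mean() * 0.7)

    @settings(deadline=None, max_examples=200)
    @given(data=hnp.arrays(np.float64, st.tuples(st.integers(2, 30), st.just(2)),
                           elements=st.floats(-50, 50)))
    def test_identity_property(self, data):
        """mean(ab) = mean(a)mean(b) + cov(a,b) for arbitrary path draws."""
        a, b = data[:, 0], data[:, 1]
        pm = PathMatrix(np.column_stack(
            [a, b, a * b, np.zeros_like(a), a * b]))
        mean_ab, ma_mb, cov = group_decompose(pm)
        assert abs(mean_ab - ma_mb - cov) < 1e-9 * max(1, abs(mean_ab))


class TestBootstrap:
    def test_floor_p_when_effect_huge(self, rng):
        pm = _random_paths(rng, n=20)
        pm.data[:, 4] = np.abs(pm.data[:, 4]) + 10  # all-positive indirect effect
        pm.data[:, 0] = 1.0
        pm.data[:, 1] = pm.data[:, 4]
        res = bootstrap_inference(pm, n_boot=500, seed=0)
        assert res.p["ab"] == pytest.approx(2 / 500)

    def test_deterministic_given_seed(self, rng):
        pm = _random_paths(rng)
        r1 = bootstrap_inference(pm, n_boot=1000, seed=5)
        r2 = bootstrap_inference(pm, n_boot=1000, seed=5)
        assert r1.p == r2.p and r1.ci == r2.ci

    def test_ci_contains_point_estimate(self, rng):
        pm = _random_paths(rng, n=15)
        res = bootstrap_inference(pm, n_boot=2000, seed=2)
        for k in ("a", "b", "c", "cprime", "ab"):
            lo, hi = res.ci[k]
            assert lo <= res.estimate[k] <= hi

    def test_identical_rows_flagged_degenerate(self):
        row = np.array([0.5, 0.4, 0.4, 0.2, 0.2])
        pm = PathMatrix(np.tile(row, (8, 1)))
        res = bootstrap_inference(pm, n_boot=200, seed=0)
        assert res.degenerate
        assert res.p["ab"] == pytest.approx(2 / 200)

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            bootstrap_inference(_random_paths(rng, n=4), n_boot=100, seed=0)

    def test_permuted_null_p_is_roughly_uniform(self, rng):
        """Bootstrap p of ab under a permuted-cue null is ~U(0,1] (KS test)."""
        from scipy.stats import kstest
        n_rep, n_sub, n_tr = 400, 20, 40
        pvals = np.empty(n_rep)
        x_base = np.tile([-1.0, 1.0], n_tr // 2)
        for r in range(n_rep):
            rows = []
            for s in range(n_sub):
                x = rng.permutation(x_base)     # breaks any x association
                m = 0.4 * rng.standard_normal() + rng.normal(size=n_tr)
                y = rng.normal(size=n_tr)
                rows.append(fit_subject_paths(x, m, y))
            pm = PathMatrix.from_rows(rows)
            pvals[r] = bootstrap_inference(pm, n_boot=500, seed=r).p["ab"]
        stat, p = kstest(pvals, "uniform")
        assert p > 0.01


@pytest.fixture(scope="module")
def planted_maps():
    rng = np.random.default_rng(0)
    shape = (5, 5, 4)
    V = int(np.prod(shape))
    planted = [0, 1, 2, 3, 4]  # first five flat indices
    n_sub, n_tr = 15, 60
    data = []
    for s in range(n_sub):
        a_i = rng.normal(0.6, 0.2)
        b_i = rng.normal(0.5, 0.2)
        x = np.tile([-1.0, 1.0], n_tr // 2)
        M = rng.normal(0, 1.0, (n_tr, V))
        med = a_i * x + rng.normal(0, 0.5, n_tr)
        M[:, planted] += med[:, None]
        y = b_i * med + 0.1 * x + rng.normal(0, 0.5, n_tr)
        cov = rng.normal(size=(n_tr, 2))
        data.append((x, M, y, cov))
    maps = voxelwise_mediation(data, n_boot=800, seed=3, shape=shape)
    return maps, planted, V


class TestVoxelwise:
    def test_planted_voxels_rank_top_by_ab_z(self, planted_maps):
        maps, planted, V = planted_maps
        z = np.abs(maps.z["ab"].ravel())
        top5 = set(np.argsort(z)[-5:])
        assert top5 == set(planted)

    def test_one_voxel_reduces_to_scalar_pipeline(self, rng):
        n_tr = 40
        x = np.tile([-1.0, 1.0], n_tr // 2)
        m = 0.5 * x + rng.normal(0, 0.5, n_tr)
        y = 0.4 * m + rng.normal(0, 0.5, n_tr)
        row = fit_subject_paths(x, m, y)
        data = [(x, m[:, None], y, None) for _ in range(8)]
        maps = voxelwise_mediation(data, n_boot=300, seed=1)
        assert maps.estimate["ab"][0] == pytest.approx(row[4])

    def test_null_grid_false_positive_rate(self, rng):
        """All-null grid: P(p < alpha) ~ alpha at a liberal alpha."""
        n_sub, n_tr, V = 20, 50, 400
        alpha = 0.05
        data = []
        for s in range(n_sub):
            x = np.tile([-1.0, 1.0], n_tr // 2)
            M = rng.normal(size=(n_tr, V))
            y = rng.normal(size=n_tr)
            data.append((x, M, y, None))
        maps = voxelwise_mediation(data, n_boot=500, seed=4)
        rate = float(np.mean(maps.p["ab"] < alpha))
        se = np.sqrt(alpha * (1 - alpha) / V)
        # voxels are independent here, so a 4-s.e. band is generous
        assert abs(rate - alpha) < 4 * se + 0.01


class TestClusterAndSvc:
    def _maps_from_p(self, pvol, est=None):
        shape = pvol.shape
        est = np.ones(shape) if est is None else est
        z = np.where(pvol < 0.5, 3.0, 0.1) * np.sign(est)
        fields = {}
        for name in ("a", "b", "c", "cprime", "ab"):
            fields[name] = None
        mk = lambda v: {k: v.copy() for k in fields}
        return MediationMaps(estimate=mk(est), p=mk(pvol), ci_lo=mk(est - 1),
                             ci_hi=mk(est + 1), z=mk(z), shape=shape)

    def test_extent_threshold_flood_fill_oracle(self):
        """Only blobs of >= k voxels survive; sizes match brute-force count."""
        pvol = np.ones((8, 8, 8))
        # one 4-voxel line and one 6-voxel block
        pvol[1, 1, 1:5] = 1e-4
        pvol[5:7, 5:7, 5] = 1e-4
        pvol[5, 5, 6] = 1e-4
        pvol[6, 6, 6] = 1e-4
        maps = self._maps_from_p(pvol)
        labels, table = threshold_and_cluster(maps, ThresholdSpec(cluster_extent=5))
        assert len(table) == 1
        assert table["size"].iloc[0] == 6

    def test_extent_one_equals_voxel_threshold(self):
        rng = np.random.default_rng(1)
        pvol = rng.uniform(size=(6, 6, 6))
        maps = self._maps_from_p(pvol)
        spec = ThresholdSpec(voxel_p=0.2, cluster_extent=1)
        labels, _ = threshold_and_cluster(maps, spec)
        assert np.array_equal(labels > 0, pvol < 0.2)

    def test_connectivity_semantics(self):
        """Diagonal voxels: one cluster at 26-connectivity, two at 6."""
        pvol = np.ones((4, 4, 4))
        pvol[1, 1, 1] = 1e-4
        pvol[2, 2, 2] = 1e-4
        maps = self._maps_from_p(pvol)
        _, t26 = threshold_and_cluster(maps, ThresholdSpec(cluster_extent=1,
                                                           connectivity=26))
        _, t6 = threshold_and_cluster(maps, ThresholdSpec(cluster_extent=1,
                                                          connectivity=6))
        assert len(t26) == 1
        assert len(t6) == 2

    def test_opposite_signs_do_not_merge(self):
        pvol = np.ones((4, 4, 4))
        pvol[1, 1, 1] = 1e-4
        pvol[1, 1, 2] = 1e-4
        est = np.ones((4, 4, 4))
        est[1, 1, 2] = -1.0
        maps = self._maps_from_p(pvol, est)
        _, table = threshold_and_cluster(maps, ThresholdSpec(cluster_extent=1))
        assert len(table) == 2

    def test_empty_suprathreshold_is_empty_table(self):
        maps = self._maps_from_p(np.ones((4, 4, 4)))
        labels, table = threshold_and_cluster(maps, ThresholdSpec())
        assert len(table) == 0
        assert labels.sum() == 0

    def test_svc_bonferroni_definition(self):
        grid = isotropic_grid((10, 10, 10), 2.0, (-9, -9, -9))
        pvol = np.ones((10, 10, 10))
        pvol[4, 4, 4] = 0.001
        maps = self._maps_from_p(pvol)
        res = small_volume_correct(maps, (0.0, 0.0, 0.0), grid, radius_mm=5.0)
        assert res["p_corrected"] == pytest.approx(0.001 * res["n_voxels"])

    def test_svc_single_voxel_sphere(self):
        grid = isotropic_grid((5, 5, 5), 2.0, (-4, -4, -4))
        pvol = np.full((5, 5, 5), 0.7)
        pvol[2, 2, 2] = 0.03
        maps = self._maps_from_p(pvol)
        res = small_volume_correct(maps, (0.0, 0.0, 0.0), grid, radius_mm=0.5)
        assert res["n_voxels"] == 1
        assert res["p_corrected"] == pytest.approx(0.03)

    def test_svc_outside_grid_fails(self):
        grid = isotropic_grid((5, 5, 5), 2.0, (0, 0, 0))
        maps = self._maps_from_p(np.ones((5, 5, 5)))
        with pytest.raises(ValueError, match="-100"):
            small_volume_correct(maps, (-100.0, 0.0, 0.0), grid, radius_mm=2.0)

    def test_classification_rules(self):
        pvol = np.ones((3, 3, 3))
        pvol[1, 1, 1] = 0.001
        est = np.ones((3, 3, 3))
        maps = self._maps_from_p(pvol, est)
        maps.p["cprime"] = np.full((3, 3, 3), 0.5)
        assert classify_mediation(maps, (1, 1, 1)) == "full"
        maps.p["cprime"][1, 1, 1] = 0.01
        assert classify_mediation(maps, (1, 1, 1)) == "partial"
        assert classify_mediation(maps, (0, 0, 0)) == "none"


class TestPrepareInputs:
    def test_extremes_coding_drops_middle_price(self):
        import pandas as pd
        trials = pd.DataFrame({
            "price": [1, 2, 3, 1, 2, 3], "payment": [0, 1] * 3,
            "wine": [1, 2, 3, 2, 3, 1], "rating": np.arange(6.0),
            "included": [True] * 5 + [False],
        })
        M = np.arange(12.0).reshape(6, 2)
        x, Mk, y, cov = prepare_mediation_inputs(trials, M)
        assert set(x) == {-1.0, 1.0}
        assert len(x) == 3  # two mid-price dropped, one QC-excluded
        assert Mk.shape == (3, 2)
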