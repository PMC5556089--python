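"""Single-trial GLM: nuisance construction, VIF, beta estimation, FIR."""

import numpy as np
import pytest

from mlmed.design import generate_design
from mlmed.glm import (SingleTrialDesign, build_nuisance,
                       build_single_trial_design, compute_all_vifs,
                       compute_vif, estimate_betas, estimate_fir)
from mlmed.hrf import convolve_boxcar
from mlmed.synth import SimConfig, SubjectParams, mediator_mask, simulate_subject


def _toy_design(rng, n=60, n_nuis=4, with_intercept=True):
    """Random design with one trial column and a small nuisance block."""
    trial = rng.normal(size=(n, 1))
    nuis = rng.normal(size=(n, n_nuis))
    if with_intercept:
        nuis = np.hstack([np.ones((n, 1)), nuis])
    matrix = np.hstack([trial, nuis])
    return SingleTrialDesign(matrix=matrix, trial_columns=np.array([0]),
                             nuisance_columns=np.arange(1, matrix.shape[1]),
                             labels=["trial_001"] + [f"n{i}" for i in range(nuis.shape[1])],
                             tr_s=2.5)


class TestBuildNuisance:
    def test_exactly_24_motion_columns(self, rng):
        motion = rng.normal(size=(90, 6))
        block = build_nuisance(motion, run_lengths=[30, 30, 30])
        assert block.motion.shape == (90, 24)
        assert block.intercepts.shape == (90, 3)
        assert block.drifts.shape == (90, 3)

    def test_constant_traces_collapse_to_intercepts(self):
        motion = np.tile(np.arange(1.0, 7.0), (60, 1))  # constant per column
        block = build_nuisance(motion, run_lengths=[30, 30])
        # mean-centred squares vanish; derivatives vanish
        assert np.allclose(block.motion[:, 6:12], 0)
        assert np.allclose(block.motion[:, 12:], 0)
        combined = np.hstack([block.motion, block.intercepts])
        assert np.linalg.matrix_rank(combined) == 2  # run intercept count

    def test_linear_ramp_has_constant_derivative(self):
        motion = np.zeros((40, 6))
        motion[:, 0] = np.linspace(0, 1, 40)
        block = build_nuisance(motion, run_lengths=[40])
        deriv = block.motion[:, 12]
        assert np.allclose(deriv[1:], deriv[1])
        assert deriv[0] == 0.0  # zero-padded at run start

    def test_nonfinite_rejected(self):
        motion = np.zeros((10, 6))
        motion[3, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            build_nuisance(motion, run_lengths=[10])


class TestVif:
    def test_orthogonal_column_has_unit_vif(self, rng):
        n = 64
        nuis = np.hstack([np.ones((n, 1)), rng.normal(size=(n, 3))])
        q, _ = np.linalg.qr(np.hstack([nuis, rng.normal(size=(n, 1))]))
        trial = q[:, -1]  # orthogonal to the nuisance span by construction
        d = SingleTrialDesign(np.hstack([trial[:, None], nuis]),
                              np.array([0]), np.arange(1, 5),
                              ["t"] + ["n"] * 4, 2.5)
        assert compute_vif(d, 0) == pytest.approx(1.0, abs=1e-10)

    def test_r2_06_gives_vif_25(self, rng):
        """A column with R^2 = 0.6 against the nuisance has VIF = 2.5."""
        n = 100
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std()
        e = rng.normal(size=n)
        e -= e.mean()
        e -= z * (z @ e) / (z @ z)     # orthogonal to z and to the intercept
        e /= e.std()
        trial = np.sqrt(0.6) * z + np.sqrt(0.4) * e
        nuis = np.hstack([np.ones((n, 1)), z[:, None]])
        d = SingleTrialDesign(np.hstack([trial[:, None], nuis]),
                              np.array([0]), np.array([1, 2]),
                              ["t", "c", "z"], 2.5)
        assert compute_vif(d, 0) == pytest.approx(2.5, abs=1e-8)

    def test_oracle_correlation_matrix_inversion(self, rng):
        """Regression VIF equals the diagonal of the inverse correlation matrix."""
        for _ in range(20):
            d = _toy_design(rng, n=20, n_nuis=4)
            vif_reg = compute_vif(d, 0)
            cols = np.hstack([d.matrix[:, [0]], d.matrix[:, d.nuisance_columns[1:]]])
            R = np.corrcoef(cols, rowvar=False)
            vif_inv = np.linalg.inv(R)[0, 0]
            assert vif_reg == pytest.approx(vif_inv, abs=1e-8)

    def test_vif_at_least_one_and_orthogonal_invariance(self, rng):
        d = _toy_design(rng, n=50, n_nuis=3)
        v0 = compute_all_vifs(d)
        assert np.all(v0 >= 1)
        # append a nuisance column orthogonal to everything
        q, _ = np.linalg.qr(np.hstack([d.matrix, rng.normal(size=(50, 1))]))
        extra = q[:, -1:]
        d2 = SingleTrialDesign(np.hstack([d.matrix, extra]), d.trial_columns,
                               np.append(d.nuisance_columns, d.matrix.shape[1]),
                               d.labels + ["extra"], 2.5)
        assert np.allclose(compute_all_vifs(d2), v0, atol=1e-8)

    def test_column_in_nuisance_span_is_infinite(self, rng):
        nuis = np.hstack([np.ones((30, 1)), rng.normal(size=(30, 2))])
        trial = nuis @ np.array([1.0, 2.0, -1.0])
        d = SingleTrialDesign(np.hstack([trial[:, None], nuis]),
                              np.array([0]), np.arange(1, 4), list("tcnn"), 2.5)
        assert np.isinf(compute_vif(d, 0))


@pytest.fixture(scope="module")
def noiseless():
    cfg = SimConfig(drift_amplitude=0, ar_coef=0, ar_innovation_sd=0,
                    motion_step_sd=0.01, motion_leak_amplitude=0,
                    grid_shape=(4, 4, 4), n_mediator_voxels=3)
    p = SubjectParams(0.8, 0.5, 0.1, 5.0, 0.5)
    from mlmed.design import DesignSpec
    spec = DesignSpec(reps_per_condition=6, n_runs=1, trials_per_run=36)
    data = simulate_subject(spec, p, cfg, seed=7)
    runs, motions = data["bold"], data["motion"]
    design = build_single_trial_design(
        data["trials"], 2.5, [r.n_scans for r in runs], np.vstack(motions))
    return cfg, data, runs, design


class TestEstimateBetas:
    def test_round_trip_recovers_amplitudes(self, noiseless):
        cfg, data, runs, design = noiseless
        series = estimate_betas(np.vstack([r.data2d for r in runs]), design)
        mask = mediator_mask(cfg).ravel()
        recovered = series.betas[:, mask].mean(axis=1)
        assert np.allclose(recovered, data["mediator"], atol=1e-10)

    def test_all_zero_voxel_gives_zero_betas(self, noiseless):
        cfg, data, runs, design = noiseless
        series = estimate_betas(np.vstack([r.data2d for r in runs]), design)
        mask = mediator_mask(cfg).ravel()
        null_betas = series.betas[:, ~mask]
        assert np.allclose(null_betas, 0, atol=1e-10)

    def test_degenerate_threshold_excludes_everything(self, noiseless):
        cfg, data, runs, design = noiseless
        with pytest.raises(ValueError, match="all .* trials excluded"):
            estimate_betas(np.vstack([r.data2d for r in runs]), design,
                           vif_threshold=1.0)

    def test_betas_invariant_to_nuisance_span_shift(self, noiseless, rng):
        """Adding any vector in the nuisance span leaves betas unchanged."""
        cfg, data, runs, design = noiseless
        Y = np.vstack([r.data2d for r in runs])[:, :5]
        shift = design.nuisance_block @ rng.normal(size=design.nuisance_block.shape[1])
        s1 = estimate_betas(Y, design)
        s2 = estimate_betas(Y + shift[:, None], design)
        assert np.allclose(s1.betas, s2.betas, atol=1e-8)

    def test_realistic_noise_excludes_few_trials(self, quiet_sim):
        from mlmed.design import DesignSpec
        spec = DesignSpec()
        p = SubjectParams(0.5, 0.4, 0.2, 5.0, 0.5)
        import dataclasses
        cfg = dataclasses.replace(quiet_sim, grid_shape=(3, 3, 3), n_mediator_voxels=1)
        data = simulate_subject(spec, p, cfg, seed=11)
        runs, motions = data["bold"], data["motion"]
        design = build_single_trial_design(
            data["trials"], 2.5, [r.n_scans for r in runs], np.vstack(motions))
        series = estimate_betas(np.vstack([r.data2d for r in runs]), design)
        assert series.excluded_count < 0.05 * len(data["trials"])


class TestFir:
    def test_recovers_hrf_shape_at_high_snr(self, rng):
        tr, n_bins = 2.5, 12
        onsets = np.arange(10) * 40.0  # far apart: no window overlap
        n_scans = 200
        signal = convolve_boxcar(onsets, 3.0, n_scans, tr).sum(axis=1)
        y = signal + rng.normal(0, 0.01, n_scans)
        est, se = estimate_fir(y, [onsets], tr_s=tr, n_bins=n_bins)
        expected = convolve_boxcar([0.0], 3.0, n_bins, tr)[:, 0]
        assert np.max(np.abs(est[:, 0] - expected)) < 5 * 0.01

    def test_null_condition_within_ci(self, rng):
        tr = 2.5
        onsets_a = np.arange(8) * 50.0
        onsets_null = onsets_a + 25.0
        n_scans = 170
        signal = convolve_boxcar(onsets_a, 3.0, n_scans, tr).sum(axis=1)
        y = signal + rng.normal(0, 0.05, n_scans)
        est, se = estimate_fir(y, [onsets_a, onsets_null], tr_s=tr, n_bins=8)
        assert np.all(np.abs(est[:, 1]) < 4 * se[:, 1])

    def test_amplitude_linearity(self, rng):
        tr = 2.5
        on_a = np.arange(8) * 60.0
        on_b = on_a + 30.0
        n_scans = 200
        sig = (convolve_boxcar(on_a, 3.0, n_scans, tr).sum(axis=1)
               + 2.0 * convolve_boxcar(on_b, 3.0, n_scans, tr).sum(axis=1))
        y = sig + rng.normal(0, 0.001, n_scans)
        est, _ = estimate_fir(y, [on_a, on_b], tr_s=tr, n_bins=8)
        ratio = est[:, 1].max() / est[:, 0].max()
        assert ratio == pytest.approx(2.0, abs=0.05)
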