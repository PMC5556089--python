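"""Synthetic two-level mediation studies with known ground truth.

The generator plants a subject-level mediation structure: per-subject path
coefficients (a_i, b_i) are drawn from a bivariate normal with controllable
means and covariance, so the population indirect effect is exactly
``mean(a)*mean(b) + cov(a, b)``.  Trial-level mediator amplitudes and ratings
follow the standard mediation regressions, and BOLD runs are synthesised by
convolving per-trial mediator amplitudes with a 3-s boxcar and the canonical
HRF, on top of linear drift, AR(1) scanner noise and motion-correlated signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, generate_design, run_duration_s
from .hrf import HrfSpec, convolve_boxcar
from .volumes import VolumeGrid, isotropic_grid


@dataclass(frozen=True)
class SubjectParams:
    """One subject's ground-truth mediation parameters."""

    a_i: float          # cue -> mediator slope
    b_i: float          # mediator -> rating slope
    cprime_i: float     # direct cue -> rating effect
    intercept_i: float  # rating intercept
    moderator_w_i: float  # external per-subject moderator value


@dataclass(frozen=True)
class SimConfig:
    """Population and noise parameters of the simulated study.

    Defaults describe the reference study conditions: a moderate planted
    indirect effect (a_mean*b_mean + ab_cov = 0.25), trial noise comparable to
    the planted slopes, and a small voxel grid with a compact blob of mediator
    voxels among null voxels.
    """

    # population means and s.d. of subject-level paths
    a_mean: float = 0.5
    a_sd: float = 0.3
    b_mean: float = 0.4
    b_sd: float = 0.3
    ab_cov: float = 0.05  # implies corr(a, b) ~ 0.56 at the default sds
    cprime_mean: float = 0.2
    cprime_sd: float = 0.1
    intercept_mean: float = 5.0
    intercept_sd: float = 1.0
    # trial-level noise
    mediator_noise_sd: float = 1.0
    rating_noise_sd: float = 1.0
    # nuisance condition effects on the rating
    gamma_wine: float = -0.1
    gamma_pay: float = -0.05
    # moderator: w_i = lambda * a_i + eta
    moderator_lambda: float = 1.0
    moderator_noise_sd: float = 0.1
    # volumetric layout
    grid_shape: tuple[int, int, int] = (6, 6, 6)
    voxel_size_mm: float = 2.0
    n_mediator_voxels: int = 7
    # BOLD noise
    drift_amplitude: float = 1.0
    ar_coef: float = 0.3
    ar_innovation_sd: float = 0.5
    motion_step_sd: float = 0.02
    motion_leak_amplitude: float = 0.5
    hrf: HrfSpec = field(default_factory=HrfSpec)
    seed: int = 0

    def validate(self) -> None:
        for name in ("a_sd", "b_sd", "cprime_sd", "intercept_sd", "mediator_noise_sd",
                     "rating_noise_sd", "moderator_noise_sd", "drift_amplitude",
                     "ar_innovation_sd", "motion_leak_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.ar_coef) >= 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        cov = self.ab_covariance_matrix()
        if np.min(np.linalg.eigvalsh(cov)) < -1e-12:
            raise ValueError("(a, b) covariance matrix is not positive semidefinite")

    def ab_covariance_matrix(self) -> np.ndarray:
        return np.array([[self.a_sd ** 2, self.ab_cov],
                         [self.ab_cov, self.b_sd ** 2]])

    @property
    def true_indirect_effect(self) -> float:
        """Population mean(a*b) = a_mean*b_mean + ab_cov."""
        return self.a_mean * self.b_mean + self.ab_cov

    def grid(self) -> VolumeGrid:
        # grid centered on mm origin so ROI centers near 0 are always inside
        shape = np.asarray(self.grid_shape)
        origin = -(shape - 1) / 2 * self.voxel_size_mm
        return isotropic_grid(self.grid_shape, self.voxel_size_mm, tuple(origin))


@dataclass
class BoldRun:
    """One simulated or measured fMRI run."""

    data: np.ndarray          # 4-D (i, j, k, t)
    tr_s: float
    run: int
    affine: np.ndarray

    @property
    def n_scans(self) -> int:
        return self.data.shape[-1]

    @property
    def data2d(self) -> np.ndarray:
        """(time, voxel) view, voxels in C order of the grid."""
        return self.data.reshape(-1, self.data.shape[-1]).T


def draw_subject_params(config: SimConfig, n_subjects: int, seed: int) -> list[SubjectParams]:
    """Sample subject-level path coefficients and moderators.

    (a_i, b_i) are bivariate normal with means ``(a_mean, b_mean)`` and
    covariance ``[[a_sd^2, ab_cov], [ab_cov, b_sd^2]]``; the moderator is
    ``w_i = moderator_lambda * a_i + eta`` with eta ~ N(0, moderator_noise_sd).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    config.validate()
    rng = np.random.default_rng(seed)
    ab = rng.multivariate_normal([config.a_mean, config.b_mean],
                                 config.ab_covariance_matrix(), size=n_subjects,
                                 method="svd")
    cprime = rng.normal(config.cprime_mean, config.cprime_sd, n_subjects)
    intercept = rng.normal(config.intercept_mean, config.intercept_sd, n_subjects)
    eta = rng.normal(0.0, config.moderator_noise_sd, n_subjects)
    w = config.moderator_lambda * ab[:, 0] + eta
    return [SubjectParams(a_i=float(ab[i, 0]), b_i=float(ab[i, 1]),
                          cprime_i=float(cprime[i]), intercept_i=float(intercept[i]),
                          moderator_w_i=float(w[i]))
            for i in range(n_subjects)]


def price_contrast(price: np.ndarray, n_levels: int = 3) -> np.ndarray:
    """Contrast-code price levels: -1 / +1 for the extremes, 0 between."""
    price = np.asarray(price, dtype=float)
    lo, hi = 1, n_levels
    x = np.zeros_like(price)
    x[price == lo] = -1.0
    x[price == hi] = 1.0
    return x


def simulate_trial_data(trials: pd.DataFrame, params: SubjectParams, config: SimConfig,
                        seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial mediator amplitudes and ratings for one subject.

    m_t = a_i * x_t + e_m,
    y_t = intercept_i + b_i * m_t + c'_i * x_t + gamma_wine * wine_t
          + gamma_pay * pay_t + e_y,
    with x the +-1 price contrast (0 for the middle level).  Ratings are
    continuous; no Likert clipping is applied.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    x = price_contrast(trials["price"].to_numpy())
    n = len(trials)
    e_m = rng.normal(0.0, config.mediator_noise_sd, n)
    e_y = rng.normal(0.0, config.rating_noise_sd, n)
    m = params.a_i * x + e_m
    y = (params.intercept_i + params.b_i * m + params.cprime_i * x
         + config.gamma_wine * trials["wine"].to_numpy()
         + config.gamma_pay * trials["payment"].to_numpy() + e_y)
    return m, y


def simulate_blind_ratings(params: SubjectParams, config: SimConfig, seed: int,
                           n_wines: int = 3) -> np.ndarray:
    """Baseline pleasantness ratings without any price cue (one per wine).

    With no cue, x = 0, so the rating reduces to the subject intercept plus
    the mediator chain driven by noise alone and the wine nuisance effect.
    """
    rng = np.random.default_rng(seed)
    wine = np.arange(1, n_wines + 1)
    e_m = rng.normal(0.0, config.mediator_noise_sd, n_wines)
    e_y = rng.normal(0.0, config.rating_noise_sd, n_wines)
    return params.intercept_i + params.b_i * e_m + config.gamma_wine * wine + e_y


def mediator_voxel_indices(config: SimConfig) -> np.ndarray:
    """Indices (n, 3) of planted mediator voxels: a compact blob at grid center."""
    shape = np.asarray(config.grid_shape)
    n_total = int(np.prod(shape))
    if config.n_mediator_voxels > n_total:
        raise ValueError(f"grid of {n_total} voxels too small for "
                         f"{config.n_mediator_voxels} mediator voxels")
    center = (shape - 1) / 2
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    d2 = np.sum((ijk - center) ** 2, axis=1)
    order = np.lexsort((ijk[:, 2], ijk[:, 1], ijk[:, 0], d2))
    return ijk[order[:config.n_mediator_voxels]]


def mediator_mask(config: SimConfig) -> np.ndarray:
    mask = np.zeros(config.grid_shape, dtype=bool)
    idx = mediator_voxel_indices(config)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


def _ar1(rng: np.random.Generator, n: int, phi: float, sd_innov: float,
         size: int) -> np.ndarray:
    """Stationary AR(1) series, shape (n, size)."""
    out = np.empty((n, size))
    if sd_innov == 0:
        return np.zeros((n, size))
    stat_sd = sd_innov / np.sqrt(1 - phi ** 2)
    out[0] = rng.normal(0.0, stat_sd, size)
    innov = rng.normal(0.0, sd_innov, (n - 1, size))
    for t in range(1, n):
        out[t] = phi * out[t - 1] + innov[t - 1]
    return out


def simulate_motion(rng: np.random.Generator, n_scans: int, step_sd: float) -> np.ndarray:
    """Six slow random-walk motion traces (3 translations, 3 rotations)."""
    steps = rng.normal(0.0, step_sd, (n_scans, 6))
    return np.cumsum(steps, axis=0)


def simulate_bold(trials: pd.DataFrame, mediator_amplitudes: np.ndarray,
                  config: SimConfig, seed: int) -> tuple[list[BoldRun], list[np.ndarray]]:
    """Synthesise BOLD runs carrying the trial mediator signal.

    Mediator voxels receive ``amplitude_t x (boxcar(tasting_duration) (*) HRF)``
    for every trial; all voxels receive per-voxel linear drift, stationary
    AR(1) noise and a random linear combination of the motion traces
    (motion leak).  Returns one :class:`BoldRun` and one (n_scans, 6) motion
    array per run.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    grid = config.grid()
    n_vox = int(np.prod(config.grid_shape))
    med_flat = np.flatnonzero(mediator_mask(config).ravel())
    amplitudes = np.asarray(mediator_amplitudes, dtype=float)
    if len(amplitudes) != len(trials):
        raise ValueError("one mediator amplitude per trial required")

    # modelled tasting epoch and TR follow the design defaults unless the
    # trial table carries overrides in its attrs
    duration_s = float(trials.attrs.get("tasting_duration_s", 3.0))
    tr = float(trials.attrs.get("TR_s", 2.5))

    runs: list[BoldRun] = []
    motions: list[np.ndarray] = []
    for run_id, run_tab in trials.groupby("run"):
        onsets = run_tab["onset_s"].to_numpy()
        amps = amplitudes[run_tab.index.to_numpy()]
        n_scans = int(np.ceil((onsets.max() + 32.0 + duration_s) / tr))
        sig_cols = convolve_boxcar(onsets, duration_s, n_scans, tr, amplitudes=amps,
                                   spec=config.hrf)
        signal = sig_cols.sum(axis=1)  # (n_scans,)

        motion = simulate_motion(rng, n_scans, config.motion_step_sd)
        data = np.zeros((n_scans, n_vox))
        # drift: per-voxel linear trend
        ramp = np.linspace(-0.5, 0.5, n_scans)
        drift_coef = rng.uniform(-1.0, 1.0, n_vox) * config.drift_amplitude
        data += np.outer(ramp, drift_coef)
        # AR(1) scanner noise
        data += _ar1(rng, n_scans, config.ar_coef, config.ar_innovation_sd, n_vox)
        # motion leak: random per-voxel weights on the 6 traces
        leak = rng.normal(0.0, 1.0, (6, n_vox)) * config.motion_leak_amplitude
        data += motion @ leak
        data[:, med_flat] += signal[:, None]

        vol4d = data.T.reshape(*config.grid_shape, n_scans)
        runs.append(BoldRun(data=vol4d, tr_s=tr, run=int(run_id), affine=grid.affine))
        motions.append(motion)
    return runs, motions


def simulate_subject(spec: DesignSpec, params: SubjectParams, config: SimConfig,
                     seed: int, with_bold: bool = True):
    """Full generative chain for one subject.

    Returns a dict with the trial table (ratings filled in), mediator
    amplitudes, and optionally BOLD runs plus motion traces.
    """
    trials = generate_design(spec, seed=seed)
    m, y = simulate_trial_data(trials, params, config, seed=seed + 1)
    trials = trials.copy()
    trials["rating"] = y
    out = {"trials": trials, "mediator": m, "ratings": y}
    if with_bold:
        runs, motion = simulate_bold(trials, m, config, seed=seed + 2)
        out["bold"] = runs
        out["motion"] = motion
    return out
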