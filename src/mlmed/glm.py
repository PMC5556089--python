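"""Single-trial ("beta series") GLM estimation with VIF-based trial QC.

One regressor per trial (3-s boxcar convolved with the canonical HRF) is fit
jointly with a nuisance set of 24 motion-derived regressors, per-run
intercepts and per-run linear drifts.  The variance inflation factor of every
trial regressor against the nuisance set, VIF_k = 1/(1 - R_k^2), flags trials
whose amplitude estimate is unstable due to collinearity with nuisance
signal; trials at or above the threshold (default 2.5) are excluded from the
downstream mediation.  Estimation is ordinary least squares per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrf import HrfSpec, convolve_boxcar
from .synth import BoldRun


@dataclass
class NuisanceBlock:
    """Nuisance design: 24 motion-derived columns, run intercepts, run drifts."""

    motion: np.ndarray      # (T, 24)
    intercepts: np.ndarray  # (T, n_runs)
    drifts: np.ndarray      # (T, n_runs)
    run_lengths: tuple[int, ...]

    @property
    def matrix(self) -> np.ndarray:
        return np.hstack([self.motion, self.intercepts, self.drifts])


@dataclass
class SingleTrialDesign:
    """Full time x regressor design with labelled column partitions."""

    matrix: np.ndarray
    trial_columns: np.ndarray      # column indices of trial regressors
    nuisance_columns: np.ndarray   # column indices of all nuisance regressors
    labels: list[str]
    tr_s: float

    @property
    def n_trials(self) -> int:
        return len(self.trial_columns)

    @property
    def trial_block(self) -> np.ndarray:
        return self.matrix[:, self.trial_columns]

    @property
    def nuisance_block(self) -> np.ndarray:
        return self.matrix[:, self.nuisance_columns]


@dataclass
class BetaSeries:
    """Per-trial, per-voxel amplitude estimates with QC flags."""

    betas: np.ndarray     # (n_trials, n_voxels)
    vif: np.ndarray       # (n_trials,)
    included: np.ndarray  # (n_trials,) bool
    vif_threshold: float

    @property
    def excluded_count(self) -> int:
        return int(np.sum(~self.included))


def _first_difference(x: np.ndarray, run_lengths) -> np.ndarray:
    """Within-run first difference, zero at each run's first volume."""
    d = np.zeros_like(x)
    start = 0
    for n in run_lengths:
        d[start + 1:start + n] = np.diff(x[start:start + n], axis=0)
        start += n
    return d


def build_nuisance(motion6: np.ndarray, run_lengths) -> NuisanceBlock:
    """Construct the nuisance design from 6 motion traces.

    The 24 motion-derived columns are the 6 raw parameters, their mean-centred
    squares (centred within run), their first differences (zero-padded at each
    run start) and the squared first differences.  Run intercepts and one
    linear drift per run are appended as separate labelled blocks.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion traces must be (time, 6)")
    if not np.all(np.isfinite(motion6)):
        bad = np.where(~np.all(np.isfinite(motion6), axis=0))[0]
        raise ValueError(f"non-finite values in motion columns {bad.tolist()}")
    run_lengths = tuple(int(n) for n in run_lengths)
    T = sum(run_lengths)
    if motion6.shape[0] != T:
        raise ValueError(f"motion rows ({motion6.shape[0]}) != total scans ({T})")

    squares = motion6 ** 2
    start = 0
    centred_sq = squares.copy()
    for n in run_lengths:
        centred_sq[start:start + n] -= squares[start:start + n].mean(axis=0)
        start += n
    deriv = _first_difference(motion6, run_lengths)
    motion24 = np.hstack([motion6, centred_sq, deriv, deriv ** 2])

    intercepts = np.zeros((T, len(run_lengths)))
    drifts = np.zeros((T, len(run_lengths)))
    start = 0
    for r, n in enumerate(run_lengths):
        intercepts[start:start + n, r] = 1.0
        drifts[start:start + n, r] = np.linspace(-0.5, 0.5, n)
        start += n
    return NuisanceBlock(motion24, intercepts, drifts, run_lengths)


def build_single_trial_design(trials: pd.DataFrame, tr_s: float,
                              run_lengths, motion6: np.ndarray,
                              duration_s: float = 3.0,
                              hrf: HrfSpec = HrfSpec()) -> SingleTrialDesign:
    """One HRF-convolved boxcar regressor per trial plus the nuisance set.

    ``trials`` must carry ``run`` and ``onset_s`` columns; columns are ordered
    trial regressors first (table order), then motion, intercepts, drifts.
    """
    run_lengths = tuple(int(n) for n in run_lengths)
    run_ids = sorted(trials["run"].unique())
    if len(run_ids) != len(run_lengths):
        raise ValueError("run_lengths must give one length per run in the table")
    T = sum(run_lengths)
    n_trials = len(trials)
    trial_cols = np.zeros((T, n_trials))
    start = 0
    for run_id, n_scans in zip(run_ids, run_lengths):
        tab = trials[trials["run"] == run_id]
        onsets = tab["onset_s"].to_numpy()
        if len(np.unique(np.round(onsets, 6))) != len(onsets):
            raise ValueError(f"overlapping identical onsets in run {run_id}")
        cols = convolve_boxcar(onsets, duration_s, n_scans, tr_s, spec=hrf)
        col_idx = np.flatnonzero(trials["run"].to_numpy() == run_id)
        trial_cols[start:start + n_scans, col_idx] = cols
        start += n_scans

    nuis = build_nuisance(motion6, run_lengths)
    matrix = np.hstack([trial_cols, nuis.matrix])
    labels = ([f"trial_{i:03d}" for i in range(1, n_trials + 1)]
              + [f"motion_{i:02d}" for i in range(1, 25)]
              + [f"intercept_run{r}" for r in range(1, len(run_lengths) + 1)]
              + [f"drift_run{r}" for r in range(1, len(run_lengths) + 1)])
    return SingleTrialDesign(
        matrix=matrix,
        trial_columns=np.arange(n_trials),
        nuisance_columns=np.arange(n_trials, matrix.shape[1]),
        labels=labels,
        tr_s=tr_s,
    )


def compute_vif(design: SingleTrialDesign, trial_column: int) -> float:
    """VIF of one trial regressor against the nuisance set: 1 / (1 - R^2).

    R^2 is the determination coefficient of the trial column regressed on the
    nuisance regressors (motion + intercepts + drifts).  Returns ``inf`` when
    the column lies in the nuisance span.
    """
    return _vif_of_column(design.matrix[:, trial_column], design.nuisance_block)


def _vif_of_column(col: np.ndarray, nuisance: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(nuisance, col, rcond=None)
    resid = col - nuisance @ coef
    sst = np.sum((col - col.mean()) ** 2)
    if sst <= 0:
        return np.inf
    r2 = 1.0 - np.sum(resid ** 2) / sst
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return float(max(1.0, 1.0 / (1.0 - r2)))


def compute_all_vifs(design: SingleTrialDesign) -> np.ndarray:
    """Vectorised VIFs for every trial regressor."""
    X = design.trial_block
    N = design.nuisance_block
    coef, *_ = np.linalg.lstsq(N, X, rcond=None)
    resid = X - N @ coef
    sst = np.sum((X - X.mean(axis=0)) ** 2, axis=0)
    ssr = np.sum(resid ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / sst, 1.0)
        vif = np.where(r2 >= 1.0 - 1e-12, np.inf, 1.0 / (1.0 - r2))
    return np.maximum(vif, 1.0)


def _as_2d(bold) -> np.ndarray:
    """Coerce BoldRun(s) or arrays to a single (time, voxel) matrix."""
    if isinstance(bold, BoldRun):
        return bold.data2d
    if isinstance(bold, (list, tuple)):
        return np.vstack([_as_2d(b) for b in bold])
    arr = np.asarray(bold, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def estimate_betas(bold, design: SingleTrialDesign,
                   vif_threshold: float = 2.5) -> BetaSeries:
    """OLS single-trial amplitudes per voxel, with VIF-based exclusion.

    Trials whose VIF is at or above ``vif_threshold`` are flagged excluded
    (their betas are still estimated); downstream mediation drops them
    listwise.  Raises if the design is rank deficient or no trial survives.
    """
    Y = _as_2d(bold)
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"time dimension mismatch: data {Y.shape[0]} rows, "
                         f"design {X.shape[0]} rows")
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "check for collinear trial/nuisance regressors")
    vif = compute_all_vifs(design)
    included = vif < vif_threshold
    if not included.any():
        raise ValueError(f"all {design.n_trials} trials excluded at "
                         f"VIF threshold {vif_threshold}")
    return BetaSeries(betas=coef[design.trial_columns, :], vif=vif,
                      included=included, vif_threshold=float(vif_threshold))


def estimate_fir(bold, onsets_by_condition, tr_s: float = 2.5,
                 n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Finite-impulse-response deconvolution of peristimulus time courses.

    One delta regressor per peristimulus bin (spaced one TR apart) per
    condition, plus an intercept, fit by OLS.  ``onsets_by_condition`` is a
    sequence of onset arrays (seconds), one per condition.

    Returns
    -------
    estimates, se : arrays of shape (n_bins, n_conditions)
    """
    Y = _as_2d(bold)
    if Y.shape[1] != 1:
        raise ValueError("estimate_fir expects a single time course")
    y = Y[:, 0]
    T = len(y)
    if np.ndim(onsets_by_condition[0]) == 0:
        onsets_by_condition = [onsets_by_condition]
    n_cond = len(onsets_by_condition)
    X = np.zeros((T, n_bins * n_cond + 1))
    X[:, -1] = 1.0
    for c, onsets in enumerate(onsets_by_condition):
        for on in np.atleast_1d(onsets):
            i0 = int(round(on / tr_s))
            for d in range(n_bins):
                if i0 + d < T:
                    X[i0 + d, c * n_bins + d] += 1.0
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            "FIR design rank deficient: overlapping peristimulus windows")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = T - X.shape[1]
    sigma2 = np.sum(resid ** 2) / max(dof, 1)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    est = coef[:-1].reshape(n_cond, n_bins).T
    se_out = se[:-1].reshape(n_cond, n_bins).T
    return est, se_out
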