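"""Second-level moderated mediation.

Tests whether subject-level mediation path coefficients scale with an
external per-subject moderator — here the sphere-averaged response of the
brain's valuation system to monetary reward in an independent task.  The
moderator is mean-centred and regressed onto the subject path coefficients
(path_i = g0 + g1 * w_i + e); inference on the moderation slope g1 uses a
pairs bootstrap over subjects, mirroring the mediation inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mediation import PathMatrix, _expand, _p_from_boots, expansion_factor
from .volumes import VolumeGrid, make_sphere


def sphere_average(volume: np.ndarray, center_mm, grid: VolumeGrid,
                   radius_mm: float = 10.0) -> float:
    """Unweighted mean of a 3-D volume over a sphere ROI.

    Voxel membership is by center-of-voxel distance <= radius in mm space.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != tuple(grid.shape):
        raise ValueError("volume shape does not match the grid")
    sphere = make_sphere(center_mm, radius_mm, grid)
    v = sphere.voxels
    return float(np.mean(volume[v[:, 0], v[:, 1], v[:, 2]]))


def moderator_table(subject_ids, w_values, source_rois=None) -> pd.DataFrame:
    """One moderator value per subject as a tidy table (TSV-serialisable)."""
    w = np.asarray(w_values, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("moderator values must be finite")
    tab = pd.DataFrame({"subject": list(subject_ids), "w": w})
    if tab["subject"].duplicated().any():
        raise ValueError("one moderator value per subject required")
    if source_rois is not None:
        tab.attrs["source_rois"] = list(source_rois)
    return tab


def moderate_path(paths, w, path: str = "a", n_boot: int = 10_000,
                  seed: int = 0) -> dict:
    """Regress one subject-level path on a mean-centred moderator.

    path_i = g0 + g1 * (w_i - mean(w)) + e.  g0 estimates the average path at
    the mean moderator; the two-tailed p for g1 comes from a pairs bootstrap
    (resampling (path_i, w_i) couples with replacement).

    ``paths`` may be a :class:`PathMatrix` (the named column is used) or a
    plain per-subject vector; ``w`` may be a ModeratorTable DataFrame or a
    vector aligned with it.
    """
    if isinstance(paths, PathMatrix):
        y = paths.column(path)
    else:
        y = np.asarray(paths, dtype=float)
    if isinstance(w, pd.DataFrame):
        w = w["w"].to_numpy()
    w = np.asarray(w, dtype=float)
    if len(w) != len(y):
        raise ValueError("paths and moderator must be aligned per subject")
    n = len(y)
    if n < 8:
        raise ValueError("moderation requires at least 8 subjects")
    if np.std(w) == 0:
        raise ValueError("moderator has zero variance")

    wc = w - w.mean()
    X = np.column_stack([np.ones(n), wc])
    g0, g1 = np.linalg.lstsq(X, y, rcond=None)[0]

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    yb = y[idx]                      # (n_boot, n)
    wb = wc[idx]
    wb_c = wb - wb.mean(axis=1, keepdims=True)
    denom = np.sum(wb_c ** 2, axis=1)
    # degenerate resamples (all-identical w) contribute a zero slope
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(denom > 0,
                          np.sum(wb_c * (yb - yb.mean(axis=1, keepdims=True)), axis=1) / denom,
                          0.0)
    # small-sample expanded percentile; slope reference df is n - 2
    slopes = _expand(slopes[:, None], expansion_factor(n, n - 2))[:, 0]
    p_g1 = float(_p_from_boots(slopes[:, None], n_boot)[0])
    lo, hi = np.quantile(slopes, [0.025, 0.975])
    return {
        "path": path,
        "gamma0": float(g0),
        "gamma1": float(g1),
        "p_gamma1": p_g1,
        "ci_gamma1": (float(lo), float(hi)),
        "se_gamma1": float(slopes.std(ddof=1)),
        "n_subjects": n,
        "n_boot": n_boot,
    }
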