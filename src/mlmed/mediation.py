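"""Two-level (multilevel) mediation with bootstrap inference.

Within each subject, three OLS regressions over trials estimate the paths of
the mediation model for a cue x, mediator m and outcome y (covariates of no
interest shared across all three equations):

    path c : y ~ x + cov          (total effect)
    path a : m ~ x + cov          (cue -> mediator)
    path b : y ~ m + x + cov      (mediator -> outcome; x slope is c')

With identical covariates, c = c' + a*b holds exactly per subject.  At the
group level the indirect effect is the subject mean of a*b, which decomposes
as mean(a)*mean(b) + cov(a, b) when the covariance uses the population (1/n)
denominator — mediation can therefore be carried either by consistent
within-subject products or by between-subject covariance of the paths.
Inference resamples whole subjects with replacement (percentile bootstrap;
two-tailed p from the sign distribution of the resampled means, floored at
2/n_boot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes import VolumeGrid, make_sphere

PATHS = ("a", "b", "c", "cprime", "ab")
_IDX = {name: i for i, name in enumerate(PATHS)}


@dataclass
class PathMatrix:
    """Subject x [a, b, c, c', a*b] path coefficients (one voxel or ROI)."""

    data: np.ndarray  # (n_subjects, 5)
    degenerate: np.ndarray | None = None  # (n_subjects,) bool

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 5:
            raise ValueError("PathMatrix requires an (n_subjects, 5) array")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.data.shape[0], dtype=bool)
        if not np.allclose(self.data[:, _IDX["ab"]],
                           self.data[:, _IDX["a"]] * self.data[:, _IDX["b"]],
                           equal_nan=True):
            raise ValueError("ab column must equal elementwise a*b")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, _IDX[name]]

    @classmethod
    def from_rows(cls, rows) -> "PathMatrix":
        return cls(np.vstack(rows))


@dataclass
class BootstrapResult:
    """Percentile-bootstrap summary for the five path columns."""

    estimate: dict[str, float]
    ci: dict[str, tuple[float, float]]
    p: dict[str, float]
    se: dict[str, float]
    n_boot: int
    degenerate: bool = False


@dataclass
class MediationMaps:
    """Voxelwise mediation results: per-path effect, bootstrap p, CI, z."""

    estimate: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    ci_lo: dict[str, np.ndarray]
    ci_hi: dict[str, np.ndarray]
    z: dict[str, np.ndarray]
    shape: tuple[int, ...]
    n_subjects_used: np.ndarray = None
    dropped_subject_voxels: int = 0

    def volume(self, field_name: str, path: str) -> np.ndarray:
        return getattr(self, field_name)[path].reshape(self.shape)


@dataclass(frozen=True)
class ThresholdSpec:
    """Voxelwise threshold, cluster extent and small-volume-correction setup."""

    voxel_p: float = 0.001
    cluster_extent: int = 5
    connectivity: int = 26  # 6, 18 or 26 neighbours
    svc_centers: tuple = ((-2.0, 48.0, -16.0),   # ventromedial PFC
                          (12.0, 10.0, -16.0),   # ventral striatum
                          (28.0, 50.0, -8.0))    # anterior PFC
    svc_radius_mm: float = 10.0
    svc_alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must be in (0, 1)")
        if self.svc_radius_mm <= 0:
            raise ValueError("svc_radius_mm must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")


# ---------------------------------------------------------------------------
# Within-subject path fitting
# ---------------------------------------------------------------------------

def _design(x: np.ndarray, covariates) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(x):
            cov = cov.T
        cols.extend(cov.T)
    return np.column_stack(cols)


def fit_paths_batch(x, m, y, covariates=None):
    """Fit the three mediation regressions for many mediators at once.

    Parameters
    ----------
    x : (n,) cue contrast codes (non-constant)
    m : (n,) or (n, V) mediator values
    y : (n,) outcomes
    covariates : optional (n, q) covariates shared by all three equations

    Returns
    -------
    paths : (V, 5) array of [a, b, c, c', a*b]
    degenerate : (V,) bool, True where the mediator is (near-)constant
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    M = np.asarray(m, dtype=float)
    scalar = M.ndim == 1
    if scalar:
        M = M[:, None]
    n = len(x)
    if n < 10:
        raise ValueError("at least 10 complete trials are required")
    if np.ptp(x) == 0:
        raise ValueError("cue vector x is constant")

    Z = _design(x, covariates)          # (n, p0)
    p0 = Z.shape[1]
    pinvZ = np.linalg.pinv(Z)
    c_coef = pinvZ @ y                  # path c from y ~ x + cov
    a_coef = pinvZ @ M                  # (p0, V), path a from m ~ x + cov
    c = float(c_coef[1])
    a = a_coef[1, :]

    # Eq-3 normal equations, batched over mediator columns: X_v = [Z, m_v]
    G = Z.T @ Z                         # (p0, p0)
    U = Z.T @ M                         # (p0, V)
    s = np.einsum("nv,nv->v", M, M)     # (V,)
    Zy = Z.T @ y                        # (p0,)
    My = M.T @ y                        # (V,)
    V = M.shape[1]
    A = np.empty((V, p0 + 1, p0 + 1))
    A[:, :p0, :p0] = G
    A[:, :p0, p0] = U.T
    A[:, p0, :p0] = U.T
    A[:, p0, p0] = s

    m_var = M.var(axis=0)
    degenerate = m_var <= 1e-12 * max(1.0, float(np.max(m_var, initial=0.0)))
    rhs = np.empty((V, p0 + 1))
    rhs[:, :p0] = Zy
    rhs[:, p0] = My
    coefs = np.full((V, p0 + 1), np.nan)
    ok = ~degenerate
    if ok.any():
        try:
            coefs[ok] = np.linalg.solve(A[ok], rhs[ok][..., None])[..., 0]
        except np.linalg.LinAlgError:
            # a mediator exactly collinear with [x, cov] makes eq-3 singular;
            # flag those columns degenerate and solve the rest individually
            for v in np.flatnonzero(ok):
                try:
                    coefs[v] = np.linalg.solve(A[v], rhs[v])
                except np.linalg.LinAlgError:
                    degenerate[v] = True
                    coefs[v] = np.nan
    b = coefs[:, p0]
    cprime = coefs[:, 1]

    paths = np.column_stack([a, b, np.full(V, c), cprime, a * b])
    return (paths[0], bool(degenerate[0])) if scalar else (paths, degenerate)


def fit_subject_paths(x, m, y, covariates=None) -> np.ndarray:
    """One subject's [a, b, c, c', a*b] row; raises on a constant mediator."""
    row, degenerate = fit_paths_batch(x, m, y, covariates)
    if degenerate:
        raise ValueError("mediator m is constant or collinear with [x, cov]: "
                         "path b undefined (row flagged degenerate)")
    return row


# ---------------------------------------------------------------------------
# Group-level summary and bootstrap
# ---------------------------------------------------------------------------

def group_decompose(paths: PathMatrix) -> tuple[float, float, float]:
    """Decompose mean(a*b) into mean(a)*mean(b) + cov(a, b).

    The covariance uses the population (1/n) denominator so the identity
    holds exactly.
    """
    if paths.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    a = paths.column("a")
    b = paths.column("b")
    ab = paths.column("ab")
    mean_ab = float(np.mean(ab))
    mean_a_mean_b = float(np.mean(a) * np.mean(b))
    cov_ab = float(np.mean((a - a.mean()) * (b - b.mean())))
    return mean_ab, mean_a_mean_b, cov_ab


def expansion_factor(n: int, df: int | None = None) -> float:
    """Small-sample widening of the percentile bootstrap (Hesterberg 2015).

    The percentile interval of a mean is too narrow by the factor
    sqrt((n-1)/n) and uses z rather than t quantiles, which inflates
    two-tailed rejection rates noticeably below n ~ 30.  Scaling resampled
    deviations by ``sqrt(n/(n-1)) * t_{df,0.975} / z_0.975`` makes the
    percentile test match the t reference exactly under normality.
    """
    if df is None:
        df = n - 1
    return float(np.sqrt(n / (n - 1))
                 * stats.t.ppf(0.975, df) / stats.norm.ppf(0.975))


def _expand(boots: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return boots
    center = boots.mean(axis=0, keepdims=True)
    return center + factor * (boots - center)


def _p_from_boots(boots: np.ndarray, n_boot: int, factor: float = 1.0) -> np.ndarray:
    """Two-tailed p from the sign distribution of (expanded) bootstrap means.

    p = 2 * min(P(theta* <= 0), P(theta* >= 0)); exact zeros count on both
    sides; floored at 2/n_boot and capped at 1.  ``factor`` applies the
    small-sample expansion of :func:`expansion_factor`.
    """
    boots = _expand(boots, factor)
    p_lo = np.mean(boots <= 0, axis=0)
    p_hi = np.mean(boots >= 0, axis=0)
    p = 2.0 * np.minimum(p_lo, p_hi)
    return np.clip(p, 2.0 / n_boot, 1.0)


def bootstrap_inference(paths: PathMatrix, n_boot: int = 10_000, seed: int = 0,
                        ci_level: float = 0.95) -> BootstrapResult:
    """Percentile bootstrap over subjects for every path column.

    Whole subject rows are resampled with replacement; each resample
    contributes the mean of each column.  For the indirect effect the mean of
    the a*b column equals mean(a)*mean(b) + cov(a, b) of the resample (1/n
    covariance), so the resampled statistic is the multilevel indirect effect.
    """
    if paths.n_subjects < 5:
        raise ValueError("bootstrap requires at least 5 subjects")
    rng = np.random.default_rng(seed)
    S = paths.n_subjects
    idx = rng.integers(0, S, size=(n_boot, S))
    boots = _expand(paths.data[idx].mean(axis=1), expansion_factor(S))  # (n_boot, 5)
    est = paths.data.mean(axis=0)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    ci = np.quantile(boots, [lo_q, hi_q], axis=0)
    p = _p_from_boots(boots, n_boot)
    se = boots.std(axis=0, ddof=1)
    degenerate = bool(np.all(np.ptp(paths.data, axis=0) == 0))
    return BootstrapResult(
        estimate={k: float(est[i]) for k, i in _IDX.items()},
        ci={k: (float(ci[0, i]), float(ci[1, i])) for k, i in _IDX.items()},
        p={k: float(p[i]) for k, i in _IDX.items()},
        se={k: float(se[i]) for k, i in _IDX.items()},
        n_boot=n_boot,
        degenerate=degenerate,
    )


def voxelwise_mediation(subject_data, n_boot: int = 1000, seed: int = 0,
                        shape: tuple[int, ...] | None = None,
                        ci_level: float = 0.95) -> MediationMaps:
    """Mass-univariate two-level mediation across a voxel grid.

    Parameters
    ----------
    subject_data : sequence of (x, M, y, covariates) tuples, one per subject,
        with M of shape (n_trials, V); all subjects must share V.
    shape : optional 3-D grid shape for reshaping output maps (prod = V).

    Subjects whose mediator is degenerate at a voxel are dropped at that voxel
    only; the total number of dropped (subject, voxel) pairs is recorded.
    """
    rows = []
    degen = []
    for x, M, y, cov in subject_data:
        M = np.asarray(M, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        paths, d = fit_paths_batch(x, M, y, cov)
        rows.append(paths)
        degen.append(d)
    P = np.stack(rows)                    # (S, V, 5)
    D = np.stack(degen)                   # (S, V)
    S, V, _ = P.shape
    if shape is not None and int(np.prod(shape)) != V:
        raise ValueError("shape does not match the voxel count")
    out_shape = shape if shape is not None else (V,)

    P = np.where(D[:, :, None], np.nan, P)
    valid = ~np.isnan(P[:, :, 0])         # (S, V)
    n_used = valid.sum(axis=0)
    if np.any(n_used < 2):
        raise ValueError("fewer than 2 non-degenerate subjects at some voxel")

    est = np.nanmean(P, axis=0)           # (V, 5)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, S, size=(n_boot, S))
    counts = np.zeros((n_boot, S))
    np.add.at(counts, (np.arange(n_boot)[:, None], idx), 1.0)
    Pz = np.nan_to_num(P)                     # (S, V, 5)
    Mz = np.broadcast_to(valid[:, :, None], (S, V, 5)).astype(float)
    factor = expansion_factor(S)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2

    ci = np.empty((2, V, 5))
    p = np.empty((V, 5))
    se = np.empty((V, 5))
    # chunk over voxels so the (n_boot, chunk, 5) resample block stays small
    chunk = max(1, int(2.5e8 / (n_boot * 5 * 8)))
    for v0 in range(0, V, chunk):
        v1 = min(v0 + chunk, V)
        w = v1 - v0
        num = counts @ Pz[:, v0:v1].reshape(S, w * 5)
        den = counts @ Mz[:, v0:v1].reshape(S, w * 5)
        boots = _expand((num / den).reshape(n_boot, w, 5), factor)
        ci[:, v0:v1] = np.quantile(boots, [lo_q, hi_q], axis=0)
        p[v0:v1] = _p_from_boots(boots, n_boot)
        se[v0:v1] = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, 0.0)

    def bypath(arr):
        return {k: arr[:, i].reshape(out_shape) for k, i in _IDX.items()}

    return MediationMaps(
        estimate=bypath(est), p=bypath(p),
        ci_lo=bypath(ci[0]), ci_hi=bypath(ci[1]), z=bypath(z),
        shape=out_shape,
        n_subjects_used=n_used.reshape(out_shape),
        dropped_subject_voxels=int(D.sum()),
    )


# ---------------------------------------------------------------------------
# Thresholding, small-volume correction, classification
# ---------------------------------------------------------------------------

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def threshold_and_cluster(maps: MediationMaps, spec: ThresholdSpec = ThresholdSpec(),
                          path: str = "ab",
                          grid: VolumeGrid | None = None
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Label suprathreshold voxels into clusters and drop small clusters.

    Voxels with bootstrap p below ``spec.voxel_p`` are labelled into connected
    components (default 26-connectivity); clusters smaller than
    ``spec.cluster_extent`` voxels are removed.  Returns the label volume and
    a table with cluster size, peak voxel (max |z|), and peak statistics.
    An empty suprathreshold set yields an empty table.
    """
    if len(maps.shape) != 3:
        raise ValueError("cluster analysis requires maps on a 3-D grid")
    pvol = maps.volume("p", path)
    zvol = maps.volume("z", path)
    evol = maps.volume("estimate", path)
    supra = pvol < spec.voxel_p
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[spec.connectivity])
    # positive and negative effects form separate clusters: a signed map's
    # components should not merge across a zero crossing
    pieces = []
    for mask in (supra & (evol > 0), supra & (evol <= 0)):
        labels, n_lab = ndimage.label(mask, structure=structure)
        pieces.append((labels, n_lab))
    records = []
    out_labels = np.zeros(supra.shape, dtype=int)
    kept = 0
    for labels, n_lab in pieces:
        for lab in range(1, n_lab + 1):
            members = np.argwhere(labels == lab)
            if len(members) < spec.cluster_extent:
                continue
            kept += 1
            out_labels[labels == lab] = kept
            zvals = zvol[members[:, 0], members[:, 1], members[:, 2]]
            peak = members[np.argmax(np.abs(zvals))]
            rec = {
                "cluster": kept,
                "size": int(len(members)),
                "peak_i": int(peak[0]), "peak_j": int(peak[1]), "peak_k": int(peak[2]),
                "peak_z": float(zvol[tuple(peak)]),
                "peak_p": float(pvol[tuple(peak)]),
            }
            if grid is not None:
                from .volumes import voxel_to_mm
                mm = voxel_to_mm(peak, grid)
                rec.update({"peak_x_mm": float(mm[0]), "peak_y_mm": float(mm[1]),
                            "peak_z_mm": float(mm[2])})
            records.append(rec)
    table = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["cluster", "size", "peak_i", "peak_j", "peak_k", "peak_z", "peak_p"])
    return out_labels, table


def small_volume_correct(maps: MediationMaps, center_mm, grid: VolumeGrid,
                         radius_mm: float = 10.0, alpha: float = 0.05,
                         path: str = "ab") -> dict:
    """Bonferroni small-volume correction within a sphere ROI.

    The minimum uncorrected bootstrap p inside the 10-mm sphere is multiplied
    by the number of in-sphere voxels (capped at 1).  This is a deliberately
    conservative, dependency-free alternative to random-field-theory FWE.
    """
    try:
        sphere = make_sphere(center_mm, radius_mm, grid)
    except ValueError as err:
        raise ValueError(f"SVC sphere at {tuple(center_mm)}: {err}") from err
    pvol = maps.volume("p", path)
    vox = sphere.voxels
    pvals = pvol[vox[:, 0], vox[:, 1], vox[:, 2]]
    i_min = int(np.argmin(pvals))
    p_corr = min(1.0, float(pvals[i_min]) * sphere.n_voxels)
    return {
        "center_mm": tuple(float(c) for c in center_mm),
        "radius_mm": float(radius_mm),
        "n_voxels": sphere.n_voxels,
        "min_p_uncorrected": float(pvals[i_min]),
        "p_corrected": p_corr,
        "significant": bool(p_corr <= alpha),
        "peak_voxel": tuple(int(v) for v in vox[i_min]),
        "path": path,
    }


def classify_mediation(maps: MediationMaps, voxel, alpha: float = 0.05) -> str:
    """Classify a voxel as 'full', 'partial' or 'none' mediation.

    A significant indirect effect (a*b) with a still-significant direct path
    c' indicates partial mediation; a significant indirect effect with a
    non-significant c' indicates full mediation.
    """
    voxel = tuple(voxel) if len(maps.shape) == 3 else (int(np.atleast_1d(voxel)[0]),)
    p_ab = float(maps.volume("p", "ab")[voxel])
    p_cp = float(maps.volume("p", "cprime")[voxel])
    if p_ab < alpha:
        return "partial" if p_cp < alpha else "full"
    return "none"


def prepare_mediation_inputs(trials: pd.DataFrame, betas, ratings=None,
                             x_coding: str = "extremes",
                             included: np.ndarray | None = None):
    """Assemble (x, M, y, covariates) for one subject from a trial table.

    Applies listwise exclusion (QC-excluded trials) and, in ``extremes``
    coding, drops middle-price trials so x is +-1; ``linear`` coding keeps
    all levels with a centred linear code.  Wine and payment enter as
    covariates of no interest.
    """
    from .synth import price_contrast

    n = len(trials)
    M = np.asarray(betas, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[0] != n:
        raise ValueError("betas must have one row per trial")
    y = np.asarray(ratings if ratings is not None else trials["rating"], dtype=float)
    price = trials["price"].to_numpy()
    keep = np.ones(n, dtype=bool)
    if included is not None:
        keep &= np.asarray(included, dtype=bool)
    if "included" in trials:
        keep &= trials["included"].to_numpy().astype(bool)
    if x_coding == "extremes":
        x = price_contrast(price)
        keep &= x != 0
    elif x_coding == "linear":
        x = price - price.mean()
    else:
        raise ValueError("x_coding must be 'extremes' or 'linear'")
    cov = np.column_stack([trials["wine"].to_numpy(), trials["payment"].to_numpy()])
    return x[keep], M[keep], y[keep], cov[keep].astype(float)
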