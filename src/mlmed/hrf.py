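"""Canonical double-gamma hemodynamic response function and boxcar convolution.

The canonical HRF is the difference of two gamma densities: a response peaking
at 6 s and an undershoot peaking at 16 s, scaled 6:1, truncated at 32 s.  Both
gamma components use unit dispersion (shape = peak delay in seconds).  The
kernel is normalised to unit peak so that a unit-amplitude event produces a
regressor with maximum 1 before boxcar convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma


@dataclass(frozen=True)
class HrfSpec:
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0
    dt_s: float = 0.1  # internal convolution grid


def canonical_hrf(spec: HrfSpec = HrfSpec(), dt_s: float | None = None) -> np.ndarray:
    """Sample the double-gamma HRF on the internal grid (unit peak)."""
    dt = spec.dt_s if dt_s is None else dt_s
    t = np.arange(0, spec.length_s + dt / 2, dt)
    h = (_gamma.pdf(t, spec.peak_delay_s, scale=1.0)
         - _gamma.pdf(t, spec.undershoot_delay_s, scale=1.0) / spec.peak_undershoot_ratio)
    return h / h.max()


def convolve_boxcar(onsets_s: np.ndarray, duration_s: float, n_scans: int, tr_s: float,
                    amplitudes: np.ndarray | None = None,
                    spec: HrfSpec = HrfSpec()) -> np.ndarray:
    """HRF-convolved boxcar regressors sampled at the TR grid.

    Events are rendered on a fine internal grid (``spec.dt_s``), convolved with
    the canonical HRF and resampled at scan times ``0, TR, 2*TR, ...``.  A zero
    duration degenerates to a unit impulse (delta event).

    Parameters
    ----------
    onsets_s : event onsets in seconds from run start
    duration_s : boxcar duration (seconds); 0 gives an impulse
    n_scans : number of volumes in the run
    tr_s : repetition time
    amplitudes : optional per-event amplitude (default 1)

    Returns
    -------
    (n_scans, n_events) array, one column per event.
    """
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    if amplitudes is None:
        amplitudes = np.ones_like(onsets_s)
    amplitudes = np.asarray(amplitudes, dtype=float)
    dt = spec.dt_s
    h = canonical_hrf(spec)
    n_fine = int(np.ceil(n_scans * tr_s / dt)) + len(h) + 1
    cols = np.zeros((n_scans, len(onsets_s)))
    scan_idx = np.round(np.arange(n_scans) * tr_s / dt).astype(int)
    n_box = max(1, int(round(duration_s / dt)))
    for j, (on, amp) in enumerate(zip(onsets_s, amplitudes)):
        stick = np.zeros(n_fine)
        i0 = int(round(on / dt))
        if i0 >= n_fine:
            continue
        stick[i0:min(i0 + n_box, n_fine)] = amp
        conv = np.convolve(stick, h)[:n_fine]
        cols[:, j] = conv[scan_idx]
    return cols
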