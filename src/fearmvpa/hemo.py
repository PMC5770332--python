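"""Canonical haemodynamic response function and event regressor construction.

Regressors are built on a fine microtime grid (default 0.1 s), convolving a
boxcar per event with a double-gamma HRF, then sampled at scan acquisition
times referenced to mid-volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HrfParams", "canonical_hrf", "event_regressor", "trial_regressors"]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF parameters (peak minus scaled undershoot)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0

    def validate(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "peak_undershoot_ratio",
                     "kernel_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


DEFAULT_HRF = HrfParams()


def canonical_hrf(dt: float, params: HrfParams = DEFAULT_HRF) -> np.ndarray:
    """Sample the double-gamma HRF at spacing ``dt``, peak scaled to 1.

    The kernel is the difference of two gamma densities: a positive response
    peaking at ``peak_delay`` and an undershoot peaking at
    ``undershoot_delay``, down-weighted by ``peak_undershoot_ratio``.
    """
    if not 0.0 < dt <= 1.0:
        raise ValueError("dt must be in (0, 1] seconds")
    params.validate()
    t = np.arange(0.0, params.kernel_length + dt / 2, dt)
    peak = stats.gamma.pdf(t, params.peak_delay / params.peak_dispersion,
                           scale=params.peak_dispersion)
    under = stats.gamma.pdf(t, params.undershoot_delay / params.undershoot_dispersion,
                            scale=params.undershoot_dispersion)
    h = peak - under / params.peak_undershoot_ratio
    return h / h.max()


def event_regressor(onsets: np.ndarray, duration: float, n_scans: int,
                    tr: float, params: HrfParams = DEFAULT_HRF,
                    dt: float = 0.1, sample_offset: float = 0.5) -> np.ndarray:
    """HRF-convolved boxcar regressor for a set of events, pooled in one column.

    Built on a ``dt`` microtime grid and sampled at ``(i + sample_offset) * tr``
    (mid-volume reference by default).  Onsets are snapped to the microtime
    grid.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    run_len = n_scans * tr
    if onsets.size and onsets.max() + duration > run_len + 1e-9:
        raise ValueError("run too short: an event extends past the last scan")
    n_fine = int(np.ceil(run_len / dt)) + 1
    stick = np.zeros(n_fine)
    width = max(1, int(round(duration / dt)))
    for on in onsets:
        i0 = int(round(on / dt))
        stick[i0:i0 + width] += 1.0
    kernel = canonical_hrf(dt, params)
    fine = np.convolve(stick, kernel)[:n_fine] * dt
    scan_idx = np.clip(np.round((np.arange(n_scans) + sample_offset) * tr / dt)
                       .astype(int), 0, n_fine - 1)
    return fine[scan_idx]


def trial_regressors(onsets: np.ndarray, duration: float, n_scans: int,
                     tr: float, params: HrfParams = DEFAULT_HRF,
                     dt: float = 0.1, sample_offset: float = 0.5) -> np.ndarray:
    """One regressor column per event: ``[n_scans, n_events]``.

    All events share one boxcar duration, so the convolved response shape is
    computed once and placed at each (grid-snapped) onset.
    """
    onsets = np.asarray(onsets, dtype=float)
    run_len = n_scans * tr
    if onsets.size and onsets.max() + duration > run_len + 1e-9:
        raise ValueError("run too short: an event extends past the last scan")
    n_fine = int(np.ceil(run_len / dt)) + 1
    width = max(1, int(round(duration / dt)))
    kernel = canonical_hrf(dt, params)
    shape = np.convolve(np.ones(width), kernel) * dt
    scan_idx = np.clip(np.round((np.arange(n_scans) + sample_offset) * tr / dt)
                       .astype(int), 0, n_fine - 1)
    out = np.zeros((n_scans, onsets.size))
    for j, on in enumerate(onsets):
        fine = np.zeros(n_fine)
        i0 = int(round(on / dt))
        seg = shape[: max(0, n_fine - i0)]
        fine[i0:i0 + seg.size] = seg
        out[:, j] = fine[scan_idx]
    return out
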