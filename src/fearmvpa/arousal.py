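"""Model-based estimation of per-trial anticipatory sympathetic arousal.

A canonical skin-conductance response function (gamma-difference kernel) is
fitted jointly to the whole trace: one non-negative amplitude per trial,
with the burst onset latency optimized on a 0.25 s grid inside a 0-3.5 s
window after each sound onset.  Raw amplitudes are z-normalized within
subject across all usable (non-reinforced) trials before condition
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

if TYPE_CHECKING:  # pragma: no cover
    from .synth.design import ExperimentDesign
    from .synth.scr import ScrTrace

__all__ = ["ScrfParams", "ScrAmplitudes", "canonical_scrf",
           "estimate_trial_amplitudes", "normalize_and_aggregate"]


@dataclass(frozen=True)
class ScrfParams:
    """Gamma-difference skin-conductance response kernel parameters.

    Defaults put the kernel peak near 3.4 s after burst onset.
    """

    shape1: float = 3.0
    scale1: float = 1.75
    shape2: float = 8.0
    scale2: float = 1.75
    ratio: float = 0.2
    kernel_length: float = 20.0
    latency_window: tuple[float, float] = (0.0, 3.5)
    latency_step: float = 0.25

    def validate(self) -> None:
        lo, hi = self.latency_window
        if not lo < hi:
            raise ValueError("latency window start must precede its end")
        if self.kernel_length <= 0 or self.latency_step <= 0:
            raise ValueError("kernel_length and latency_step must be > 0")


DEFAULT_SCRF = ScrfParams()


def canonical_scrf(sample_rate: float,
                   params: ScrfParams = DEFAULT_SCRF) -> np.ndarray:
    """Sample the canonical SCR kernel at ``sample_rate``, peak scaled to 1."""
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    params.validate()
    t = np.arange(0.0, params.kernel_length, 1.0 / sample_rate)
    h = (stats.gamma.pdf(t, params.shape1, scale=params.scale1)
         - params.ratio * stats.gamma.pdf(t, params.shape2, scale=params.scale2))
    peak = h.max()
    if peak <= 0:
        raise ValueError("kernel must be positive at its peak")
    return h / peak


@dataclass
class ScrAmplitudes:
    """Per-trial sudomotor burst amplitudes and condition aggregates."""

    raw: np.ndarray
    latencies: np.ndarray
    trial_metadata: pd.DataFrame
    included: np.ndarray                       # bool; False for reinforced (US) trials
    normalized: np.ndarray | None = None
    condition_means: dict = field(default_factory=dict)
    learning_index: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.trial_metadata.copy()
        df["amplitude"] = self.raw
        df["latency"] = self.latencies
        df["included"] = self.included.astype(int)
        if self.normalized is not None:
            df["amplitude_z"] = self.normalized
        return df


def _latency_grid(params: ScrfParams) -> np.ndarray:
    lo, hi = params.latency_window
    return np.arange(lo, hi + 1e-9, params.latency_step)


def _regressor(n: int, onset_idx: int, kernel: np.ndarray) -> np.ndarray:
    col = np.zeros(n)
    if onset_idx >= n:
        return col
    seg = kernel[: n - onset_idx]
    col[onset_idx: onset_idx + seg.size] = seg
    return col


def estimate_trial_amplitudes(trace: "ScrTrace", design: "ExperimentDesign",
                              params: ScrfParams = DEFAULT_SCRF,
                              max_iter: int = 10,
                              nonnegative: bool = True) -> ScrAmplitudes:
    """Joint fit of one SCR burst per trial.

    Latencies are optimized per trial by deterministic coordinate descent
    over the latency grid (closed-form 1-D updates), followed by a joint
    refit at the selected latencies.  Amplitudes are constrained >= 0 by
    default (a sudomotor burst is physically non-negative); set
    ``nonnegative=False`` for an unconstrained least-squares fit.
    """
    params.validate()
    y = np.asarray(trace.signal, dtype=float)
    fs = trace.sample_rate
    n = y.size
    onsets = design.onsets
    if n / fs < onsets[-1] + params.latency_window[1]:
        raise ValueError("trace shorter than the design's trial windows")

    kernel = canonical_scrf(fs, params)
    kk = kernel @ kernel
    grid = _latency_grid(params)
    n_trials = len(onsets)

    # candidate regressor start index per (trial, latency)
    starts = np.round((onsets[:, None] + grid[None, :]) * fs).astype(int)

    lat_idx = np.zeros(n_trials, dtype=int)
    amp = np.zeros(n_trials)
    model = np.zeros(n)

    for _ in range(max_iter):
        changed = False
        for i in range(n_trials):
            cur = _regressor(n, starts[i, lat_idx[i]], kernel) * amp[i]
            resid = y - (model - cur)
            best = (np.inf, lat_idx[i], amp[i])
            for g in range(grid.size):
                col = _regressor(n, starts[i, g], kernel)
                a = (resid @ col) / kk
                if nonnegative:
                    a = max(0.0, a)
                sse = resid @ resid - 2 * a * (resid @ col) + a * a * kk
                if sse < best[0] - 1e-12:
                    best = (sse, g, a)
            if best[1] != lat_idx[i] or abs(best[2] - amp[i]) > 1e-12:
                changed = True
            model = model - cur
            lat_idx[i], amp[i] = best[1], best[2]
            model = model + _regressor(n, starts[i, lat_idx[i]], kernel) * amp[i]
        if not changed:
            break

    X = np.column_stack([_regressor(n, starts[i, lat_idx[i]], kernel)
                         for i in range(n_trials)])
    if nonnegative:
        amp, _ = nnls(X, y)
    else:
        amp, *_ = np.linalg.lstsq(X, y, rcond=None)

    meta = design.to_frame()
    included = ~meta["reinforced"].astype(bool).to_numpy()
    return ScrAmplitudes(raw=amp, latencies=grid[lat_idx],
                         trial_metadata=meta, included=included)


def normalize_and_aggregate(raw: ScrAmplitudes,
                            design: "ExperimentDesign | None" = None) -> ScrAmplitudes:
    """Z-normalize within subject and compute condition means.

    Normalization uses all included (non-US) trials; condition means cover
    the (role, complexity) cells and the learning index per complexity is
    mean(CS+) - mean(CS-).
    """
    inc = raw.included
    vals = raw.raw[inc]
    if inc.sum() < 2:
        raise ValueError("need at least 2 included trials")
    sd = vals.std()
    if sd <= 1e-10 * max(1.0, float(np.abs(vals).max())):
        raise ValueError("zero variance across included trials; cannot normalize")
    z = np.full_like(raw.raw, np.nan, dtype=float)
    z[inc] = (vals - vals.mean()) / sd

    meta = raw.trial_metadata
    cond_means: dict = {}
    for (role, complexity), sub in meta[inc].assign(z=z[inc]).groupby(
            ["trial_type", "complexity"]):
        cond_means[(role, complexity)] = float(sub["z"].mean())
    learning = {}
    for complexity in meta["complexity"].unique():
        learning[complexity] = (cond_means.get(("CS+", complexity), np.nan)
                                - cond_means.get(("CS-", complexity), np.nan))
    return ScrAmplitudes(raw=raw.raw, latencies=raw.latencies,
                         trial_metadata=meta, included=inc, normalized=z,
                         condition_means=cond_means, learning_index=learning)
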