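"""Synthetic skin-conductance traces with per-trial anticipatory bursts."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExperimentDesign

__all__ = ["ScrTrace", "simulate_scr"]

DEFAULT_SAMPLE_RATE = 10.0  # Hz; the estimator is rate-agnostic


@dataclass
class ScrTrace:
    """A conductance time series (microsiemens) and its ground truth."""

    signal: np.ndarray
    sample_rate: float
    ground_truth_amplitudes: np.ndarray
    ground_truth_latencies: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("trace must be finite")

    def save(self, path: str | Path) -> None:
        t = np.arange(self.signal.size) / self.sample_rate
        pd.DataFrame({"time": t, "conductance": self.signal}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ScrTrace":
        df = pd.read_csv(path, sep="\t")
        t = df["time"].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        sig = df["conductance"].to_numpy(dtype=float)
        return cls(signal=sig, sample_rate=float(fs),
                   ground_truth_amplitudes=np.full(0, np.nan),
                   ground_truth_latencies=np.full(0, np.nan))


def simulate_scr(design: ExperimentDesign,
                 amp_by_condition: dict[str, float],
                 noise_sd: float = 0.0,
                 seed: int | None = None,
                 sample_rate: float = DEFAULT_SAMPLE_RATE,
                 amp_sd: float = 0.0,
                 latency: float = 0.0,
                 latency_jitter: bool = False,
                 scrf_params=None) -> ScrTrace:
    """Place one amplitude-scaled SCR kernel per trial, plus Gaussian noise.

    ``amp_by_condition`` maps trial role (CS+, CS-, NS1, NS2) to the mean
    burst amplitude; per-trial amplitudes are drawn Normal(mean, amp_sd)
    truncated at 0.  Burst onset latency is ``latency`` seconds after sound
    onset, or drawn from the 0.25 s estimation grid inside [0, 3.5] s when
    ``latency_jitter`` is set.  Deterministic given ``seed``.
    """
    from ..arousal import DEFAULT_SCRF, canonical_scrf

    params = scrf_params or DEFAULT_SCRF
    if any(v < 0 for v in amp_by_condition.values()):
        raise ValueError("condition amplitudes must be >= 0")
    itis = np.diff(design.onsets) - design.params.stim_duration
    if itis.size and itis.min() < 1.0:
        raise ValueError("kernel placement undefined for ITI < 1 s")
    lo, hi = params.latency_window
    if not lo <= latency <= hi:
        raise ValueError("latency must lie inside the latency window")

    rng = np.random.default_rng(seed)
    kernel = canonical_scrf(sample_rate, params)
    onsets = design.onsets
    n = int(np.ceil((onsets[-1] + hi + params.kernel_length + 5.0) * sample_rate))
    sig = np.zeros(n)

    grid = np.arange(lo, hi + 1e-9, params.latency_step)
    amps = np.zeros(design.n_trials)
    lats = np.zeros(design.n_trials)
    for i, t in enumerate(design.trials):
        mean = amp_by_condition.get(t.role, 0.0)
        a = mean if amp_sd == 0 else max(0.0, rng.normal(mean, amp_sd))
        lat = float(rng.choice(grid)) if latency_jitter else latency
        amps[i], lats[i] = a, lat
        i0 = int(round((t.onset + lat) * sample_rate))
        seg = kernel[: max(0, n - i0)]
        sig[i0:i0 + seg.size] += a * seg

    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=n)

    return ScrTrace(signal=sig, sample_rate=sample_rate,
                    ground_truth_amplitudes=amps, ground_truth_latencies=lats)
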