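"""Synthetic 4-D BOLD series with planted multivoxel patterns.

Each trial contributes an HRF-convolved boxcar response whose multivoxel
amplitude is the sum of a stimulus-identity pattern (present for every
stimulus, across the whole simulated gray-matter mask) and, for CS+ trials,
threat patterns confined to a designated ROI: one shared across
complexities and one specific per complexity (orthogonal between
complexities).  Low-frequency sinusoidal drift and Gaussian (optionally
AR(1)) noise are added on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..hemo import DEFAULT_HRF, HrfParams, trial_regressors
from .design import COMPLEXITIES, ExperimentDesign

__all__ = ["EffectSpec", "BoldSeries", "make_roi_labels", "random_effects",
           "simulate_bold"]

DEFAULT_GRID = (12, 12, 12)
DEFAULT_VOXEL_SIZE = 1.5  # mm isotropic


def make_roi_labels(shape: tuple[int, int, int] = DEFAULT_GRID,
                    roi_voxels: dict[int, int] | None = None) -> np.ndarray:
    """Integer label image with compact cubic ROIs in distinct corners.

    Default: three 64-voxel ROIs (labels 1..3).  Label 0 is background.
    """
    roi_voxels = roi_voxels or {1: 64, 2: 64, 3: 64}
    labels = np.zeros(shape, dtype=np.int16)
    sides = {label: int(np.ceil(n ** (1.0 / 3.0)))
             for label, n in roi_voxels.items()}
    corner_fns = [
        lambda s: (1, 1, 1),
        lambda s: (shape[0] - s - 1, 1, 1),
        lambda s: (1, shape[1] - s - 1, shape[2] - s - 1),
        lambda s: (shape[0] - s - 1, shape[1] - s - 1, shape[2] - s - 1),
    ]
    for (label, n), corner_fn in zip(sorted(roi_voxels.items()), corner_fns):
        side = sides[label]
        corner = corner_fn(side)
        if min(corner) < 0:
            raise ValueError(f"grid too small for ROI {label} of {n} voxels")
        filled = 0
        for dx in range(side):
            for dy in range(side):
                for dz in range(side):
                    if filled >= n:
                        break
                    x, y, z = corner[0] + dx, corner[1] + dy, corner[2] + dz
                    if labels[x, y, z] == 0:
                        labels[x, y, z] = label
                        filled += 1
        if filled < n:
            raise ValueError(f"grid too small for ROI {label} of {n} voxels")
    return labels


@dataclass
class EffectSpec:
    """Generative multivoxel effect structure over a labelled grid."""

    labels: np.ndarray
    stimulus_patterns: dict[int, np.ndarray]          # over mask voxels, unit norm
    threat_pattern_shared: np.ndarray                 # over mask voxels, ROI support
    threat_pattern_specific: dict[str, np.ndarray]    # per complexity, ROI support
    stim_amplitude: float = 1.0
    threat_shared_amplitude: float = 0.0
    threat_specific_amplitude: float = 0.0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0
    drift_period: float = 300.0
    ar_rho: float = 0.0
    boxcar_duration: float = 3.5
    threat_roi: int = 1
    voxel_size: float = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("standard deviations/amplitudes must be >= 0")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be > 0")
        n_mask = int((self.labels > 0).sum())
        for sid, p in self.stimulus_patterns.items():
            if p.shape != (n_mask,):
                raise ValueError(f"stimulus pattern {sid} has wrong length")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def trial_amplitudes(self, design: ExperimentDesign) -> np.ndarray:
        """Planted multivoxel amplitude per trial: ``[n_trials, n_mask]``."""
        A = np.zeros((design.n_trials, int(self.mask.sum())))
        for i, t in enumerate(design.trials):
            a = self.stim_amplitude * self.stimulus_patterns[t.stimulus_id]
            if t.role == "CS+":
                a = a + self.threat_shared_amplitude * self.threat_pattern_shared
                a = a + (self.threat_specific_amplitude
                         * self.threat_pattern_specific[t.complexity])
            A[i] = a
        return A


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero pattern vector")
    return v / n


def random_effects(labels: np.ndarray | None = None, seed: int | None = None,
                   **kwargs) -> EffectSpec:
    """Draw unit-norm Gaussian patterns over a labelled grid.

    Threat patterns are supported on the threat ROI only; the two
    complexity-specific patterns are orthogonalized against each other and
    against the shared pattern.
    """
    labels = labels if labels is not None else make_roi_labels()
    rng = np.random.default_rng(seed)
    mask = labels > 0
    n_mask = int(mask.sum())
    threat_roi = kwargs.get("threat_roi", 1)
    roi_sel = labels[mask] == threat_roi

    stim_patterns = {sid: _unit(rng.standard_normal(n_mask))
                     for sid in range(1, 9)}

    def roi_pattern() -> np.ndarray:
        v = np.zeros(n_mask)
        v[roi_sel] = rng.standard_normal(int(roi_sel.sum()))
        return _unit(v)

    shared = roi_pattern()
    spec_a = roi_pattern()
    spec_a = _unit(spec_a - (spec_a @ shared) * shared)
    spec_b = roi_pattern()
    spec_b = _unit(spec_b - (spec_b @ shared) * shared - (spec_b @ spec_a) * spec_a)

    return EffectSpec(labels=labels, stimulus_patterns=stim_patterns,
                      threat_pattern_shared=shared,
                      threat_pattern_specific={COMPLEXITIES[0]: spec_a,
                                               COMPLEXITIES[1]: spec_b},
                      **kwargs)


@dataclass
class BoldSeries:
    """Simulated 4-D BOLD data with its generative ground truth."""

    data: np.ndarray                   # [x, y, z, time]
    tr: float
    roi_labels: np.ndarray
    design: ExperimentDesign
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        last_onset = self.design.trials[-1].onset
        if self.data.shape[3] * self.tr < last_onset + 30.0:
            raise ValueError("run truncates the final trial's response window")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    def save(self, bold_path: str | Path, labels_path: str | Path) -> None:
        import nibabel as nib

        vs = self.ground_truth.get("voxel_size", DEFAULT_VOXEL_SIZE)
        affine = np.diag([vs, vs, vs, 1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine,
                                 dtype=np.float32), str(bold_path))
        nib.save(nib.Nifti1Image(self.roi_labels.astype(np.int16), affine,
                                 dtype=np.int16), str(labels_path))


def simulate_bold(design: ExperimentDesign, spec: EffectSpec,
                  seed: int | None = None, tr: float = 2.5,
                  hrf: HrfParams = DEFAULT_HRF,
                  n_scans: int | None = None, dt: float = 0.1) -> BoldSeries:
    """Simulate a BOLD run for one subject; deterministic given ``seed``."""
    onsets = design.onsets
    min_scans = int(np.ceil((onsets[-1] + 30.0) / tr))
    if n_scans is None:
        n_scans = min_scans
    elif n_scans < min_scans:
        raise ValueError("n_scans would truncate the final trial's response window")

    rng = np.random.default_rng(seed)
    shape = spec.labels.shape
    mask = spec.mask
    n_vox = int(np.prod(shape))

    R = trial_regressors(onsets, spec.boxcar_duration, n_scans, tr, hrf, dt=dt)
    A = spec.trial_amplitudes(design)
    signal = R @ A                                   # [n_scans, n_mask]

    data = np.zeros(shape + (n_scans,))
    if spec.noise_sd > 0:
        noise = rng.standard_normal((n_vox, n_scans)) * spec.noise_sd
        if spec.ar_rho:
            rho = spec.ar_rho
            noise[:, 0] /= np.sqrt(1 - rho ** 2)
            for k in range(1, n_scans):
                noise[:, k] += rho * noise[:, k - 1]
        data += noise.reshape(shape + (n_scans,))
    if spec.drift_amplitude > 0:
        t = (np.arange(n_scans) + 0.5) * tr
        phase = rng.uniform(0, 2 * np.pi, size=n_vox).reshape(shape)
        data += spec.drift_amplitude * np.sin(
            2 * np.pi * t / spec.drift_period + phase[..., None])
    data[mask] += signal.T

    gt = {"effect_spec": spec, "trial_amplitudes": A, "seed": seed,
          "voxel_size": spec.voxel_size}
    return BoldSeries(data=data, tr=tr, roi_labels=spec.labels,
                      design=design, ground_truth=gt)
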