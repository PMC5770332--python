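"""Single-trial BOLD amplitude estimation (least-squares-all GLM).

One regressor per trial (3.5 s boxcar convolved with the canonical HRF),
one pooled regressor for the aversive stimulation, a DCT high-pass basis
(cut-off 128 s) plus intercept, and optional nuisance columns, fitted
jointly per voxel by ordinary least squares.  Responses of reinforced
trials are estimated but flagged unusable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .hemo import DEFAULT_HRF, HrfParams, event_regressor, trial_regressors

if TYPE_CHECKING:  # pragma: no cover
    from .synth.bold import BoldSeries
    from .synth.design import ExperimentDesign

logger = logging.getLogger(__name__)

__all__ = ["TrialDesignMatrix", "BetaSeries", "dct_basis",
           "build_design_matrix", "estimate_betas"]

US_DURATION = 0.5  # seconds; electric stimulation co-terminating with CS+


def dct_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass basis: columns with period >= ``cutoff``.

    Returns ``[n_scans, K]`` with ``K = floor(2 * n_scans * tr / cutoff)``;
    columns are orthonormal and orthogonal to the constant.
    """
    K = int(np.floor(2.0 * n_scans * tr / cutoff))
    n = np.arange(n_scans)
    cols = [np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * n + 1) * k / (2 * n_scans))
            for k in range(1, K + 1)]
    return np.column_stack(cols) if cols else np.zeros((n_scans, 0))


@dataclass
class TrialDesignMatrix:
    matrix: np.ndarray                 # [n_scans, n_regressors]
    column_roles: list[str]            # "trial:i", "US", "intercept", "dct:k", "nuisance:j"
    boxcar_duration: float
    highpass_cutoff: float
    tr: float

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.column_roles):
            raise ValueError("column_roles length must equal regressor count")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def trial_columns(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.column_roles)
                         if r.startswith("trial:")], dtype=int)

    @property
    def trial_order(self) -> np.ndarray:
        """Event index of each trial column, in column order."""
        return np.array([int(r.split(":")[1]) for r in self.column_roles
                         if r.startswith("trial:")], dtype=int)


@dataclass
class BetaSeries:
    """Per-trial, per-voxel response amplitudes plus trial metadata."""

    betas: np.ndarray                  # [n_trials, n_voxels]
    trial_metadata: pd.DataFrame       # one row per trial, chronological
    usable_mask: np.ndarray            # bool per trial; False for reinforced
    voxel_index: np.ndarray | None = None   # [n_voxels, 3] grid coordinates
    shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.betas.shape[0] != len(self.trial_metadata):
            raise ValueError("betas rows must align with trial metadata")
        if self.usable_mask.shape[0] != self.betas.shape[0]:
            raise ValueError("usable_mask must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def save(self, image_path: str | Path, sidecar_path: str | Path,
             affine: np.ndarray | None = None) -> None:
        """Write betas as a 4-D NIfTI (trial axis last) and a metadata TSV."""
        import nibabel as nib

        if self.voxel_index is None or self.shape is None:
            raise ValueError("voxel grid information required to write NIfTI")
        vol = np.zeros(self.shape + (self.n_trials,), dtype=np.float32)
        ix, iy, iz = self.voxel_index.T
        vol[ix, iy, iz, :] = self.betas.T
        nib.save(nib.Nifti1Image(vol, affine if affine is not None else np.eye(4)),
                 str(image_path))
        meta = self.trial_metadata.copy()
        meta["usable"] = self.usable_mask.astype(int)
        meta.to_csv(sidecar_path, sep="\t", index=False)


def build_design_matrix(design: "ExperimentDesign", n_scans: int, tr: float,
                        hrf: HrfParams = DEFAULT_HRF,
                        nuisance: np.ndarray | None = None,
                        boxcar_duration: float = 3.5,
                        highpass_cutoff: float = 128.0,
                        dt: float = 0.1) -> TrialDesignMatrix:
    """Assemble the least-squares-all design matrix for a run."""
    onsets = design.onsets
    if n_scans * tr < onsets.max() + boxcar_duration:
        raise ValueError("n_scans * tr must cover the last trial's boxcar")

    X_trials = trial_regressors(onsets, boxcar_duration, n_scans, tr, hrf, dt=dt)
    roles = [f"trial:{i}" for i in range(len(onsets))]

    # duplicate trial regressors make single-trial amplitudes unidentifiable
    _, counts = np.unique(np.round(onsets / dt).astype(int), return_counts=True)
    if (counts > 1).any():
        raise ValueError("degenerate design: two trials share a regressor "
                         "(identical onsets on the microtime grid)")

    cols = [X_trials]
    us_onsets = np.array([t.onset + t.duration - US_DURATION
                          for t in design.trials if t.reinforced])
    if us_onsets.size:
        cols.append(event_regressor(us_onsets, US_DURATION, n_scans, tr, hrf,
                                    dt=dt)[:, None])
        roles.append("US")
    else:
        logger.warning("no reinforced trials: US regressor dropped")

    cols.append(np.ones((n_scans, 1)))
    roles.append("intercept")

    dct = dct_basis(n_scans, tr, highpass_cutoff)
    cols.append(dct)
    roles.extend(f"dct:{k + 1}" for k in range(dct.shape[1]))

    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance rows must equal n_scans")
        cols.append(nuisance)
        roles.extend(f"nuisance:{j}" for j in range(nuisance.shape[1]))

    return TrialDesignMatrix(matrix=np.hstack(cols), column_roles=roles,
                             boxcar_duration=boxcar_duration,
                             highpass_cutoff=highpass_cutoff, tr=tr)


def _rank_deficient_columns(X: np.ndarray, roles: Sequence[str]) -> list[str]:
    """Name columns implicated in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[np.where(diag < tol)[0]]
    return [roles[i] for i in sorted(bad)]


def estimate_betas(bold: "BoldSeries | np.ndarray", X: TrialDesignMatrix,
                   design: "ExperimentDesign | None" = None,
                   mask: np.ndarray | None = None) -> BetaSeries:
    """Fit the LS-A model per voxel and return trial-column coefficients.

    ``bold`` may be a :class:`~fearmvpa.synth.bold.BoldSeries` (its ROI
    labels provide a default mask) or a plain ``[n_scans, n_voxels]`` array.
    """
    voxel_index = None
    shape = None
    if hasattr(bold, "roi_labels"):
        if design is None:
            design = bold.design
        data4d = bold.data
        if mask is None:
            mask = bold.roi_labels > 0
        if not mask.any():
            raise ValueError("mask selects no voxels")
        voxel_index = np.argwhere(mask)
        shape = data4d.shape[:3]
        Y = data4d[mask].T            # [n_scans, n_voxels]
    else:
        Y = np.asarray(bold, dtype=float)
        if Y.ndim != 2:
            raise ValueError("array input must be [n_scans, n_voxels]")
    if design is None:
        raise ValueError("design metadata required")
    if Y.shape[0] != X.n_scans:
        raise ValueError("design matrix rows must equal BOLD time points")

    M = X.matrix
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        bad = _rank_deficient_columns(M, X.column_roles)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {M.shape[1]}); "
            f"offending columns: {bad}")

    coef, *_ = np.linalg.lstsq(M, Y, rcond=None)
    betas = coef[X.trial_columns]      # [n_trials, n_voxels]

    meta = design.to_frame()
    usable = ~meta["reinforced"].astype(bool).to_numpy()
    return BetaSeries(betas=betas, trial_metadata=meta, usable_mask=usable,
                      voxel_index=voxel_index, shape=shape)
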