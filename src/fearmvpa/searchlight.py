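"""Spherical searchlight decoding maps and group-level sign-flip inference."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .decoding import DEFAULT_SVM, SvmConfig, roi_decoding
from .glm import BetaSeries

__all__ = ["SearchlightSpec", "AccuracyMap", "sphere_offsets",
           "sphere_neighbors", "run_searchlight", "group_searchlight_inference"]


@dataclass(frozen=True)
class SearchlightSpec:
    radius: float = 10.0
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    mask: np.ndarray | None = None
    min_voxels_per_sphere: int = 2

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.mask is not None and not self.mask.any():
            raise ValueError("mask is empty")


def sphere_offsets(radius: float,
                   voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Integer voxel offsets with centre-to-centre distance <= radius (mm)."""
    vs = np.asarray(voxel_size, dtype=float)
    r = np.floor(radius / vs).astype(int)
    ax = [np.arange(-ri, ri + 1) for ri in r]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    offs = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])
    dist = np.linalg.norm(offs * vs, axis=1)
    return offs[dist <= radius + 1e-9]


def sphere_neighbors(spec: SearchlightSpec, center: tuple[int, int, int],
                     offsets: np.ndarray | None = None) -> np.ndarray:
    """Mask voxels within ``spec.radius`` mm of ``center`` (centre included)."""
    if spec.mask is None:
        raise ValueError("spec.mask required")
    if not spec.mask[tuple(center)]:
        raise ValueError("center must lie inside the mask")
    if offsets is None:
        offsets = sphere_offsets(spec.radius, spec.voxel_size)
    pts = np.asarray(center) + offsets
    shape = np.asarray(spec.mask.shape)
    ok = np.all((pts >= 0) & (pts < shape), axis=1)
    pts = pts[ok]
    inside = spec.mask[pts[:, 0], pts[:, 1], pts[:, 2]]
    return pts[inside]


@dataclass
class AccuracyMap:
    """Per-voxel corrected accuracies per condition plus the CS-NS contrast."""

    condition_maps: dict[tuple, np.ndarray]
    contrast: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float]


def run_searchlight(betas: BetaSeries, spec: SearchlightSpec,
                    n_perm: int = 100, n_rep: int = 10,
                    seed: int | None = None, config: SvmConfig = DEFAULT_SVM,
                    shared_chance: bool = False) -> AccuracyMap:
    """Corrected-accuracy maps from a moving sphere over the mask.

    At each centre the full condition-wise corrected decoding runs on the
    sphere's voxels.  ``shared_chance`` reuses the chance level of the first
    centre for the reinforced-context cells at all later centres (chance
    depends on label counts, not location); the neutral branch always
    derives chance from its own subsampled permutations.  The contrast map
    is mean corrected CS accuracy minus mean corrected NS accuracy across
    complexities.  Centres whose sphere falls below
    ``min_voxels_per_sphere`` usable voxels are left missing (NaN).
    """
    if spec.mask is None:
        raise ValueError("searchlight needs a mask")
    if betas.voxel_index is None:
        raise ValueError("betas must carry voxel grid information")
    if betas.shape != spec.mask.shape:
        raise ValueError("betas grid and mask shape disagree")

    vox_lookup = -np.ones(spec.mask.shape, dtype=int)
    for col, (x, y, z) in enumerate(betas.voxel_index):
        vox_lookup[x, y, z] = col

    offsets = sphere_offsets(spec.radius, spec.voxel_size)
    centers = np.argwhere(spec.mask)
    conditions = [("reinforced", "simple"), ("reinforced", "complex"),
                  ("neutral", "simple"), ("neutral", "complex")]
    maps = {c: np.full(spec.mask.shape, np.nan) for c in conditions}
    contrast = np.full(spec.mask.shape, np.nan)

    ss = np.random.SeedSequence(seed)
    center_seeds = ss.spawn(len(centers))
    chance_cache: dict | None = None

    for ci, center in enumerate(centers):
        pts = sphere_neighbors(spec, tuple(center), offsets)
        cols = vox_lookup[pts[:, 0], pts[:, 1], pts[:, 2]]
        cols = cols[cols >= 0]
        if cols.size < spec.min_voxels_per_sphere:
            continue
        outcomes = roi_decoding(
            betas, n_perm=n_perm, n_rep=n_rep,
            seed=int(center_seeds[ci].generate_state(1)[0]), config=config,
            voxel_sel=cols, shared_chance=chance_cache)
        if shared_chance and chance_cache is None:
            chance_cache = {o.condition: o.chance_accuracy for o in outcomes
                            if o.condition[0] == "reinforced"}
        cs, ns = [], []
        for o in outcomes:
            maps[o.condition][tuple(center)] = o.corrected_accuracy
            (cs if o.condition[0] == "reinforced" else ns).append(
                o.corrected_accuracy)
        contrast[tuple(center)] = np.mean(cs) - np.mean(ns)

    return AccuracyMap(condition_maps=maps, contrast=contrast, mask=spec.mask,
                       voxel_size=spec.voxel_size)


def group_searchlight_inference(maps: list[np.ndarray],
                                mask: np.ndarray | None = None,
                                n_flips: int = 1000, alpha: float = 0.05,
                                seed: int | None = None,
                                voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5),
                                ) -> tuple[np.ndarray, pd.DataFrame]:
    """One-sample t map across subjects with sign-flip max-statistic FWE.

    Returns the t map (NaN outside the analysis mask) and a cluster table of
    suprathreshold voxels (peak voxel index, peak mm coordinate, size).
    Under exchangeability of subject-map signs the max-statistic threshold
    controls the family-wise error at ``alpha``.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("subject maps must share a grid")
    stack = np.stack(maps)                       # [S, x, y, z]
    finite = np.all(np.isfinite(stack), axis=0)
    if mask is not None:
        if mask.shape != stack.shape[1:]:
            raise ValueError("mask grid mismatch")
        finite &= mask.astype(bool)
    S = stack.shape[0]
    V = stack[:, finite]                         # [S, V]

    def tstat(data: np.ndarray) -> np.ndarray:
        m = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        return m / (sd / np.sqrt(S))

    t_obs = tstat(V)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_flips)
    for f in range(n_flips):
        signs = rng.choice([-1.0, 1.0], size=S)[:, None]
        null_max[f] = tstat(V * signs).max()
    thresh = float(np.quantile(null_max, 1.0 - alpha))

    t_map = np.full(stack.shape[1:], np.nan)
    t_map[finite] = t_obs
    supra = np.zeros(stack.shape[1:], dtype=bool)
    supra[finite] = t_obs > thresh

    lab, n_clusters = ndimage.label(supra)
    rows = []
    vox_vol_cm3 = float(np.prod(voxel_size)) / 1000.0
    for c in range(1, n_clusters + 1):
        sel = lab == c
        size = int(sel.sum())
        tvals = np.where(sel, t_map, -np.inf)
        peak = np.unravel_index(np.nanargmax(tvals), t_map.shape)
        rows.append({"cluster": c, "n_voxels": size,
                     "volume_cm3": size * vox_vol_cm3,
                     "peak_t": float(t_map[peak]),
                     "peak_x": peak[0], "peak_y": peak[1], "peak_z": peak[2],
                     "peak_mm_x": peak[0] * voxel_size[0],
                     "peak_mm_y": peak[1] * voxel_size[1],
                     "peak_mm_z": peak[2] * voxel_size[2],
                     "threshold": thresh})
    table = pd.DataFrame(rows, columns=["cluster", "n_voxels", "volume_cm3",
                                        "peak_t", "peak_x", "peak_y", "peak_z",
                                        "peak_mm_x", "peak_mm_y", "peak_mm_z",
                                        "threshold"])
    return t_map, table
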