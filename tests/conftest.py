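import numpy as np
import pytest

from fearmvpa.glm import BetaSeries
from fearmvpa.synth import (DesignParams, ExperimentDesign, generate_design,
                            make_roi_labels, random_effects)


@pytest.fixture(scope="session")
def default_design() -> ExperimentDesign:
    return generate_design(seed=42)


@pytest.fixture(scope="session")
def small_design() -> ExperimentDesign:
    """Two-block design: 48 trials, 6 per stimulus."""
    return generate_design(DesignParams(n_blocks=2), seed=7)


@pytest.fixture(scope="session")
def feature_subject():
    """Factory for feature-level simulated subjects.

    Skips the BOLD/GLM stages: trial-wise multivoxel amplitudes are drawn
    from the same generative effect structure used by the BOLD simulator
    (stimulus-identity patterns plus optional threat patterns on a single
    64-voxel region) and i.i.d. Gaussian noise is added directly at the
    beta level.
    """

    def make(seed: int, noise_sd: float = 1.0, stim_amplitude: float = 0.0,
             threat_shared_amplitude: float = 0.0,
             threat_specific_amplitude: float = 0.0,
             n_side: int = 4, design: ExperimentDesign | None = None) -> BetaSeries:
        design = design or generate_design(seed=seed)
        labels = np.ones((n_side, n_side, n_side), dtype=np.int16)
        spec = random_effects(labels, seed=seed, noise_sd=noise_sd,
                              stim_amplitude=stim_amplitude,
                              threat_shared_amplitude=threat_shared_amplitude,
                              threat_specific_amplitude=threat_specific_amplitude)
        A = spec.trial_amplitudes(design)
        rng = np.random.default_rng(seed + 10_000)
        betas = A + rng.normal(0.0, noise_sd, size=A.shape)
        meta = design.to_frame()
        return BetaSeries(betas=betas, trial_metadata=meta,
                          usable_mask=~meta["reinforced"].astype(bool).to_numpy(),
                          voxel_index=np.argwhere(labels > 0),
                          shape=labels.shape)

    return make


@pytest.fixture(scope="session")
def pipeline_subject():
    """Factory running the full BOLD simulation + single-trial GLM chain."""
    from fearmvpa.glm import build_design_matrix, estimate_betas
    from fearmvpa.synth import simulate_bold

    def make(seed: int, design: ExperimentDesign | None = None,
             labels: np.ndarray | None = None, **effect_kwargs) -> BetaSeries:
        design = design or generate_design(seed=seed)
        labels = labels if labels is not None else make_roi_labels()
        spec = random_effects(labels, seed=seed, **effect_kwargs)
        bold = simulate_bold(design, spec, seed=seed + 50_000)
        X = build_design_matrix(design, n_scans=bold.n_scans, tr=bold.tr)
        return estimate_betas(bold, X)

    return make
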