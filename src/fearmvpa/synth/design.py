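"""Generation of fear-conditioning experiment designs.

A design is a chronological list of sound-presentation trials organised in
blocks and miniblocks.  Each miniblock presents one stimulus pair (one
complexity level in one context); the two miniblocks of a block share a
context and alternate complexity, and consecutive blocks alternate context.
Under the default parameters this yields 24 presentations of each of the
8 stimuli, with 50% of CS+ presentations reinforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DesignParams",
    "TrialEvent",
    "ExperimentDesign",
    "STIMULUS_TABLE",
    "generate_design",
    "read_events_tsv",
]

ROLES = ("CS+", "CS-", "NS1", "NS2")
COMPLEXITIES = ("simple", "complex")
CONTEXTS = ("reinforced", "neutral")

#: stimulus_id -> (role, complexity, context, response_key).  The paired
#: stimuli of a miniblock map to different response keys; CS+ and NS1 share
#: a key across complexities (and so do CS- and NS2), mirroring the
#: balanced sound/button mapping of the task.
STIMULUS_TABLE: dict[int, tuple[str, str, str, str]] = {
    1: ("CS+", "simple", "reinforced", "left"),
    2: ("CS-", "simple", "reinforced", "right"),
    3: ("CS+", "complex", "reinforced", "left"),
    4: ("CS-", "complex", "reinforced", "right"),
    5: ("NS1", "simple", "neutral", "left"),
    6: ("NS2", "simple", "neutral", "right"),
    7: ("NS1", "complex", "neutral", "left"),
    8: ("NS2", "complex", "neutral", "right"),
}

_PAIR_BY_CELL = {
    ("reinforced", "simple"): (1, 2),
    ("reinforced", "complex"): (3, 4),
    ("neutral", "simple"): (5, 6),
    ("neutral", "complex"): (7, 8),
}


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the trial-design generator."""

    n_blocks: int = 8
    miniblocks_per_block: int = 2
    trials_per_miniblock: int = 12
    n_stimuli: int = 8
    stim_duration: float = 4.0
    iti_set: tuple[float, ...] = (7.0, 9.0, 11.0)
    reinforcement_rate: float = 0.5
    block_padding: float = 10.0  # lead-in and lead-out per block, seconds
    seed: int | None = None

    def validate(self) -> None:
        for name in ("n_blocks", "miniblocks_per_block", "trials_per_miniblock",
                     "n_stimuli"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.reinforcement_rate <= 1.0:
            raise ValueError("reinforcement_rate must be in [0, 1]")
        if len(self.iti_set) == 0:
            raise ValueError("iti_set must be non-empty")
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be > 0")
        if self.trials_per_miniblock % 2 != 0:
            raise ValueError(
                "trials_per_miniblock must be even: both stimuli of a pair "
                "appear equally often within a miniblock")
        if self.n_stimuli != 8:
            raise ValueError("the stimulus table defines exactly 8 stimuli")


@dataclass(frozen=True)
class TrialEvent:
    """One sound presentation."""

    onset: float
    duration: float
    stimulus_id: int
    role: str
    complexity: str
    context: str
    reinforced: bool
    response_key: str
    block_index: int
    miniblock_index: int

    def __post_init__(self) -> None:
        if self.reinforced and not (self.role == "CS+" and self.context == "reinforced"):
            raise ValueError("only CS+ trials in the reinforced context can be reinforced")
        if self.role in ("NS1", "NS2") and self.context != "neutral":
            raise ValueError("NS trials must be in the neutral context")


@dataclass(frozen=True)
class ExperimentDesign:
    params: DesignParams
    trials: tuple[TrialEvent, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.trials])

    @property
    def run_duration(self) -> float:
        """Seconds from run start to the end of the last block's lead-out."""
        last = self.trials[-1]
        return last.onset + self.params.stim_duration + max(self.params.iti_set) \
            + self.params.block_padding

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [t.onset for t in self.trials],
                "duration": [t.duration for t in self.trials],
                "trial_type": [t.role for t in self.trials],
                "stimulus_id": [t.stimulus_id for t in self.trials],
                "context": [t.context for t in self.trials],
                "complexity": [t.complexity for t in self.trials],
                "reinforced": [int(t.reinforced) for t in self.trials],
                "response_key": [t.response_key for t in self.trials],
                "block_index": [t.block_index for t in self.trials],
                "miniblock_index": [t.miniblock_index for t in self.trials],
            }
        )

    def write_events_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def trial_indices(self, *, context: str | None = None,
                      complexity: str | None = None,
                      role: str | None = None,
                      usable_only: bool = False) -> np.ndarray:
        """Chronological indices of trials matching the given labels.

        ``usable_only`` drops reinforced trials (their responses overlap the
        aversive stimulation and are excluded from analysis).
        """
        idx = []
        for i, t in enumerate(self.trials):
            if context is not None and t.context != context:
                continue
            if complexity is not None and t.complexity != complexity:
                continue
            if role is not None and t.role != role:
                continue
            if usable_only and t.reinforced:
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)


def _block_contexts(n_blocks: int, rng: np.random.Generator) -> list[str]:
    start = rng.integers(0, 2)
    return [CONTEXTS[(start + b) % 2] for b in range(n_blocks)]


def _block_complexities(m: int, rng: np.random.Generator) -> list[str]:
    start = rng.integers(0, 2)
    return [COMPLEXITIES[(start + i) % 2] for i in range(m)]


def generate_design(params: DesignParams | None = None,
                    seed: int | None = None) -> ExperimentDesign:
    """Generate a randomized design satisfying the block/miniblock structure.

    Deterministic given ``seed`` (which overrides ``params.seed``).
    """
    params = params or DesignParams()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    contexts = _block_contexts(params.n_blocks, rng)
    half = params.trials_per_miniblock // 2

    rows: list[dict] = []
    t = 0.0
    mb_counter = 0
    for b, context in enumerate(contexts):
        t += params.block_padding
        for complexity in _block_complexities(params.miniblocks_per_block, rng):
            sid_a, sid_b = _PAIR_BY_CELL[(context, complexity)]
            order = np.array([sid_a] * half + [sid_b] * half)
            rng.shuffle(order)
            for sid in order:
                rows.append({"onset": t, "stimulus_id": int(sid),
                             "block_index": b, "miniblock_index": mb_counter})
                t += params.stim_duration + float(rng.choice(params.iti_set))
            mb_counter += 1
        t += params.block_padding

    # reinforcement: per CS+ stimulus, round(rate * n) of its trials, uniform
    reinforced = np.zeros(len(rows), dtype=bool)
    for sid, (role, _, _, _) in STIMULUS_TABLE.items():
        if role != "CS+":
            continue
        positions = [i for i, r in enumerate(rows) if r["stimulus_id"] == sid]
        k = int(round(params.reinforcement_rate * len(positions)))
        chosen = rng.choice(len(positions), size=k, replace=False)
        for c in chosen:
            reinforced[positions[c]] = True

    trials = []
    for i, r in enumerate(rows):
        role, complexity, context, key = STIMULUS_TABLE[r["stimulus_id"]]
        trials.append(TrialEvent(
            onset=r["onset"], duration=params.stim_duration,
            stimulus_id=r["stimulus_id"], role=role, complexity=complexity,
            context=context, reinforced=bool(reinforced[i]), response_key=key,
            block_index=r["block_index"], miniblock_index=r["miniblock_index"]))
    return ExperimentDesign(params=params, trials=tuple(trials))


def read_events_tsv(path: str | Path,
                    params: DesignParams | None = None) -> ExperimentDesign:
    """Load a design from a BIDS-style events TSV written by this package."""
    df = pd.read_csv(path, sep="\t")
    params = params or DesignParams()
    trials = tuple(
        TrialEvent(
            onset=float(r.onset), duration=float(r.duration),
            stimulus_id=int(r.stimulus_id), role=str(r.trial_type),
            complexity=str(r.complexity), context=str(r.context),
            reinforced=bool(int(r.reinforced)), response_key=str(r.response_key),
            block_index=int(getattr(r, "block_index", 0)),
            miniblock_index=int(getattr(r, "miniblock_index", 0)))
        for r in df.itertuples())
    return ExperimentDesign(params=params, trials=trials)
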