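"""Permutation-corrected SVM decoding of condition labels from beta patterns.

Implements the condition-wise decoding chain: per-voxel z-scoring, 3-fold
cross-validation where every third trial is test data, linear-kernel SVM
classification, chance estimation from label permutations (preserving the
12:24 class imbalance of the reinforced context), 50% subsampling of one
neutral class to match that imbalance, and simple<->complex
cross-classification without cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .glm import BetaSeries

logger = logging.getLogger(__name__)

__all__ = ["SvmConfig", "FeatureMatrix", "FoldScheme", "DecodingOutcome",
           "CrossDecodingOutcome", "zscore_features", "make_folds",
           "decode_condition", "permutation_chance", "decode_corrected",
           "subsampled_ns_decoding", "cross_classify", "roi_decoding"]


@dataclass(frozen=True)
class SvmConfig:
    """Linear-kernel C-SVC settings (library defaults; no internal scaling)."""

    C: float = 1.0
    chance_statistic: str = "mean"     # or "median"


DEFAULT_SVM = SvmConfig()


@dataclass
class FeatureMatrix:
    """Trials x voxels features, z-scored per voxel, with binary labels."""

    values: np.ndarray
    labels: np.ndarray
    trial_order: np.ndarray            # original chronological positions

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D [n_trials, n_voxels]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features contain non-finite values")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per trial required")
        if np.unique(self.labels).size > 2:
            raise ValueError("binary classification only")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(values=self.values[idx], labels=self.labels[idx],
                             trial_order=self.trial_order[idx])


@dataclass(frozen=True)
class FoldScheme:
    """Chronology-based fold assignment: test fold k = positions == k (mod 3)."""

    assignment: np.ndarray
    n_folds: int = 3

    def test_indices(self, k: int) -> np.ndarray:
        return np.where(self.assignment == k)[0]

    def train_indices(self, k: int) -> np.ndarray:
        return np.where(self.assignment != k)[0]


@dataclass
class DecodingOutcome:
    raw_accuracy: float
    chance_accuracy: float
    corrected_accuracy: float
    n_permutations: int
    condition: tuple = ()
    n_subsample_reps: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.raw_accuracy <= 1.0 and 0.0 <= self.chance_accuracy <= 1.0):
            raise ValueError("accuracies must lie in [0, 1]")


@dataclass
class CrossDecodingOutcome(DecodingOutcome):
    direction: str = ""
    stimulus_set: str = ""


def zscore_features(betas: BetaSeries | np.ndarray,
                    trial_subset: np.ndarray | None = None,
                    labels: np.ndarray | None = None) -> FeatureMatrix:
    """Standardize each voxel across the selected trials (population SD).

    Constant voxels are dropped with a warning; an all-constant matrix is an
    error.
    """
    if isinstance(betas, BetaSeries):
        values = betas.betas
    else:
        values = np.asarray(betas, dtype=float)
    if trial_subset is None:
        trial_subset = np.arange(values.shape[0])
    trial_subset = np.asarray(trial_subset, dtype=int)
    if trial_subset.size < 2:
        raise ValueError("need at least 2 trials to z-score")
    X = values[trial_subset].astype(float)
    sd = X.std(axis=0)
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    if not keep.any():
        raise ValueError("all voxels constant across the selected trials")
    if not keep.all():
        logger.warning("dropping %d constant voxel(s)", int((~keep).sum()))
        X = X[:, keep]
        sd = sd[keep]
    X = (X - X.mean(axis=0)) / sd
    if labels is None:
        labels = np.zeros(trial_subset.size, dtype=int)
    return FeatureMatrix(values=X, labels=np.asarray(labels),
                         trial_order=trial_subset)


def make_folds(n_trials: int, n_folds: int = 3) -> FoldScheme:
    """Every ``n_folds``-th trial (chronological position) shares a fold."""
    if n_trials < n_folds:
        raise ValueError(f"need at least {n_folds} trials")
    return FoldScheme(assignment=np.arange(n_trials) % n_folds, n_folds=n_folds)


def _fit_predict(X_train: np.ndarray, y_train: np.ndarray,
                 X_test: np.ndarray, config: SvmConfig) -> np.ndarray:
    classes, counts = np.unique(y_train, return_counts=True)
    if classes.size < 2:
        raise ValueError("training fold contains a single class")
    clf = SVC(kernel="linear", C=config.C)
    clf.fit(X_train, y_train)
    scores = clf.decision_function(X_test)
    pred = np.where(scores > 0, clf.classes_[1], clf.classes_[0])
    # a decision value of exactly 0 is resolved to the majority training class
    ties = scores == 0
    if ties.any():
        pred[ties] = classes[np.argmax(counts)]
    return pred


def _cv_accuracy(values: np.ndarray, labels: np.ndarray, folds: FoldScheme,
                 config: SvmConfig) -> float:
    correct = 0
    for k in range(folds.n_folds):
        tr, te = folds.train_indices(k), folds.test_indices(k)
        pred = _fit_predict(values[tr], labels[tr], values[te], config)
        correct += int((pred == labels[te]).sum())
    return correct / len(labels)


def decode_condition(fm: FeatureMatrix, folds: FoldScheme,
                     config: SvmConfig = DEFAULT_SVM) -> float:
    """Cross-validated accuracy, pooled over all test trials."""
    return _cv_accuracy(fm.values, fm.labels, folds, config)


def permutation_chance(fm: FeatureMatrix, folds: FoldScheme,
                       n_perm: int = 1000, seed: int | None = None,
                       config: SvmConfig = DEFAULT_SVM) -> float:
    """Mean CV accuracy over uniform label permutations (counts preserved).

    A permutation that leaves a training fold single-class (possible only
    for very small trial counts) is redrawn.
    """
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for p in range(n_perm):
        for _attempt in range(100):
            try:
                accs[p] = _cv_accuracy(fm.values, rng.permutation(fm.labels),
                                       folds, config)
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not draw a permutation with both classes "
                             "in every training fold")
    return float(np.median(accs) if config.chance_statistic == "median"
                 else accs.mean())


def decode_corrected(fm: FeatureMatrix, folds: FoldScheme,
                     n_perm: int = 1000, seed: int | None = None,
                     config: SvmConfig = DEFAULT_SVM,
                     condition: tuple = (),
                     chance: float | None = None) -> DecodingOutcome:
    """Raw, chance and corrected accuracy for one condition.

    ``chance`` short-circuits the permutation step with a precomputed value
    (used by the searchlight's shared-chance mode).
    """
    raw = decode_condition(fm, folds, config)
    if chance is None:
        chance = permutation_chance(fm, folds, n_perm, seed, config)
    return DecodingOutcome(raw_accuracy=raw, chance_accuracy=chance,
                           corrected_accuracy=raw - chance,
                           n_permutations=n_perm, condition=condition,
                           seed=seed)


def subsampled_ns_decoding(fm_ns: FeatureMatrix, n_rep: int = 100,
                           n_perm: int = 1000, seed: int | None = None,
                           config: SvmConfig = DEFAULT_SVM,
                           condition: tuple = ()) -> DecodingOutcome:
    """Neutral-pair decoding with imbalance matched to the reinforced context.

    Per repetition one neutral class (alternating with repetition parity) is
    randomly halved from 24 to 12 trials, the 3-fold CV runs on the
    remaining 12:24 trials, and both raw and permutation-chance accuracies
    are averaged over repetitions.
    """
    classes, counts = np.unique(fm_ns.labels, return_counts=True)
    if classes.size != 2 or not np.all(counts == counts[0]):
        raise ValueError("expected two equally frequent neutral classes "
                         f"(got counts {dict(zip(classes, counts))})")
    half = counts[0] // 2
    if counts[0] % 2:
        raise ValueError("class size must be even to discard 50% of trials")

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_rep)
    raws = np.empty(n_rep)
    chances = np.empty(n_rep)
    for r in range(n_rep):
        rng = np.random.default_rng(rep_seeds[r])
        victim = classes[r % 2]
        victim_idx = np.where(fm_ns.labels == victim)[0]
        keep_victim = np.sort(rng.choice(victim_idx, size=half, replace=False))
        keep = np.sort(np.concatenate(
            [keep_victim, np.where(fm_ns.labels != victim)[0]]))
        sub = fm_ns.subset(keep)
        folds = make_folds(sub.n_trials)
        raws[r] = decode_condition(sub, folds, config)
        chances[r] = permutation_chance(
            sub, folds, n_perm, rng.integers(2 ** 31), config)
    raw = float(raws.mean())
    chance = float(chances.mean())
    return DecodingOutcome(raw_accuracy=raw, chance_accuracy=chance,
                           corrected_accuracy=raw - chance,
                           n_permutations=n_perm, n_subsample_reps=n_rep,
                           condition=condition, seed=seed)


def cross_classify(fm_train: FeatureMatrix, fm_test: FeatureMatrix,
                   config: SvmConfig = DEFAULT_SVM, n_perm: int = 1000,
                   seed: int | None = None, direction: str = "",
                   stimulus_set: str = "") -> CrossDecodingOutcome:
    """Train on one stimulus set, test on the other; no cross-validation.

    Chance is estimated by permuting the training labels, retraining, and
    scoring against the unpermuted test labels.
    """
    if fm_train.values.shape[1] != fm_test.values.shape[1]:
        raise ValueError("train and test features must share the voxel space")
    pred = _fit_predict(fm_train.values, fm_train.labels, fm_test.values, config)
    raw = float((pred == fm_test.labels).mean())
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for p in range(n_perm):
        perm_pred = _fit_predict(fm_train.values,
                                 rng.permutation(fm_train.labels),
                                 fm_test.values, config)
        accs[p] = (perm_pred == fm_test.labels).mean()
    chance = float(np.median(accs) if config.chance_statistic == "median"
                   else accs.mean())
    return CrossDecodingOutcome(raw_accuracy=raw, chance_accuracy=chance,
                                corrected_accuracy=raw - chance,
                                n_permutations=n_perm, seed=seed,
                                direction=direction, stimulus_set=stimulus_set,
                                condition=(direction, stimulus_set))


def _condition_features(betas: BetaSeries, context: str, complexity: str,
                        voxel_sel: np.ndarray | None = None) -> FeatureMatrix:
    meta = betas.trial_metadata
    usable = betas.usable_mask
    sel = ((meta["context"] == context) & (meta["complexity"] == complexity)
           & usable).to_numpy()
    idx = np.where(sel)[0]
    values = betas.betas if voxel_sel is None else betas.betas[:, voxel_sel]
    if context == "reinforced":
        labels = (meta["trial_type"].to_numpy()[idx] == "CS+").astype(int)
    else:
        labels = (meta["trial_type"].to_numpy()[idx] == "NS1").astype(int)
    return zscore_features(values, idx, labels)


def roi_decoding(betas: BetaSeries, n_perm: int = 1000, n_rep: int = 100,
                 seed: int | None = None, config: SvmConfig = DEFAULT_SVM,
                 voxel_sel: np.ndarray | None = None,
                 shared_chance: dict | None = None) -> list[DecodingOutcome]:
    """Corrected decoding per (context, complexity) cell on one voxel set.

    Reinforced-context cells use the usable 12:24 CS+/CS- trials directly;
    neutral cells use the imbalance-matched subsampling branch.
    ``shared_chance`` maps a (context, complexity) cell to a precomputed
    chance accuracy (reinforced cells only).
    """
    ss = np.random.SeedSequence(seed)
    cell_seeds = iter(int(s.generate_state(1)[0]) for s in ss.spawn(4))
    outcomes = []
    for context in ("reinforced", "neutral"):
        for complexity in ("simple", "complex"):
            fm = _condition_features(betas, context, complexity, voxel_sel)
            cond = (context, complexity)
            child = next(cell_seeds)
            if context == "reinforced":
                folds = make_folds(fm.n_trials)
                pre = None if shared_chance is None else shared_chance.get(cond)
                outcomes.append(decode_corrected(
                    fm, folds, n_perm, child, config, condition=cond,
                    chance=pre))
            else:
                outcomes.append(subsampled_ns_decoding(
                    fm, n_rep, n_perm, child, config, condition=cond))
    return outcomes


def cross_decoding_suite(betas: BetaSeries, n_perm: int = 1000,
                         seed: int | None = None,
                         config: SvmConfig = DEFAULT_SVM,
                         voxel_sel: np.ndarray | None = None) -> list[CrossDecodingOutcome]:
    """Simple<->complex cross-classification for CS and key-matched NS sets.

    CS sets carry threat labels (CS+ vs CS-); NS sets carry response-key
    labels, the attribute matched between complexities.
    """
    meta = betas.trial_metadata
    usable = betas.usable_mask
    values = betas.betas if voxel_sel is None else betas.betas[:, voxel_sel]

    def features(context: str, complexity: str) -> FeatureMatrix:
        sel = ((meta["context"] == context) & (meta["complexity"] == complexity)
               & usable).to_numpy()
        idx = np.where(sel)[0]
        if context == "reinforced":
            labels = (meta["trial_type"].to_numpy()[idx] == "CS+").astype(int)
        else:
            labels = (meta["response_key"].to_numpy()[idx] == "left").astype(int)
        return zscore_features(values, idx, labels)

    ss = np.random.SeedSequence(seed)
    seeds = iter(s.generate_state(1)[0] for s in ss.spawn(4))
    out = []
    for stimulus_set, context in (("CS", "reinforced"), ("NS-keymatched", "neutral")):
        fms = {cx: features(context, cx) for cx in ("simple", "complex")}
        for a, b in (("simple", "complex"), ("complex", "simple")):
            out.append(cross_classify(fms[a], fms[b], config, n_perm,
                                      int(next(seeds)),
                                      direction=f"{a}->{b}",
                                      stimulus_set=stimulus_set))
    return out
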