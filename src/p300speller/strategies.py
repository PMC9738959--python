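"""Decoding strategies: single classifier and four ensemble variants.

All strategies share the same skeleton.  A per-epoch scorer rho gives the
probability that one post-stimulus epoch contains a P300.  Scoring a
sequence produces a length-(n+m) vector indexed by stimulus code (tau);
averaging over the alpha sequences of a selection produces the selection
score vector (Psi); the decoded symbol sits at the intersection of the
best-scoring column (argmax over codes 1..m) and row (argmax over codes
m+1..m+n).

Variants differ in how many learners exist and what data each one sees:

- ``single``            : one learner, whole training set.
- ``hetero_unweighted`` : N learners with distinct algorithms, each trained
  on the whole set; selection vectors averaged with equal weight.
- ``hetero_weighted``   : as above, but each learner's vector is scaled by
  its cross-validated training accuracy w_i; the fused vector is
  (1/N) * sum_i w_i * Psi_i (division by N, not by sum w_i — the argmax is
  scale-invariant so the normalization choice cannot change the decision).
- ``homo_horizontal``   : alpha copies of one algorithm; partition i holds
  the i-th sequence of every selection, and at test time learner i scores
  only the i-th sequence of the selection.
- ``homo_vertical``     : N copies of one algorithm; partition i holds a
  consecutive block of beta/N whole selections, and at test time every
  learner scores the whole selection, vectors averaged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence as TySequence

import numpy as np

from .classifiers import ClassifierSpec, TrainedClassifier, train_binary, training_weight
from .paradigm import Dataset, ParadigmParams, Selection, Sequence, SymbolMatrix
from .preprocessing import PreprocessConfig, preprocess_dataset, preprocess_epoch

__all__ = [
    "VARIANTS",
    "EpochScorer",
    "FeatureScorer",
    "TrainedStrategy",
    "score_sequence",
    "score_selection_single",
    "fuse_scores",
    "decide_symbol",
    "partition_horizontal",
    "partition_vertical",
    "train_strategy",
    "score_selection",
    "predict_symbol",
]

logger = logging.getLogger(__name__)

VARIANTS = (
    "single",
    "hetero_unweighted",
    "hetero_weighted",
    "homo_horizontal",
    "homo_vertical",
)


class EpochScorer(Protocol):
    """Anything that maps one epoch to a P300 probability in [0, 1]."""

    def score_epoch(self, epoch) -> float: ...


@dataclass
class FeatureScorer:
    """Adapts a trained binary classifier to score raw epochs.

    Applies the preprocessing pipeline to the epoch, then the classifier.
    """

    classifier: TrainedClassifier
    config: PreprocessConfig

    def score_epoch(self, epoch) -> float:
        return self.classifier.score_epoch_features(preprocess_epoch(epoch, self.config))


def score_sequence(scorer: EpochScorer, seq: Sequence) -> np.ndarray:
    """tau: score one sequence, indexed by stimulus code (entry j-1 <-> code j).

    The result depends only on each epoch's code, never on its position in
    the presentation order.
    """
    ncodes = len(seq.epochs)
    u = np.empty(ncodes)
    seen = set()
    for ep in seq.epochs:
        if not 1 <= ep.code <= ncodes or ep.code in seen:
            raise ValueError(f"sequence codes must be a permutation of 1..{ncodes}")
        seen.add(ep.code)
        u[ep.code - 1] = scorer.score_epoch(ep)
    return u


def score_selection_single(
    scorer: EpochScorer, sel: Selection, k: int | None = None
) -> np.ndarray:
    """Psi: mean of tau over the first k sequences (all alpha by default)."""
    k = sel.alpha if k is None else k
    if not 1 <= k <= sel.alpha:
        raise ValueError(f"k={k} outside 1..{sel.alpha}")
    return np.mean([score_sequence(scorer, s) for s in sel.sequences[:k]], axis=0)


def fuse_scores(
    score_vectors: TySequence[np.ndarray], weights: TySequence[float] | None = None
) -> np.ndarray:
    """Voting fusion: r = (1/N) * sum_i w_i * v_i (all w_i = 1 when unweighted)."""
    vecs = [np.asarray(v, dtype=float) for v in score_vectors]
    if not vecs:
        raise ValueError("need at least one score vector")
    L = vecs[0].shape
    if any(v.shape != L for v in vecs):
        raise ValueError("score vectors have mismatched lengths")
    N = len(vecs)
    if weights is None:
        weights = [1.0] * N
    if len(weights) != N:
        raise ValueError("one weight per score vector required")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    return sum(w * v for w, v in zip(weights, vecs)) / N


def decide_symbol(r: np.ndarray, mat: SymbolMatrix) -> tuple[int, int, str]:
    """Pick the symbol at the best column x best row; ties break to lowest code."""
    r = np.asarray(r, dtype=float)
    if r.shape != (mat.n + mat.m,):
        raise ValueError(f"score vector length {r.size} != n+m = {mat.n + mat.m}")
    y = int(np.argmax(r[: mat.m])) + 1
    x = int(np.argmax(r[mat.m :])) + 1
    return (x, y, mat.symbol_at(x, y))


def partition_horizontal(dataset: Dataset) -> list[Dataset]:
    """Split by sequence rank: partition i = the i-th sequence of every selection.

    Returns alpha datasets of beta single-sequence selections each; they are
    pairwise disjoint and their union is the input dataset.
    """
    p = dataset.paradigm
    for si, sel in enumerate(dataset.selections, start=1):
        if sel.alpha != p.alpha:
            raise ValueError(
                f"selection {si} has {sel.alpha} sequences, expected alpha={p.alpha}"
            )
    sub_paradigm = ParadigmParams(
        n=p.n, m=p.m, alpha=1, fs=p.fs, n_channels=p.n_channels, window_ms=p.window_ms
    )
    return [
        Dataset(
            selections=[
                Selection(sequences=[sel.sequences[i]], true_symbol=sel.true_symbol)
                for sel in dataset.selections
            ],
            paradigm=sub_paradigm,
        )
        for i in range(p.alpha)
    ]


def partition_vertical(dataset: Dataset, N: int) -> list[Dataset]:
    """Split into N consecutive blocks of whole selections.

    When N divides beta every block has beta/N selections; otherwise the
    remainder selections are appended to the final block (with a warning).
    """
    beta = dataset.beta
    if not 1 <= N <= beta:
        raise ValueError(f"N={N} must satisfy 1 <= N <= beta={beta}")
    size = beta // N
    if beta % N:
        warnings.warn(
            f"beta={beta} not divisible by N={N}; final partition takes the "
            f"{beta % N} remainder selections",
            stacklevel=2,
        )
    blocks = []
    for i in range(N):
        lo = i * size
        hi = (i + 1) * size if i < N - 1 else beta
        blocks.append(Dataset(selections=dataset.selections[lo:hi], paradigm=dataset.paradigm))
    return blocks


@dataclass
class TrainedStrategy:
    """A fitted decoding strategy: variant + learners + fusion weights + paradigm."""

    variant: str
    learners: list[TrainedClassifier]
    paradigm: ParadigmParams
    preprocess: PreprocessConfig
    weights: list[float] | None = None
    specs: list[ClassifierSpec] = field(default_factory=list)

    @property
    def n_learners(self) -> int:
        return len(self.learners)

    def score_selection(self, sel: Selection, k: int | None = None) -> np.ndarray:
        return score_selection(self, sel, k=k)

    def predict_symbol(
        self, sel: Selection, mat: SymbolMatrix, k: int | None = None
    ) -> tuple[int, int, str]:
        return decide_symbol(self.score_selection(sel, k=k), mat)


def _fit_on(dataset: Dataset, spec: ClassifierSpec, config: PreprocessConfig) -> TrainedClassifier:
    X, labels, _ = preprocess_dataset(dataset, config)
    if any(l == "unknown" for l in labels):
        raise ValueError("training data must be fully labeled (no 'unknown' epochs)")
    return train_binary(spec, X, labels)


def train_strategy(
    dataset: Dataset,
    variant: str,
    specs: ClassifierSpec | TySequence[ClassifierSpec],
    N: int | None = None,
    preprocess_config: PreprocessConfig | None = None,
    weight_folds: int = 5,
) -> TrainedStrategy:
    """Train any of the five decoding strategies on a labeled dataset.

    ``specs`` is a single spec for single/homogeneous variants and a list of
    specs with pairwise-distinct algorithms for the heterogeneous ones.
    ``N`` is required only for ``homo_vertical``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    p = dataset.paradigm
    config = preprocess_config or PreprocessConfig(window_ms=p.window_ms, fs=p.fs)

    if isinstance(specs, ClassifierSpec):
        spec_list = [specs]
    else:
        spec_list = list(specs)

    if variant == "single":
        if len(spec_list) != 1:
            raise ValueError("single strategy takes exactly one classifier spec")
        learners = [_fit_on(dataset, spec_list[0], config)]
        logger.info("single: 1 learner trained on %d epochs", dataset.n_epochs())
        return TrainedStrategy("single", learners, p, config, specs=spec_list)

    if variant in ("hetero_unweighted", "hetero_weighted"):
        if len(spec_list) < 2:
            raise ValueError("heterogeneous ensemble needs at least two classifier specs")
        algos = [s.algorithm for s in spec_list]
        if len(set(algos)) != len(algos):
            raise ValueError(f"heterogeneous specs must use distinct algorithms, got {algos}")
        learners = [_fit_on(dataset, s, config) for s in spec_list]
        logger.info(
            "%s: %d learners each trained on %d epochs",
            variant, len(learners), dataset.n_epochs(),
        )
        weights = None
        if variant == "hetero_weighted":
            X, labels, _ = preprocess_dataset(dataset, config)
            weights = [
                training_weight(s, X, labels, folds=weight_folds) for s in spec_list
            ]
            logger.info("voting weights: %s", [round(w, 4) for w in weights])
        return TrainedStrategy(variant, learners, p, config, weights=weights, specs=spec_list)

    if len(spec_list) != 1:
        raise ValueError("homogeneous ensemble takes exactly one classifier spec")
    spec = spec_list[0]

    if variant == "homo_horizontal":
        parts = partition_horizontal(dataset)
        learners = [_fit_on(part, spec, config) for part in parts]
        logger.info(
            "homo_horizontal: %d learners, one per sequence rank, %d epochs each",
            len(learners), parts[0].n_epochs(),
        )
        return TrainedStrategy("homo_horizontal", learners, p, config, specs=[spec])

    # homo_vertical
    if N is None:
        raise ValueError("homo_vertical requires N (number of partitions)")
    parts = partition_vertical(dataset, N)
    learners = [_fit_on(part, spec, config) for part in parts]
    logger.info(
        "homo_vertical: %d learners on blocks of %d selections (%d epochs each)",
        N, parts[0].beta, parts[0].n_epochs(),
    )
    return TrainedStrategy("homo_vertical", learners, p, config, specs=[spec])


def score_selection(
    strategy: TrainedStrategy, sel: Selection, k: int | None = None
) -> np.ndarray:
    """Selection score vector under any trained strategy.

    ``k`` truncates decoding to the first k sequences (accuracy-vs-sequences
    curves); the averaging then divides by k.  For ``homo_horizontal`` the
    learner of rank i always scores the sequence of the same rank, so
    truncation uses learners 1..k; if a selection has fewer sequences than
    learners the surplus learners are skipped.
    """
    if strategy.variant not in VARIANTS:
        raise ValueError(f"unknown variant {strategy.variant!r}")
    k = sel.alpha if k is None else k
    if not 1 <= k <= sel.alpha:
        raise ValueError(f"k={k} outside 1..{sel.alpha}")

    if strategy.variant == "single":
        scorer = FeatureScorer(strategy.learners[0], strategy.preprocess)
        return score_selection_single(scorer, sel, k=k)

    if strategy.variant in ("hetero_unweighted", "hetero_weighted"):
        vecs = [
            score_selection_single(FeatureScorer(c, strategy.preprocess), sel, k=k)
            for c in strategy.learners
        ]
        return fuse_scores(vecs, strategy.weights)

    if strategy.variant == "homo_horizontal":
        kk = min(k, strategy.n_learners)
        vecs = [
            score_sequence(FeatureScorer(strategy.learners[i], strategy.preprocess),
                           sel.sequences[i])
            for i in range(kk)
        ]
        return fuse_scores(vecs)  # (1/k) * sum of per-rank tau vectors

    # homo_vertical
    vecs = [
        score_selection_single(FeatureScorer(c, strategy.preprocess), sel, k=k)
        for c in strategy.learners
    ]
    return fuse_scores(vecs)


def predict_symbol(
    strategy: TrainedStrategy, sel: Selection, mat: SymbolMatrix, k: int | None = None
) -> tuple[int, int, str]:
    """Decode a selection to its (row, column, symbol)."""
    return decide_symbol(score_selection(strategy, sel, k=k), mat)
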