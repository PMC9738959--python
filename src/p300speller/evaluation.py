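"""Strategy evaluation: symbol accuracy, per-epoch binary accuracy, and the
accuracy-vs-number-of-sequences curve."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paradigm import Dataset, SymbolMatrix
from .strategies import FeatureScorer, TrainedStrategy, decide_symbol, score_selection

__all__ = ["EvaluationReport", "evaluate"]


@dataclass
class EvaluationReport:
    """Results of running a trained strategy over a labeled test set.

    ``symbol_accuracy`` is the fraction of selections decoded to the correct
    symbol using all alpha sequences; ``binary_accuracy`` thresholds the
    per-epoch P300 probability at 0.5 against the epoch labels;
    ``accuracy_by_sequences[k-1]`` is the symbol accuracy when only the
    first k sequences of each selection are decoded.
    """

    symbol_accuracy: float
    binary_accuracy: float | None
    predictions: pd.DataFrame
    accuracy_by_sequences: list[float]

    def to_frame(self) -> pd.DataFrame:
        return self.predictions


def evaluate(
    strategy: TrainedStrategy,
    dataset: Dataset,
    mat: SymbolMatrix,
    curve: bool = True,
) -> EvaluationReport:
    """Decode every selection of a labeled dataset and score the result.

    Requires ``true_symbol`` on every selection.  When ``curve`` is True the
    truncated decodings for k = 1..alpha are also computed (re-scoring each
    selection alpha times).
    """
    if any(s.true_symbol is None for s in dataset.selections):
        raise ValueError("evaluation requires true symbols on every selection")
    alpha = dataset.paradigm.alpha
    rows = []
    correct_by_k = np.zeros(alpha)
    hits = 0
    bin_hits = 0
    bin_total = 0
    for si, sel in enumerate(dataset.selections, start=1):
        r = score_selection(strategy, sel)
        x, y, sym = decide_symbol(r, mat)
        tx, ty = sel.true_symbol
        ok = (x, y) == (tx, ty)
        hits += ok
        rows.append(
            {
                "selection": si,
                "true_row": tx, "true_col": ty,
                "true_symbol": mat.symbol_at(tx, ty),
                "pred_row": x, "pred_col": y, "pred_symbol": sym,
                "correct": bool(ok),
            }
        )
        if curve:
            for k in range(1, alpha + 1):
                rk = r if k == alpha else score_selection(strategy, sel, k=k)
                xk, yk, _ = decide_symbol(rk, mat)
                correct_by_k[k - 1] += (xk, yk) == (tx, ty)
        # per-epoch binary accuracy is strategy-dependent for ensembles;
        # the first learner's rho serves as the representative epoch score
        scorer = FeatureScorer(strategy.learners[0], strategy.preprocess)
        for seq in sel.sequences:
            for ep in seq.epochs:
                if ep.label == "unknown":
                    continue
                rho = scorer.score_epoch(ep)
                bin_hits += (rho >= 0.5) == (ep.label == "target")
                bin_total += 1
    n = dataset.beta
    return EvaluationReport(
        symbol_accuracy=hits / n,
        binary_accuracy=(bin_hits / bin_total) if bin_total else None,
        predictions=pd.DataFrame(rows),
        accuracy_by_sequences=list(correct_by_k / n) if curve else [],
    )
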