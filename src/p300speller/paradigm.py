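"""Data model for the row/column (RC) speller paradigm.

A speller presents an ``n x m`` matrix of symbols.  One *intensification*
flashes a whole row or column and elicits one post-stimulus EEG epoch.  A
*sequence* is one randomized pass in which every row and every column
flashes exactly once (``n + m`` intensifications).  A *selection* is the
group of ``alpha`` consecutive sequences used to spell a single symbol.

Rows and columns share a single serial code space: column ``j`` carries
code ``j`` (1..m) and row ``i`` carries code ``m + i`` (m+1..m+n).  All
public APIs use this 1-based convention, which matches the stimulus-code
numbering of the BCI Competition III speller recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence as TySequence

import numpy as np

__all__ = [
    "SymbolMatrix",
    "Epoch",
    "Sequence",
    "Selection",
    "Dataset",
    "ParadigmParams",
    "code_of",
    "decode_code",
    "target_codes",
    "count_signals",
    "validate",
]

Label = Literal["target", "nontarget", "unknown"]

#: Standard 6x6 speller grid (letters A-Z then digits, '9' last).
DEFAULT_SYMBOLS = [
    list("ABCDEF"),
    list("GHIJKL"),
    list("MNOPQR"),
    list("STUVWX"),
    list("YZ1234"),
    list("56789_"),
]


@dataclass(frozen=True)
class SymbolMatrix:
    """An ``n x m`` grid of distinct printable symbols.

    Positions are (row, column), 1-based.  ``symbol_at(2, 3)`` returns the
    symbol in row 2, column 3.
    """

    symbols: tuple[tuple[str, ...], ...]

    def __init__(self, symbols: TySequence[TySequence[str]] | None = None):
        if symbols is None:
            symbols = DEFAULT_SYMBOLS
        rows = tuple(tuple(r) for r in symbols)
        if not rows or not rows[0]:
            raise ValueError("symbol matrix must have at least one row and column")
        m = len(rows[0])
        if any(len(r) != m for r in rows):
            raise ValueError("symbol matrix rows must all have equal length")
        flat = [s for r in rows for s in r]
        if len(set(flat)) != len(flat):
            raise ValueError("symbols must be distinct")
        object.__setattr__(self, "symbols", rows)

    @property
    def n(self) -> int:
        return len(self.symbols)

    @property
    def m(self) -> int:
        return len(self.symbols[0])

    def symbol_at(self, row: int, col: int) -> str:
        if not (1 <= row <= self.n and 1 <= col <= self.m):
            raise ValueError(f"position ({row}, {col}) outside {self.n}x{self.m} matrix")
        return self.symbols[row - 1][col - 1]

    def position_of(self, symbol: str) -> tuple[int, int]:
        for i, r in enumerate(self.symbols, start=1):
            for j, s in enumerate(r, start=1):
                if s == symbol:
                    return (i, j)
        raise KeyError(symbol)


@dataclass
class Epoch:
    """One post-stimulus EEG window: ``channels x samples`` in microvolts."""

    data: np.ndarray
    fs: float
    code: int
    label: Label = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Sequence:
    """One randomized pass: ``n + m`` epochs whose codes are a permutation of 1..n+m."""

    epochs: list[Epoch]

    def codes(self) -> list[int]:
        return [e.code for e in self.epochs]

    def epoch_for_code(self, code: int) -> Epoch:
        for e in self.epochs:
            if e.code == code:
                return e
        raise ValueError(f"sequence has no epoch with code {code}")


@dataclass
class Selection:
    """``alpha`` sequences spelling one symbol; ``true_symbol`` is its (row, col)."""

    sequences: list[Sequence]
    true_symbol: tuple[int, int] | None = None

    @property
    def alpha(self) -> int:
        return len(self.sequences)

    def epochs(self) -> list[Epoch]:
        return [e for s in self.sequences for e in s.epochs]


@dataclass(frozen=True)
class ParadigmParams:
    """Paradigm geometry and recording parameters shared by a dataset."""

    n: int = 6
    m: int = 6
    alpha: int = 15
    fs: float = 240.0
    n_channels: int = 64
    window_ms: float = 667.0

    @property
    def codes_per_sequence(self) -> int:
        return self.n + self.m


@dataclass
class Dataset:
    """``beta`` selections plus the paradigm parameters they were recorded under."""

    selections: list[Selection]
    paradigm: ParadigmParams = field(default_factory=ParadigmParams)

    @property
    def beta(self) -> int:
        return len(self.selections)

    def n_epochs(self) -> int:
        return sum(len(s.epochs()) for s in self.selections)

    def epochs(self) -> list[Epoch]:
        return [e for s in self.selections for e in s.epochs()]


def code_of(axis: Literal["row", "column"], index: int, n: int, m: int) -> int:
    """Serial stimulus code of a row or column (columns 1..m, rows m+1..m+n)."""
    if axis == "column":
        if not 1 <= index <= m:
            raise ValueError(f"column index {index} outside 1..{m}")
        return index
    if axis == "row":
        if not 1 <= index <= n:
            raise ValueError(f"row index {index} outside 1..{n}")
        return m + index
    raise ValueError(f"axis must be 'row' or 'column', got {axis!r}")


def decode_code(code: int, n: int, m: int) -> tuple[Literal["row", "column"], int]:
    """Inverse of :func:`code_of`: map a serial code back to (axis, 1-based index)."""
    if 1 <= code <= m:
        return ("column", code)
    if m < code <= m + n:
        return ("row", code - m)
    raise ValueError(f"code {code} outside 1..{n + m}")


def target_codes(true_symbol: tuple[int, int], n: int, m: int) -> set[int]:
    """The two stimulus codes (its column and its row) that flash the target symbol."""
    row, col = true_symbol
    return {code_of("column", col, n, m), code_of("row", row, n, m)}


def count_signals(
    level: Literal["sequence", "selection", "dataset"],
    n: int,
    m: int,
    alpha: int | None = None,
    beta: int | None = None,
) -> int:
    """Number of post-stimulus epochs at a given structural level.

    sequence -> n+m; selection -> alpha*(n+m); dataset -> beta*alpha*(n+m).
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    if level == "sequence":
        return n + m
    if level == "selection":
        if alpha is None or alpha < 1:
            raise ValueError("alpha required and positive for selection level")
        return alpha * (n + m)
    if level == "dataset":
        if alpha is None or alpha < 1 or beta is None or beta < 1:
            raise ValueError("alpha and beta required and positive for dataset level")
        return beta * alpha * (n + m)
    raise ValueError(f"unknown level {level!r}")


def validate(dataset: Dataset) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the dataset is well formed: each sequence's codes are a
    permutation of 1..n+m, every selection has alpha sequences, labeled
    sequences carry exactly the two target epochs implied by the true symbol,
    and epoch shapes match the paradigm parameters.
    """
    p = dataset.paradigm
    ncodes = p.codes_per_sequence
    expected_codes = set(range(1, ncodes + 1))
    violations: list[str] = []
    for si, sel in enumerate(dataset.selections, start=1):
        if sel.alpha != p.alpha:
            violations.append(
                f"selection {si}: has {sel.alpha} sequences, expected alpha={p.alpha}"
            )
        tcodes: set[int] | None = None
        if sel.true_symbol is not None:
            r, c = sel.true_symbol
            if not (1 <= r <= p.n and 1 <= c <= p.m):
                violations.append(f"selection {si}: true_symbol {sel.true_symbol} out of range")
            else:
                tcodes = target_codes(sel.true_symbol, p.n, p.m)
        for qi, seq in enumerate(sel.sequences, start=1):
            codes = seq.codes()
            if sorted(codes) != sorted(expected_codes):
                violations.append(
                    f"selection {si} sequence {qi}: codes {sorted(codes)} are not a "
                    f"permutation of 1..{ncodes}"
                )
                continue
            labels = {e.code: e.label for e in seq.epochs}
            labeled = [c for c, l in labels.items() if l != "unknown"]
            if labeled and tcodes is not None:
                got_targets = {c for c, l in labels.items() if l == "target"}
                if got_targets != tcodes:
                    violations.append(
                        f"selection {si} sequence {qi}: target-labeled codes "
                        f"{sorted(got_targets)} do not match target codes {sorted(tcodes)}"
                    )
            for e in seq.epochs:
                if e.n_channels != p.n_channels:
                    violations.append(
                        f"selection {si} sequence {qi} code {e.code}: "
                        f"{e.n_channels} channels, expected {p.n_channels}"
                    )
                    break
    return violations
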