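"""Dataset container read/write, model persistence, and the optional
BCI Competition III dataset II reader.

Container layout: a directory holding ``epochs.npy`` (one float array of
shape ``n_epochs x channels x samples``, selection-major then sequence-major
order) and a ``meta.json`` sidecar with the paradigm parameters, the
per-epoch stimulus codes and labels, and the per-selection true symbols.
The round trip ``read_container(write_container(d))`` is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np

from .paradigm import Dataset, Epoch, ParadigmParams, Selection, Sequence
from .strategies import TrainedStrategy

__all__ = [
    "write_container",
    "read_container",
    "read_bci3",
    "save_strategy",
    "load_strategy",
    "FormatError",
]

CONTAINER_VERSION = "1"

META_KEYS = ("version", "n", "m", "alpha", "beta", "fs", "n_channels",
             "window_ms", "codes", "labels", "true_symbols")


class FormatError(ValueError):
    """Raised when a container or external file does not match its format."""


def write_container(dataset: Dataset, path: str | Path, provenance: dict | None = None) -> Path:
    """Write a dataset to a container directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    p = dataset.paradigm
    epochs = dataset.epochs()
    arr = np.stack([e.data for e in epochs]) if epochs else np.empty((0, p.n_channels, 0))
    meta = {
        "version": CONTAINER_VERSION,
        "n": p.n,
        "m": p.m,
        "alpha": p.alpha,
        "beta": dataset.beta,
        "fs": p.fs,
        "n_channels": p.n_channels,
        "window_ms": p.window_ms,
        "codes": [e.code for e in epochs],
        "labels": [e.label for e in epochs],
        "true_symbols": [
            list(s.true_symbol) if s.true_symbol is not None else None
            for s in dataset.selections
        ],
        "provenance": provenance or {},
    }
    np.save(path / "epochs.npy", arr)
    (path / "meta.json").write_text(json.dumps(meta))
    return path


def read_container(path: str | Path) -> Dataset:
    """Read a container directory back into a Dataset (inverse of write)."""
    path = Path(path)
    meta_path, arr_path = path / "meta.json", path / "epochs.npy"
    if not meta_path.exists() or not arr_path.exists():
        raise FormatError(f"{path} is not a dataset container (meta.json / epochs.npy missing)")
    meta = json.loads(meta_path.read_text())
    for key in META_KEYS:
        if key not in meta:
            raise FormatError(f"container metadata missing key {key!r}")
    arr = np.load(arr_path)
    n, m, alpha, beta = meta["n"], meta["m"], meta["alpha"], meta["beta"]
    per_seq = n + m
    expected = beta * alpha * per_seq
    if arr.shape[0] != expected:
        raise FormatError(
            f"epoch array has {arr.shape[0]} epochs, metadata implies {expected}"
        )
    if len(meta["codes"]) != expected or len(meta["labels"]) != expected:
        raise FormatError("codes/labels length does not match epoch count")
    if len(meta["true_symbols"]) != beta:
        raise FormatError("true_symbols length does not match beta")
    paradigm = ParadigmParams(
        n=n, m=m, alpha=alpha, fs=meta["fs"],
        n_channels=meta["n_channels"], window_ms=meta["window_ms"],
    )
    selections = []
    k = 0
    for si in range(beta):
        ts = meta["true_symbols"][si]
        sequences = []
        for _ in range(alpha):
            epochs = []
            for _ in range(per_seq):
                epochs.append(
                    Epoch(arr[k], paradigm.fs, meta["codes"][k], meta["labels"][k])
                )
                k += 1
            sequences.append(Sequence(epochs=epochs))
        selections.append(
            Selection(sequences=sequences, true_symbol=tuple(ts) if ts else None)
        )
    return Dataset(selections=selections, paradigm=paradigm)


def save_strategy(strategy: TrainedStrategy, path: str | Path) -> Path:
    """Persist a trained strategy (learners + weights + configs) with joblib."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(strategy, path)
    return path


def load_strategy(path: str | Path) -> TrainedStrategy:
    obj = joblib.load(path)
    if not isinstance(obj, TrainedStrategy):
        raise FormatError(f"{path} does not contain a trained strategy")
    return obj


# --- optional reader for the BCI Competition III dataset II MATLAB files ---

_MATRIX_ROWS = ["ABCDEF", "GHIJKL", "MNOPQR", "STUVWX", "YZ1234", "56789_"]


def _char_position(ch: str) -> tuple[int, int]:
    for i, row in enumerate(_MATRIX_ROWS, start=1):
        j = row.find(ch.upper()) + 1
        if j:
            return (i, j)
    raise FormatError(f"character {ch!r} not in the 6x6 speller matrix")


def _load_mat(path: Path) -> dict:
    try:
        from scipy.io import loadmat
    except ImportError as e:  # pragma: no cover
        raise RuntimeError("scipy is required to read MATLAB files") from e
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: external data required — the speller competition files are "
            "not distributed with this package and must be supplied locally"
        )
    return loadmat(str(path), squeeze_me=False)


def read_bci3(
    path: str | Path,
    fs: float = 240.0,
    window_ms: float = 667.0,
    alpha: int = 15,
) -> Dataset:
    """Read one subject file of the P300 speller competition recordings.

    Expects the MATLAB fields ``Signal`` (selections x time x channels),
    ``StimulusCode`` (selections x time), and optionally ``StimulusType``
    and ``TargetChar`` (training files only).  Epochs are cut at each
    rising edge of the stimulus code and grouped into sequences of 12 in
    presentation order.
    """
    path = Path(path)
    mat = _load_mat(path)
    for fld in ("Signal", "StimulusCode"):
        if fld not in mat:
            raise FormatError(f"{path}: MATLAB field {fld!r} missing")
    sig = np.asarray(mat["Signal"], dtype=float)          # (beta, time, channels)
    scode = np.asarray(mat["StimulusCode"])               # (beta, time)
    if sig.ndim != 3 or scode.ndim != 2 or sig.shape[:2] != scode.shape:
        raise FormatError(f"{path}: Signal/StimulusCode shapes are inconsistent")
    stype = np.asarray(mat["StimulusType"]) if "StimulusType" in mat else None
    tchar = mat.get("TargetChar")
    if tchar is not None:
        tchar = "".join(np.asarray(tchar).astype(str).ravel())

    beta, n_time, n_channels = sig.shape
    T = int(np.floor(window_ms * fs / 1000.0))
    per_seq = 12
    selections = []
    for b in range(beta):
        codes_t = scode[b]
        # rising edges: first sample where the code becomes nonzero
        onsets = np.flatnonzero((codes_t[1:] > 0) & (codes_t[:-1] == 0)) + 1
        if codes_t[0] > 0:
            onsets = np.concatenate(([0], onsets))
        flashes = []
        for on in onsets:
            if on + T > n_time:
                raise FormatError(
                    f"{path}: epoch at onset {on} exceeds recording length {n_time}"
                )
            code = int(codes_t[on])
            label = "unknown"
            if stype is not None:
                label = "target" if int(stype[b, on]) == 1 else "nontarget"
            flashes.append(Epoch(sig[b, on : on + T, :].T.copy(), fs, code, label))
        if len(flashes) != alpha * per_seq:
            raise FormatError(
                f"{path}: selection {b + 1} has {len(flashes)} flashes, "
                f"expected {alpha * per_seq}"
            )
        sequences = [
            Sequence(epochs=flashes[i * per_seq : (i + 1) * per_seq]) for i in range(alpha)
        ]
        true_symbol = _char_position(tchar[b]) if tchar else None
        selections.append(Selection(sequences=sequences, true_symbol=true_symbol))
    paradigm = ParadigmParams(
        n=6, m=6, alpha=alpha, fs=fs, n_channels=n_channels, window_ms=window_ms
    )
    return Dataset(selections=selections, paradigm=paradigm)
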