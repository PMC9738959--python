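"""Epoch preprocessing: window extraction, IIR bandpass, decimation, flattening.

The pipeline turns a raw post-stimulus epoch into a flat feature vector:

1. extract the 0-667 ms window after the intensification onset
   (160 samples at 240 Hz);
2. bandpass 0.1-10 Hz with an order-8 Butterworth IIR filter, applied
   causally by default (the speller is an online paradigm);
3. decimate by keeping every r-th sample, r = floor(fs / (2 f_high)) = 12,
   leaving 14 samples per channel (the bandpass is the anti-alias stage);
4. concatenate channels (channel-major), giving 896 = 14 x 64 features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

from .paradigm import Dataset, Epoch

__all__ = [
    "PreprocessConfig",
    "extract_epoch",
    "bandpass",
    "decimate_epoch",
    "featurize",
    "preprocess_epoch",
    "preprocess_dataset",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter and windowing parameters.

    Parameters
    ----------
    window_ms : float
        Post-stimulus window length in milliseconds (default 667).
    f_low, f_high : float
        Bandpass edges in Hz (defaults 0.1 and 10).
    filter_order : int
        Total IIR filter order; must be even (default 8).
    fs : float
        Sampling rate in Hz (default 240).
    zero_phase : bool
        If True filter forward-backward (non-causal); default False (causal).
    """

    window_ms: float = 667.0
    f_low: float = 0.1
    f_high: float = 10.0
    filter_order: int = 8
    fs: float = 240.0
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high < self.fs / 2):
            raise ValueError(
                f"need 0 < f_low < f_high < fs/2, got {self.f_low}, {self.f_high}, fs={self.fs}"
            )
        if self.filter_order < 2 or self.filter_order % 2:
            raise ValueError(f"filter_order must be even and >= 2, got {self.filter_order}")

    @property
    def window_samples(self) -> int:
        """Epoch length in samples; fractional samples truncate."""
        return int(math.floor(self.window_ms * self.fs / 1000.0))

    @property
    def decimation_factor(self) -> int:
        """Subsampling step r = floor(fs / (2 f_high))."""
        r = int(math.floor(self.fs / (2.0 * self.f_high)))
        if r < 1:
            raise ValueError(f"decimation factor {r} < 1; lower f_high or raise fs")
        return r

    @property
    def samples_per_channel(self) -> int:
        """Samples kept per channel after decimation: ceil(T / r)."""
        return -(-self.window_samples // self.decimation_factor)

    def sos(self) -> np.ndarray:
        """Second-order sections of the Butterworth bandpass (total order = filter_order)."""
        sos = sps.butter(
            self.filter_order // 2,
            [self.f_low, self.f_high],
            btype="bandpass",
            fs=self.fs,
            output="sos",
        )
        if not np.all(np.isfinite(sos)):
            raise ValueError("unstable filter design for the given configuration")
        return sos

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)


def extract_epoch(
    signal: np.ndarray,
    onset_sample: int,
    config: PreprocessConfig,
    code: int = 1,
    label: str = "unknown",
) -> Epoch:
    """Cut the post-stimulus window from a continuous ``channels x time`` recording."""
    signal = np.asarray(signal, dtype=float)
    T = config.window_samples
    if T < 1:
        raise ValueError(f"window of {config.window_ms} ms at {config.fs} Hz is empty")
    if onset_sample < 0 or onset_sample + T > signal.shape[1]:
        raise ValueError(
            f"epoch window [{onset_sample}, {onset_sample + T}) exceeds signal "
            f"length {signal.shape[1]}"
        )
    return Epoch(signal[:, onset_sample : onset_sample + T].copy(), config.fs, code, label)  # type: ignore[arg-type]


def bandpass(epoch: Epoch, config: PreprocessConfig) -> Epoch:
    """Bandpass-filter each channel; removes DC, keeps 0.1-10 Hz near unit gain."""
    sos = config.sos()
    if config.zero_phase:
        filtered = sps.sosfiltfilt(sos, epoch.data, axis=1)
    else:
        filtered = sps.sosfilt(sos, epoch.data, axis=1)
    return Epoch(np.asarray(filtered), epoch.fs, epoch.code, epoch.label)


def decimate_epoch(epoch: Epoch, config: PreprocessConfig) -> Epoch:
    """Keep every r-th sample of an already-bandpassed epoch."""
    r = config.decimation_factor
    return Epoch(epoch.data[:, ::r].copy(), epoch.fs / r, epoch.code, epoch.label)


def featurize(epoch: Epoch) -> np.ndarray:
    """Flatten a decimated epoch channel-major into one feature vector."""
    vec = epoch.data.reshape(-1)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite values in epoch; cannot featurize")
    return vec


def preprocess_epoch(epoch: Epoch, config: PreprocessConfig) -> np.ndarray:
    """Full per-epoch pipeline: bandpass, decimate, flatten."""
    return featurize(decimate_epoch(bandpass(epoch, config), config))


def preprocess_dataset(
    dataset: Dataset, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, list[str], list[tuple[int, int, int]]]:
    """Preprocess every epoch of a dataset, preserving order.

    Returns
    -------
    features : ndarray, shape (n_epochs, C * k)
    labels : list of str
        Per-epoch labels ("target" / "nontarget" / "unknown").
    index : list of (selection, sequence, code)
        1-based coordinates of each row, so the selection/sequence structure
        can be reconstructed from the flat arrays.
    """
    if config is None:
        config = PreprocessConfig(window_ms=dataset.paradigm.window_ms, fs=dataset.paradigm.fs)
    feats: list[np.ndarray] = []
    labels: list[str] = []
    index: list[tuple[int, int, int]] = []
    sos = config.sos()
    r = config.decimation_factor
    filt = sps.sosfiltfilt if config.zero_phase else sps.sosfilt
    for si, sel in enumerate(dataset.selections, start=1):
        for qi, seq in enumerate(sel.sequences, start=1):
            for ep in seq.epochs:
                x = np.asarray(filt(sos, ep.data, axis=1))[:, ::r].reshape(-1)
                if not np.all(np.isfinite(x)):
                    raise ValueError(
                        f"non-finite feature at selection {si}, sequence {qi}, code {ep.code}"
                    )
                feats.append(x)
                labels.append(ep.label)
                index.append((si, qi, ep.code))
    if not feats:
        return np.empty((0, 0)), [], []
    return np.vstack(feats), labels, index
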