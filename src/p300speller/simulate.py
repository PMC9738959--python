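"""Synthetic oddball-EEG generator for the RC speller paradigm.

Emulates exactly the structure the decoders assume: a 6x6 symbol matrix,
alpha = 15 sequences per selection, each sequence a fresh random permutation
of the 12 stimulus codes with exactly 2 target flashes (the target symbol's
row and column), 64-channel epochs at 240 Hz.  Target epochs carry a
positive Gaussian-shaped deflection peaking ~300 ms post-stimulus on a
fixed parietal channel block; every epoch gets additive Gaussian noise
(optionally AR(1)-colored).

The generator produces epochs directly; inter-stimulus timing and the
continuous recording stream are not simulated, because the decoders consume
epochs, never the stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .paradigm import (
    Dataset,
    Epoch,
    ParadigmParams,
    Selection,
    Sequence,
    target_codes,
)

__all__ = ["SimulationConfig", "generate_sequence_codes", "synth_epoch", "generate_dataset"]


def _default_p300_channels(n_channels: int) -> tuple[int, ...]:
    # fixed "parietal" block: the quarter of the montage just past its middle
    # (channels 33..48, 1-based, for the standard 64-channel cap)
    width = max(1, n_channels // 4)
    start = n_channels // 2 + 1
    return tuple(range(start, min(start + width, n_channels + 1)))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic RC-paradigm generator.

    Defaults reproduce the benchmark recording structure: n=m=6, alpha=15
    sequences per selection, beta=85 selections, 64 channels at 240 Hz with
    667 ms epochs.  The P300 template is a Gaussian bump of amplitude 5 uV
    (SD 50 ms) peaking at 300 ms on the parietal block; background noise is
    white Gaussian with SD 1 uV.
    """

    n: int = 6
    m: int = 6
    alpha: int = 15
    beta: int = 85
    n_channels: int = 64
    fs: float = 240.0
    window_ms: float = 667.0
    p300_amplitude: float = 5.0
    p300_latency_ms: float = 300.0
    p300_width_ms: float = 50.0
    latency_jitter_ms: float = 0.0
    noise_sd: float = 1.0
    noise_ar1: float = 0.0  # AR(1) coefficient; 0 = white noise
    p300_channels: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p300_channels is None:
            object.__setattr__(self, "p300_channels", _default_p300_channels(self.n_channels))
        if min(self.n, self.m, self.alpha, self.beta, self.n_channels) < 1:
            raise ValueError("paradigm sizes must be positive")
        if not self.p300_latency_ms < self.window_ms:
            raise ValueError("p300_latency_ms must fall inside the epoch window")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must be in [0, 1)")
        if any(not 1 <= c <= self.n_channels for c in self.p300_channels):
            raise ValueError("p300_channels must be 1-based channel numbers within range")

    @property
    def window_samples(self) -> int:
        return int(math.floor(self.window_ms * self.fs / 1000.0))

    @property
    def paradigm(self) -> ParadigmParams:
        return ParadigmParams(
            n=self.n, m=self.m, alpha=self.alpha, fs=self.fs,
            n_channels=self.n_channels, window_ms=self.window_ms,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["p300_channels"] = list(self.p300_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "p300_channels" in d:
            d["p300_channels"] = tuple(d["p300_channels"])
        return cls(**d)


def generate_sequence_codes(n: int, m: int, rng: np.random.Generator) -> list[int]:
    """Uniform random flash order: a permutation of the codes 1..n+m."""
    return list(rng.permutation(np.arange(1, n + m + 1)))


def _p300_template(config: SimulationConfig, latency_ms: float) -> np.ndarray:
    """Noiseless target deflection, shape (channels, samples)."""
    T = config.window_samples
    t_ms = np.arange(T) / config.fs * 1000.0
    bump = config.p300_amplitude * np.exp(
        -0.5 * ((t_ms - latency_ms) / config.p300_width_ms) ** 2
    )
    tpl = np.zeros((config.n_channels, T))
    idx = [c - 1 for c in config.p300_channels]
    tpl[idx, :] = bump
    return tpl


def synth_epoch(
    is_target: bool, config: SimulationConfig, rng: np.random.Generator, code: int = 1
) -> Epoch:
    """One synthetic post-stimulus epoch: noise plus, for targets, the P300 bump."""
    T = config.window_samples
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_channels, T))
    if config.noise_ar1 > 0 and config.noise_sd > 0:
        # AR(1) coloring with variance-preserving innovation scale
        phi = config.noise_ar1
        colored = np.empty_like(noise)
        colored[:, 0] = noise[:, 0]
        scale = math.sqrt(1.0 - phi * phi)
        for t in range(1, T):
            colored[:, t] = phi * colored[:, t - 1] + scale * noise[:, t]
        noise = colored
    data = noise
    if is_target:
        latency = config.p300_latency_ms
        if config.latency_jitter_ms > 0:
            latency += rng.normal(0.0, config.latency_jitter_ms)
        data = data + _p300_template(config, latency)
    return Epoch(data, config.fs, code, "target" if is_target else "nontarget")


def generate_dataset(config: SimulationConfig, seed: int | None = None) -> Dataset:
    """Generate a fully labeled dataset of ``beta`` selections.

    Target symbols are drawn uniformly over the grid; every sequence is a
    fresh random permutation of the stimulus codes; epoch labels follow from
    the target symbol's row/column codes.  Bit-reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    selections = []
    for _ in range(config.beta):
        row = int(rng.integers(1, config.n + 1))
        col = int(rng.integers(1, config.m + 1))
        tcodes = target_codes((row, col), config.n, config.m)
        sequences = []
        for _ in range(config.alpha):
            codes = generate_sequence_codes(config.n, config.m, rng)
            epochs = [
                synth_epoch(code in tcodes, config, rng, code=int(code)) for code in codes
            ]
            sequences.append(Sequence(epochs=epochs))
        selections.append(Selection(sequences=sequences, true_symbol=(row, col)))
    return Dataset(selections=selections, paradigm=config.paradigm)
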