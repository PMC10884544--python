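"""Rician magnitude noise for diffusion-weighted signals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSpec", "add_rician"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise level specified as SNR on the b=0, TE=0 signal.

    sigma = S(b=0, TE=0) / snr; for the normalised forward model the
    reference signal is 1, so sigma = 1/snr.
    """

    snr: float = 100.0
    s0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.s0 <= 0:
            raise ValueError("s0 must be > 0")

    @property
    def sigma(self) -> float:
        return self.s0 / self.snr

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def add_rician(signals, sigma: float, rng: np.random.Generator):
    """Rician-corrupt signals: sqrt((S + e1)^2 + e2^2), e1, e2 ~ N(0, sigma).

    This is the magnitude of a complex Gaussian perturbation of the
    noiseless signal; the output is non-negative and biased upward at low
    SNR (Rayleigh floor sigma*sqrt(pi/2) at S = 0).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s = np.asarray(signals, dtype=float)
    if np.any(s < 0):
        raise ValueError("signals must be >= 0")
    if sigma == 0:
        return s.copy()
    e1 = rng.normal(0.0, sigma, size=s.shape)
    e2 = rng.normal(0.0, sigma, size=s.shape)
    return np.sqrt((s + e1) ** 2 + e2**2)
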