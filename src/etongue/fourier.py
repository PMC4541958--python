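"""FFT compression of current traces and reconstruction-fidelity scoring.

A trace of n samples is compressed to its first k one-sided discrete Fourier
coefficients (index 0 is the DC/mean term).  Reconstruction zero-fills the
discarded coefficients and inverts with conjugate symmetry, so the output is
real.  Fidelity is scored with fc, the ratio of the area shared by the raw
and reconstructed curves to the area of their union, after shifting both by
their common minimum so "area under the curve" is well defined for signed
traces:

    fc = sum_i min(f~_i, g~_i) / sum_i max(f~_i, g~_i),
    f~ = f - m,  m = min(0, min f, min g)

fc = 1 iff the curves are identical; fc = 0 when the shifted curves share no
mass.  The compression ratio is (1 - k/n) x 100%, reported to two decimals by
truncation.

Plain rectangular sums (not trapezoids) are used throughout: sampling is
uniform and plain sums are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import Voltammogram


@dataclass(frozen=True)
class SpectralCompression:
    """The leading one-sided DFT coefficients of a real signal."""

    coefficients: np.ndarray  # complex, length min(k, n//2 + 1)
    original_length: int
    k: int

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.original_length):
            raise ValueError("k must satisfy 1 <= k <= original_length")


@dataclass(frozen=True)
class FeatureVector:
    """A flat real feature vector with its extraction mode tag."""

    values: np.ndarray
    mode: str  # "fft" or "landmark"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


def compress(signal: np.ndarray, k: int) -> SpectralCompression:
    """Keep the first ``k`` one-sided DFT coefficients of a real signal.

    The one-sided spectrum of a length-n real signal has n//2 + 1 distinct
    coefficients; requesting more keeps them all (and still reconstructs
    perfectly).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("signal must be non-empty")
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > signal.size:
        raise ValueError(f"k={k} exceeds signal length {signal.size}")
    spectrum = np.fft.rfft(signal)
    kept = spectrum[: min(k, spectrum.size)].copy()
    return SpectralCompression(
        coefficients=kept, original_length=signal.size, k=k
    )


def reconstruct(c: SpectralCompression) -> np.ndarray:
    """Inverse transform with the discarded coefficients set to zero."""
    n = c.original_length
    full = np.zeros(n // 2 + 1, dtype=complex)
    full[: c.coefficients.size] = c.coefficients
    return np.fft.irfft(full, n=n)


def fc(raw: np.ndarray, recon: np.ndarray) -> float:
    """Reconstruction degree in [0, 1]; 1 iff the two curves are identical."""
    raw = np.asarray(raw, dtype=float)
    recon = np.asarray(recon, dtype=float)
    if raw.shape != recon.shape:
        raise ValueError(f"length mismatch: {raw.shape} vs {recon.shape}")
    # areas are undefined for signed traces: shift by the common minimum,
    # but only when some value is negative (non-negative curves compare
    # as-is)
    m = min(0.0, raw.min(), recon.min())
    f = raw - m
    g = recon - m
    union = np.maximum(f, g).sum()
    if union == 0.0:  # both curves constant and equal
        return 1.0
    return float(np.minimum(f, g).sum() / union)


def compression_ratio(k: int, n: int) -> float:
    """(1 - k/n) x 100, truncated (not rounded) to two decimals."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    ratio = (1.0 - k / n) * 100.0
    return math.floor(ratio * 100.0) / 100.0


def extract_fft_features(v: Voltammogram, k: int = 16) -> FeatureVector:
    """Magnitudes of the first ``k`` coefficients per channel, concatenated.

    With the default k = 16 and four channels this yields the 64-value input
    vector of the 64-32-1 network topology.  Phase is discarded.
    """
    blocks = []
    for ch in v.channels:
        comp = compress(v.currents[ch], k)
        mags = np.abs(comp.coefficients)
        if mags.size < k:  # short signals: pad so the layout stays fixed
            mags = np.pad(mags, (0, k - mags.size))
        blocks.append(mags)
    return FeatureVector(values=np.concatenate(blocks), mode="fft")
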