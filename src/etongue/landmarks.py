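"""Landmark ("special data point") features: peaks, troughs and inflections.

The alternative to FFT features is an 18-value vector of characteristic
current values read off each electrode's trace: 5 from Pt, 3 from Ag, 5 from
Au and 5 from Pd.  The original points were circled by eye on current-time
charts; here detection is operationalized as:

1. moving-average smoothing (odd window, plain box kernel);
2. candidate extrema = peaks of the smoothed trace and of its negation,
   candidate inflections = peaks of +/- the first derivative (an inflection
   of f is an extremum of f');
3. candidates are ranked by prominence — derivative prominences are scaled
   by the window length to put them on the current scale — and the top m are
   kept, greedily skipping candidates within one window of an already
   selected, stronger one;
4. the selected landmarks are returned in index order with their smoothed
   current values.

Ties in prominence break toward the lower index, so extraction is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .data import Voltammogram
from .fourier import FeatureVector

DEFAULT_COUNTS: dict[str, int] = {"Pt": 5, "Ag": 3, "Au": 5, "Pd": 5}


class LandmarkError(RuntimeError):
    """A channel did not expose enough prominent landmarks."""


@dataclass(frozen=True)
class LandmarkSpec:
    """Detection settings: per-channel landmark counts, smoothing, prominence.

    ``min_prominence`` is a fraction of the smoothed channel's signal range;
    candidates below it are discarded before ranking.
    """

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    window: int = 25
    min_prominence: float = 0.02

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if not (0 <= self.min_prominence < 1):
            raise ValueError("min_prominence must lie in [0, 1)")
        if sum(self.counts.values()) != 18:
            raise ValueError("per-channel landmark counts must sum to 18")

    @property
    def n_features(self) -> int:
        return sum(self.counts.values())


def _smooth(signal: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return signal.astype(float)
    half = window // 2
    padded = np.pad(signal.astype(float), half, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def find_landmarks(
    signal: np.ndarray,
    count: int,
    spec: LandmarkSpec | None = None,
    channel: str = "?",
) -> list[tuple[int, float]]:
    """Locate the ``count`` most prominent landmarks of one channel trace.

    Returns (index, smoothed current value) pairs in index order.  Raises
    :class:`LandmarkError` naming the channel when fewer than ``count``
    sufficiently prominent candidates exist.
    """
    spec = spec or LandmarkSpec()
    signal = np.asarray(signal, dtype=float)
    if signal.size < spec.window:
        raise ValueError("signal shorter than the smoothing window")
    smooth = _smooth(signal, spec.window)
    amp_range = float(smooth.max() - smooth.min())
    if amp_range == 0.0:
        raise LandmarkError(f"channel {channel}: constant signal has no landmarks")
    prom_min = spec.min_prominence * amp_range

    # landmarks are interior features: trim one window off each end so
    # smoothing edge effects cannot spawn candidates
    w = spec.window
    candidates: list[tuple[float, int]] = []  # (score, index)
    for sgn in (1.0, -1.0):
        idx, props = find_peaks(sgn * smooth[w:-w], prominence=prom_min)
        candidates += [(p, i + w) for i, p in zip(idx, props["prominences"])]
    deriv = np.gradient(smooth)
    for sgn in (1.0, -1.0):
        idx, props = find_peaks(sgn * deriv[w:-w], prominence=prom_min / w)
        candidates += [(p * w, i + w) for i, p in zip(idx, props["prominences"])]

    # strongest first; prominence ties break toward the lower index
    candidates.sort(key=lambda t: (-t[0], t[1]))
    chosen: list[int] = []
    for _, i in candidates:
        if all(abs(i - j) > spec.window for j in chosen):
            chosen.append(i)
        if len(chosen) == count:
            break
    if len(chosen) < count:
        raise LandmarkError(
            f"channel {channel}: found {len(chosen)} landmarks, need {count}"
        )
    chosen.sort()
    return [(i, float(smooth[i])) for i in chosen]


def extract_landmark_features(
    v: Voltammogram, spec: LandmarkSpec | None = None
) -> FeatureVector:
    """Concatenate landmark current values Pt(5), Ag(3), Au(5), Pd(5)."""
    spec = spec or LandmarkSpec()
    blocks = []
    for ch in v.channels:
        marks = find_landmarks(v.currents[ch], spec.counts[ch], spec, channel=ch)
        blocks.append(np.array([val for _, val in marks]))
    return FeatureVector(values=np.concatenate(blocks), mode="landmark")
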