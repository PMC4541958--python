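"""Core domain types for voltammetric electronic-tongue datasets.

A measurement is one cyclic-voltammetry sweep recorded simultaneously on four
metallic working electrodes (Pt, Ag, Au, Pd).  The full experimental design is
4 rice varieties x 4 commercial samples per variety x 5 replicate measurements
= 80 records per dilution level, each record a 4 x 3986 block of current
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical working-electrode order used for every concatenated feature /
#: matrix layout in the package.
CHANNELS: tuple[str, ...] = ("Pt", "Ag", "Au", "Pd")

#: Fixed class-code mapping (code -> variety).  Never inferred from sort order.
CODE_TO_LABEL: dict[int, str] = {
    1: "JiaHe218",
    2: "JiaHe66",
    3: "XiuShui128",
    4: "XiuShui134",
}
LABEL_TO_CODE: dict[str, int] = {v: k for k, v in CODE_TO_LABEL.items()}

#: Class labels in class-code order 1..4.
CLASS_ORDER: tuple[str, ...] = tuple(CODE_TO_LABEL[c] for c in (1, 2, 3, 4))

#: Number of current samples per channel in the reference acquisition.
DEFAULT_RECORD_LENGTH = 3986

#: Dilution levels of the reference design.
DILUTIONS: tuple[int, ...] = (0, 5, 10, 100)


class SchemaError(ValueError):
    """A file or matrix does not match the documented dataset schema."""


@dataclass(frozen=True)
class ExcitationProgram:
    """Triangle-wave potential program of a cyclic-voltammetry sweep.

    Potentials in volts, ``scan_rate`` in V/s, ``sampling_rate`` in Hz.
    The sweep runs initial -> high -> low -> final at constant ``scan_rate``;
    with initial = final = low the waveform is the isosceles triangle of a
    standard CV cycle.
    """

    initial_potential: float = -2.0
    low_potential: float = -2.0
    high_potential: float = 2.0
    final_potential: float = -2.0
    scan_rate: float = 0.2
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        if not (self.low_potential <= self.initial_potential <= self.high_potential):
            raise ValueError("initial potential must lie in [low, high]")
        if not (self.low_potential <= self.final_potential <= self.high_potential):
            raise ValueError("final potential must lie in [low, high]")
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def sweep_span(self) -> float:
        """Total potential excursion of one cycle, in volts."""
        return (
            abs(self.high_potential - self.initial_potential)
            + abs(self.high_potential - self.low_potential)
            + abs(self.final_potential - self.low_potential)
        )

    @property
    def cycle_samples(self) -> int:
        """Number of samples spanned by one full cycle."""
        return round(self.sampling_rate * self.sweep_span / self.scan_rate)

    def to_dict(self) -> dict[str, float]:
        return {
            "initial_potential": self.initial_potential,
            "low_potential": self.low_potential,
            "high_potential": self.high_potential,
            "final_potential": self.final_potential,
            "scan_rate": self.scan_rate,
            "sampling_rate": self.sampling_rate,
        }


@dataclass
class Voltammogram:
    """One measurement: per-channel current traces plus the excitation program.

    ``currents`` maps channel name -> 1-D float array (amperes); all channels
    must have equal length.
    """

    currents: dict[str, np.ndarray]
    excitation: ExcitationProgram = field(default_factory=ExcitationProgram)

    def __post_init__(self) -> None:
        self.currents = {
            ch: np.asarray(v, dtype=float) for ch, v in self.currents.items()
        }
        lengths = {v.size for v in self.currents.values()}
        if len(lengths) > 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        for ch in self.currents:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}; expected one of {CHANNELS}")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(ch for ch in CHANNELS if ch in self.currents)

    @property
    def n_points(self) -> int:
        return next(iter(self.currents.values())).size

    def concatenated(self) -> np.ndarray:
        """Channel traces concatenated in canonical Pt, Ag, Au, Pd order."""
        return np.concatenate([self.currents[ch] for ch in self.channels])


@dataclass
class SampleRecord:
    """A labelled measurement within the experimental design."""

    voltammogram: Voltammogram
    class_label: str
    dilution: int
    replicate: int
    sample_id: int

    def __post_init__(self) -> None:
        if self.class_label not in LABEL_TO_CODE:
            raise ValueError(
                f"unknown class label {self.class_label!r}; "
                f"expected one of {CLASS_ORDER}"
            )
        if self.dilution < 0:
            raise ValueError("dilution must be non-negative")

    @property
    def class_code(self) -> int:
        return LABEL_TO_CODE[self.class_label]


@dataclass
class LabeledDataset:
    """A collection of labelled measurements sharing channel layout."""

    records: list[SampleRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_codes(self) -> np.ndarray:
        return np.array([r.class_code for r in self.records], dtype=int)

    @property
    def class_labels(self) -> list[str]:
        return [r.class_label for r in self.records]


def dataset_matrix(ds: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack a dataset into an (n_records, n_channels * n_points) matrix.

    Column blocks are ordered Pt, Ag, Au, Pd; the returned label vector holds
    class codes aligned with the rows.  An empty dataset yields a
    (0, 4 * 3986) matrix.
    """
    if not ds.records:
        return (
            np.empty((0, len(CHANNELS) * DEFAULT_RECORD_LENGTH)),
            np.empty(0, dtype=int),
        )
    lengths = {r.voltammogram.n_points for r in ds.records}
    channel_sets = {r.voltammogram.channels for r in ds.records}
    if len(lengths) > 1 or len(channel_sets) > 1:
        raise ValueError("records have heterogeneous channel layout or lengths")
    X = np.vstack([r.voltammogram.concatenated() for r in ds.records])
    return X, ds.class_codes


def matrix_to_dataset(
    X: np.ndarray,
    class_codes: np.ndarray,
    *,
    n_points: int | None = None,
    excitation: ExcitationProgram | None = None,
) -> LabeledDataset:
    """Inverse of :func:`dataset_matrix` for conforming matrices.

    Rows are split into four equal channel blocks (Pt, Ag, Au, Pd).  Metadata
    beyond the class code (dilution, replicate, sample id) is not recoverable
    from a bare matrix and is filled with placeholder values.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] % len(CHANNELS):
        raise ValueError("matrix width must be a multiple of the channel count")
    npts = n_points if n_points is not None else X.shape[1] // len(CHANNELS)
    if npts * len(CHANNELS) != X.shape[1]:
        raise ValueError("matrix width inconsistent with n_points")
    exc = excitation if excitation is not None else ExcitationProgram()
    records = []
    for row, code in zip(X, np.asarray(class_codes, dtype=int)):
        currents = {
            ch: row[i * npts : (i + 1) * npts] for i, ch in enumerate(CHANNELS)
        }
        records.append(
            SampleRecord(
                voltammogram=Voltammogram(currents=currents, excitation=exc),
                class_label=CODE_TO_LABEL[int(code)],
                dilution=0,
                replicate=1,
                sample_id=1,
            )
        )
    return LabeledDataset(records=records)


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 confusion matrix; rows = expected class, columns = predicted class.

    ``classes`` records the row/column label order explicitly, because the
    reference tables print classes in a different order than the class codes.
    """

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts must be square and match the class list")
        if (counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @classmethod
    def from_codes(
        cls, expected: np.ndarray, predicted: np.ndarray
    ) -> "ConfusionMatrix":
        """Accumulate a matrix from class-code vectors, canonical code order."""
        expected = np.asarray(expected, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        if expected.shape != predicted.shape:
            raise ValueError("expected/predicted length mismatch")
        g = len(CLASS_ORDER)
        counts = np.zeros((g, g), dtype=int)
        for e, p in zip(expected, predicted):
            counts[e - 1, p - 1] += 1
        return cls(counts=counts, classes=CLASS_ORDER)
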