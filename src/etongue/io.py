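"""Readers and writers for signal datasets and confusion-matrix fixtures.

Two on-disk layouts are supported for labelled signal sets:

* delimited text — one row per measurement; metadata columns
  (``class_label, class_code, dilution, replicate, sample_id``) followed by
  current columns named ``<channel>_<index>`` in canonical channel order.
  Excitation parameters are stored in ``# key=value`` comment lines before
  the header.  Comma separator, ``.`` decimal, full ``%.17g`` precision so a
  round trip is value-exact.
* HDF5 — one group per record (``rec00000`` ...), one dataset per channel,
  metadata and excitation parameters as attributes.  Round trips bit-exactly.

Confusion-matrix fixtures mirroring the published leave-one-out prediction
tables (one per dilution level) ship with the package as delimited files.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import (
    CHANNELS,
    LABEL_TO_CODE,
    ConfusionMatrix,
    ExcitationProgram,
    LabeledDataset,
    SampleRecord,
    SchemaError,
    Voltammogram,
)

_META_COLUMNS = ["class_label", "class_code", "dilution", "replicate", "sample_id"]
_FIXTURE_NAMES = ("dil0", "dil5", "dil10", "dil100")


def write_dataset(ds: LabeledDataset, path: str | Path, format: str = "delimited") -> None:
    """Write a dataset to ``path`` in ``delimited`` or ``hdf5`` format."""
    path = Path(path)
    if format == "delimited":
        _write_delimited(ds, path)
    elif format == "hdf5":
        _write_hdf5(ds, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_dataset(path: str | Path, format: str = "delimited") -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset`.

    Raises :class:`~etongue.data.SchemaError` on malformed headers, ragged
    rows or unknown class labels, naming the offending row where possible.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        return _read_delimited(path)
    if format == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {format!r}")


def _write_delimited(ds: LabeledDataset, path: Path) -> None:
    if not ds.records:
        raise ValueError("refusing to write an empty dataset")
    exc = ds.records[0].voltammogram.excitation
    npts = ds.records[0].voltammogram.n_points
    channels = ds.records[0].voltammogram.channels
    cols = _META_COLUMNS + [f"{ch}_{i}" for ch in channels for i in range(npts)]
    with open(path, "w") as fh:
        for key, val in exc.to_dict().items():
            fh.write(f"# {key}={val!r}\n")
        fh.write(",".join(cols) + "\n")
        for rec in ds.records:
            meta = [
                rec.class_label,
                str(rec.class_code),
                str(rec.dilution),
                str(rec.replicate),
                str(rec.sample_id),
            ]
            vals = rec.voltammogram.concatenated()
            fh.write(",".join(meta) + "," + ",".join(f"{v:.17g}" for v in vals) + "\n")


def _read_delimited(path: Path) -> LabeledDataset:
    exc_kwargs: dict[str, float] = {}
    header: list[str] | None = None
    rows: list[tuple[list[str], np.ndarray]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                exc_kwargs[key.strip()] = float(val)
                continue
            parts = line.split(",")
            if header is None:
                header = parts
                if parts[: len(_META_COLUMNS)] != _META_COLUMNS:
                    raise SchemaError(
                        f"{path}: line {lineno}: header must start with "
                        f"{_META_COLUMNS}, got {parts[:len(_META_COLUMNS)]}"
                    )
                continue
            if len(parts) != len(header):
                raise SchemaError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            meta = parts[: len(_META_COLUMNS)]
            try:
                vals = np.array(parts[len(_META_COLUMNS) :], dtype=float)
            except ValueError as err:
                raise SchemaError(f"{path}: line {lineno}: {err}") from err
            rows.append((meta, vals))
    if header is None:
        raise SchemaError(f"{path}: no header row found")

    signal_cols = header[len(_META_COLUMNS) :]
    channels, npts = _parse_signal_columns(signal_cols, path)
    exc = ExcitationProgram(**exc_kwargs) if exc_kwargs else ExcitationProgram()
    records = []
    for lineno_offset, (meta, vals) in enumerate(rows):
        label = meta[0]
        if label not in LABEL_TO_CODE:
            raise SchemaError(
                f"{path}: record {lineno_offset}: unknown class label {label!r}"
            )
        currents = {
            ch: vals[i * npts : (i + 1) * npts] for i, ch in enumerate(channels)
        }
        records.append(
            SampleRecord(
                voltammogram=Voltammogram(currents=currents, excitation=exc),
                class_label=label,
                dilution=int(meta[2]),
                replicate=int(meta[3]),
                sample_id=int(meta[4]),
            )
        )
    return LabeledDataset(records=records)


def _parse_signal_columns(cols: list[str], path: Path) -> tuple[tuple[str, ...], int]:
    channels: list[str] = []
    counts: dict[str, int] = {}
    for col in cols:
        ch, _, idx = col.rpartition("_")
        if ch not in CHANNELS or not idx.isdigit():
            raise SchemaError(f"{path}: unrecognized signal column {col!r}")
        if ch not in counts:
            channels.append(ch)
            counts[ch] = 0
        counts[ch] += 1
    npts_set = set(counts.values())
    if len(npts_set) != 1:
        raise SchemaError(f"{path}: channels have unequal column counts {counts}")
    return tuple(channels), npts_set.pop()


def _write_hdf5(ds: LabeledDataset, path: Path) -> None:
    with h5py.File(path, "w") as f:
        if ds.records:
            for key, val in ds.records[0].voltammogram.excitation.to_dict().items():
                f.attrs[key] = val
        for i, rec in enumerate(ds.records):
            grp = f.create_group(f"rec{i:05d}")
            grp.attrs["class_label"] = rec.class_label
            grp.attrs["dilution"] = rec.dilution
            grp.attrs["replicate"] = rec.replicate
            grp.attrs["sample_id"] = rec.sample_id
            for ch in rec.voltammogram.channels:
                grp.create_dataset(ch, data=rec.voltammogram.currents[ch])


def _read_hdf5(path: Path) -> LabeledDataset:
    records = []
    with h5py.File(path, "r") as f:
        exc_kwargs = {k: float(v) for k, v in f.attrs.items()}
        exc = ExcitationProgram(**exc_kwargs) if exc_kwargs else ExcitationProgram()
        for name in sorted(f.keys()):
            grp = f[name]
            label = str(grp.attrs["class_label"])
            if label not in LABEL_TO_CODE:
                raise SchemaError(f"{path}: {name}: unknown class label {label!r}")
            currents = {ch: np.asarray(grp[ch]) for ch in grp.keys()}
            records.append(
                SampleRecord(
                    voltammogram=Voltammogram(currents=currents, excitation=exc),
                    class_label=label,
                    dilution=int(grp.attrs["dilution"]),
                    replicate=int(grp.attrs["replicate"]),
                    sample_id=int(grp.attrs["sample_id"]),
                )
            )
    return LabeledDataset(records=records)


def read_confusion_csv(path: str | Path) -> ConfusionMatrix:
    """Read a confusion matrix from a delimited file with labelled rows."""
    df = pd.read_csv(path, index_col=0)
    return ConfusionMatrix(
        counts=df.to_numpy(dtype=int), classes=tuple(df.columns)
    )


def write_confusion_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, index=list(cm.classes), columns=list(cm.classes))
    df.index.name = "expected"
    df.to_csv(path)


def load_fixture_confusion(name: str) -> ConfusionMatrix:
    """Load one of the packaged reference confusion matrices.

    ``name`` is one of ``dil0``, ``dil5``, ``dil10``, ``dil100`` — the
    leave-one-out prediction tables at 0x, 5x, 10x and 100x dilution.
    """
    if name not in _FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {_FIXTURE_NAMES}")
    ref = importlib.resources.files("etongue.fixtures") / f"confusion_{name}.csv"
    with importlib.resources.as_file(ref) as path:
        return read_confusion_csv(path)
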