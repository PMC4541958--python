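"""End-to-end experiment runner: simulate -> features -> DFA + RBF-LOOCV.

An experiment sweeps the configured dilution levels; per dilution it
generates (or accepts) a labelled dataset, extracts features in the chosen
mode (``fft``: 16 coefficient magnitudes per electrode, 64 inputs; or
``landmark``: 18 characteristic current values), fits the discriminant map
and Discrimination Index, runs leave-one-out cross-validation of the RBF
network, and scores the resulting confusion matrix.  Everything downstream
of the top-level seed is deterministic, so reruns produce byte-identical
summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import dfa as dfa_mod
from . import metrics as metrics_mod
from .data import CLASS_ORDER, LabeledDataset, dataset_matrix
from .fourier import extract_fft_features
from .io import write_confusion_csv
from .landmarks import LandmarkSpec, extract_landmark_features
from .rbf import RBFConfig, loocv
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger("etongue")

SCHEMA_VERSION = 1

#: Default hidden-layer sizes per feature mode (64-32-1 and 18-13-1).
DEFAULT_HIDDEN = {"fft": 32, "landmark": 13}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    feature_mode: str = "fft"
    fft_k: int = 16
    landmark_spec: LandmarkSpec = field(default_factory=LandmarkSpec)
    n_hidden: int | None = None  # None -> mode default (32 fft / 13 landmark)
    overlap_coefficient: float = 1.5
    scaling: str = "zscore"
    dilutions: tuple[int, ...] = (0, 5, 10, 100)
    seed: int = 1234
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.feature_mode not in ("fft", "landmark"):
            raise ValueError("feature_mode must be 'fft' or 'landmark'")
        # the top-level seed overrides the generator's own
        self.generator = replace(self.generator, seed=self.seed)

    def hidden_units(self, mode: str | None = None) -> int:
        if self.n_hidden is not None:
            return self.n_hidden
        return DEFAULT_HIDDEN[mode or self.feature_mode]


def feature_matrix(
    ds: LabeledDataset,
    mode: str,
    fft_k: int = 16,
    landmark_spec: LandmarkSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the per-record feature matrix and aligned class codes."""
    rows = []
    for rec in ds.records:
        if mode == "fft":
            fv = extract_fft_features(rec.voltammogram, k=fft_k)
        elif mode == "landmark":
            fv = extract_landmark_features(rec.voltammogram, landmark_spec)
        else:
            raise ValueError(f"unknown feature mode {mode!r}")
        rows.append(fv.values)
    return np.vstack(rows), ds.class_codes


def _topology(mode: str, n_features: int, n_hidden: int) -> str:
    return f"{n_features}-{n_hidden}-1"


def _analyze_dilution(
    ds: LabeledDataset,
    mode: str,
    config: ExperimentConfig,
    dilution: int,
) -> dict:
    X, codes = feature_matrix(ds, mode, config.fft_k, config.landmark_spec)
    model = dfa_mod.fit_dfa(X, codes)
    di = dfa_mod.discrimination_index(model, X, codes)
    n_hidden = config.hidden_units(mode)
    rbf_cfg = RBFConfig(
        n_hidden=n_hidden,
        overlap_coefficient=config.overlap_coefficient,
        seed=(config.seed + 97 * dilution) % (2**31),
        scaling=config.scaling,
    )
    cm, _ = loocv(X, codes, rbf_cfg)
    report = metrics_mod.score(cm)
    return {
        "dilution": dilution,
        "n_records": len(ds),
        "topology": _topology(mode, X.shape[1], n_hidden),
        "dfa": {
            "discrimination_index": di,
            "eigenvalues": [float(v) for v in model.eigenvalues],
            "contribution_pct": [
                float(100 * c) for c in model.contribution
            ],
            "accumulated_2axis_contribution_pct": float(
                100 * model.accumulated_contribution[min(1, model.contribution.size - 1)]
            ),
        },
        "confusion": cm.counts.tolist(),
        "metrics": {
            "accuracy": report.accuracy,
            "macro_specificity": report.macro_specificity,
            "macro_sensitivity": report.macro_sensitivity,
            "n_correct": report.n_correct,
        },
        "_cm": cm,
        "_dfa_model": model,
        "_scores_2d": model.scores_2d,
        "_codes": codes,
    }


def _strip_private(entry: dict) -> dict:
    return {k: v for k, v in entry.items() if not k.startswith("_")}


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the configured experiment; optionally write report artifacts.

    Returns the machine-readable summary (JSON-serializable).  When
    ``config.output_dir`` is set, writes ``summary.json``,
    ``confusion_<dil>.csv``, ``dfa_map_<dil>.png`` and ``log.txt`` there.
    """
    t0 = time.time()
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    log(
        f"experiment: mode={config.feature_mode} seed={config.seed} "
        f"dilutions={list(config.dilutions)}"
    )
    per_dilution = {}
    for dil in config.dilutions:
        t = time.time()
        ds = generate_dataset(config.generator, dil)
        entry = _analyze_dilution(ds, config.feature_mode, config, dil)
        log(
            f"dilution {dil}: n={len(ds)} topology={entry['topology']} "
            f"DI={entry['dfa']['discrimination_index']} "
            f"accuracy={entry['metrics']['accuracy']}% "
            f"({time.time() - t:.1f}s)"
        )
        if outdir:
            write_confusion_csv(entry["_cm"], outdir / f"confusion_{dil}.csv")
            _plot_dfa_map(
                entry["_scores_2d"],
                entry["_codes"],
                entry["_dfa_model"],
                outdir / f"dfa_map_{dil}.png",
                dil,
            )
        per_dilution[str(dil)] = _strip_private(entry)

    summary = {
        "schema_version": SCHEMA_VERSION,
        "feature_mode": config.feature_mode,
        "seed": config.seed,
        "dilutions": per_dilution,
        "accuracy_by_dilution": {
            str(d): per_dilution[str(d)]["metrics"]["accuracy"]
            for d in config.dilutions
        },
    }
    log(f"done in {time.time() - t0:.1f}s")
    if outdir:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return summary


def compare_feature_modes(config: ExperimentConfig) -> dict:
    """Run both feature modes on identical datasets, per dilution.

    Reports the per-dilution accuracy pair and which mode wins (``tie``
    when equal).
    """
    rows = {}
    for dil in config.dilutions:
        ds = generate_dataset(config.generator, dil)
        acc = {}
        for mode in ("fft", "landmark"):
            entry = _analyze_dilution(ds, mode, config, dil)
            acc[mode] = entry["metrics"]["accuracy"]
        winner = (
            "tie"
            if acc["fft"] == acc["landmark"]
            else max(acc, key=acc.get)
        )
        rows[str(dil)] = {
            "fft_accuracy": acc["fft"],
            "landmark_accuracy": acc["landmark"],
            "winner": winner,
        }
    return {"schema_version": SCHEMA_VERSION, "seed": config.seed, "modes": rows}


def _plot_dfa_map(
    scores: np.ndarray, codes: np.ndarray, model, path: Path, dilution: int
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    markers = {1: "^", 2: "v", 3: "*", 4: "o"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for i, code in enumerate(model.class_codes):
        pts = scores[codes == code]
        ax.scatter(
            pts[:, 0],
            pts[:, 1] if scores.shape[1] > 1 else np.zeros(len(pts)),
            marker=markers.get(int(code), "o"),
            label=CLASS_ORDER[int(code) - 1],
        )
        cen = model.class_centroids[i]
        ax.scatter(
            [cen[0]],
            [cen[1] if cen.size > 1 else 0.0],
            marker="+",
            c="k",
            s=120,
        )
    ax.set_xlabel("discriminant function 1")
    ax.set_ylabel("discriminant function 2")
    ax.set_title(f"DFA map, dilution {dilution}x")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
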