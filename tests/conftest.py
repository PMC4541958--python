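import numpy as np
import pytest

from etongue.data import ExcitationProgram, LabeledDataset, SampleRecord, Voltammogram
from etongue.dfa import discrimination_index, fit_dfa
from etongue.metrics import score
from etongue.pipeline import feature_matrix
from etongue.rbf import RBFConfig, loocv
from etongue.synthetic import GeneratorConfig, generate_dataset

SHIPPED_SEED = 1234


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def noise_free_cfg() -> GeneratorConfig:
    return GeneratorConfig(noise_sd=0.0, sample_offset_sd=0.0)


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """Two small handmade records (50 points per channel)."""
    rng = np.random.default_rng(7)
    exc = ExcitationProgram()
    records = []
    for i, label in enumerate(["JiaHe218", "XiuShui134"]):
        currents = {ch: rng.normal(size=50) for ch in ("Pt", "Ag", "Au", "Pd")}
        records.append(
            SampleRecord(
                voltammogram=Voltammogram(currents=currents, excitation=exc),
                class_label=label,
                dilution=0,
                replicate=i + 1,
                sample_id=i + 1,
            )
        )
    return LabeledDataset(records=records)


@pytest.fixture(scope="session")
def shipped_run():
    """Full shipped-seed pipeline over all dilutions and both feature modes.

    Computed once per session; returns per-(dilution, mode) accuracies and
    per-dilution FFT-mode Discrimination Indices.
    """
    cfg = GeneratorConfig(seed=SHIPPED_SEED)
    accuracy: dict[tuple[int, str], float] = {}
    di: dict[int, int] = {}
    for d in (0, 5, 10, 100):
        ds = generate_dataset(cfg, d)
        for mode, n_hidden in (("fft", 32), ("landmark", 13)):
            X, y = feature_matrix(ds, mode)
            if mode == "fft":
                model = fit_dfa(X, y)
                di[d] = discrimination_index(model, X, y)
            cm, _ = loocv(
                X,
                y,
                RBFConfig(n_hidden=n_hidden, seed=(SHIPPED_SEED + 97 * d) % 2**31),
            )
            accuracy[(d, mode)] = score(cm).accuracy
    return {"accuracy": accuracy, "di": di}
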