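import numpy as np
import pytest

from etongue.data import (
    CHANNELS,
    ConfusionMatrix,
    ExcitationProgram,
    LabeledDataset,
    SampleRecord,
    SchemaError,
    Voltammogram,
    dataset_matrix,
    matrix_to_dataset,
)
from etongue.io import load_fixture_confusion, read_dataset, write_dataset
from etongue.synthetic import GeneratorConfig, generate_dataset


class TestExcitationProgram:
    def test_defaults_match_reference_settings(self):
        p = ExcitationProgram()
        assert p.initial_potential == -2.0
        assert p.high_potential == 2.0
        assert p.cycle_samples == 4000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"initial_potential": -3.0},  # below low
            {"final_potential": 5.0},  # above high
            {"scan_rate": 0.0},
            {"sampling_rate": -1.0},
        ],
    )
    def test_invalid_programs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExcitationProgram(**kwargs)


class TestVoltammogram:
    def test_unequal_channel_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            Voltammogram(currents={"Pt": np.zeros(10), "Ag": np.zeros(9)})

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            Voltammogram(currents={"Cu": np.zeros(10)})

    def test_concatenation_follows_canonical_order(self):
        v = Voltammogram(
            currents={
                "Pd": np.full(3, 4.0),
                "Pt": np.full(3, 1.0),
                "Au": np.full(3, 3.0),
                "Ag": np.full(3, 2.0),
            }
        )
        assert v.channels == CHANNELS
        np.testing.assert_array_equal(
            v.concatenated(), np.repeat([1.0, 2.0, 3.0, 4.0], 3)
        )


class TestDatasetRoundTrip:
    @pytest.mark.parametrize("fmt", ["delimited", "hdf5"])
    def test_two_record_round_trip_is_lossless(self, tiny_dataset, tmp_path, fmt):
        path = tmp_path / f"ds.{fmt}"
        write_dataset(tiny_dataset, path, format=fmt)
        back = read_dataset(path, format=fmt)
        X0, y0 = dataset_matrix(tiny_dataset)
        X1, y1 = dataset_matrix(back)
        np.testing.assert_array_equal(X0, X1)
        np.testing.assert_array_equal(y0, y1)
        assert [r.class_label for r in back] == [r.class_label for r in tiny_dataset]
        assert back.records[0].voltammogram.excitation == ExcitationProgram()

    def test_full_design_round_trip(self, tmp_path):
        cfg = GeneratorConfig(seed=5)
        ds = generate_dataset(cfg, 0)
        path = tmp_path / "design.h5"
        write_dataset(ds, path, format="hdf5")
        back = read_dataset(path, format="hdf5")
        assert len(back) == 80
        assert all(r.voltammogram.n_points == 3986 for r in back)
        X0, _ = dataset_matrix(ds)
        X1, _ = dataset_matrix(back)
        np.testing.assert_array_equal(np.sort(X0, axis=0), np.sort(X1, axis=0))

    def test_ragged_row_raises_schema_error(self, tiny_dataset, tmp_path):
        path = tmp_path / "ds.csv"
        write_dataset(tiny_dataset, path)
        lines = path.read_text().splitlines()
        lines[-1] = ",".join(lines[-1].split(",")[:-5])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SchemaError, match="fields"):
            read_dataset(path)

    def test_unknown_label_raises_schema_error(self, tiny_dataset, tmp_path):
        path = tmp_path / "ds.csv"
        write_dataset(tiny_dataset, path)
        path.write_text(path.read_text().replace("XiuShui134", "Basmati"))
        with pytest.raises(SchemaError, match="Basmati"):
            read_dataset(path)

    def test_garbage_header_raises_schema_error(self, tmp_path):
        path = tmp_path / "junk.csv"
        path.write_text(",".join(f"meta{i}" for i in range(81)) + "\n")
        with pytest.raises(SchemaError, match="header"):
            read_dataset(path)


class TestDatasetMatrix:
    def test_full_design_shape(self):
        ds = generate_dataset(GeneratorConfig(seed=3), 0)
        X, y = dataset_matrix(ds)
        assert X.shape == (80, 4 * 3986)
        assert y.shape == (80,)
        assert sorted(np.unique(y)) == [1, 2, 3, 4]

    def test_empty_dataset(self):
        X, y = dataset_matrix(LabeledDataset(records=[]))
        assert X.shape == (0, 4 * 3986)
        assert y.size == 0

    def test_single_record_block_order(self, tiny_dataset):
        ds = LabeledDataset(records=tiny_dataset.records[:1])
        X, _ = dataset_matrix(ds)
        v = ds.records[0].voltammogram
        np.testing.assert_array_equal(X[0], v.concatenated())

    def test_heterogeneous_lengths_rejected(self, tiny_dataset):
        short = SampleRecord(
            voltammogram=Voltammogram(
                currents={ch: np.zeros(10) for ch in CHANNELS}
            ),
            class_label="JiaHe66",
            dilution=0,
            replicate=1,
            sample_id=3,
        )
        ds = LabeledDataset(records=tiny_dataset.records + [short])
        with pytest.raises(ValueError, match="heterogeneous"):
            dataset_matrix(ds)

    def test_matrix_round_trip_identity(self, tiny_dataset):
        X, y = dataset_matrix(tiny_dataset)
        back = matrix_to_dataset(X, y, n_points=50)
        X2, y2 = dataset_matrix(back)
        np.testing.assert_array_equal(X, X2)
        np.testing.assert_array_equal(y, y2)


class TestFixtureConfusions:
    @pytest.mark.parametrize("name", ["dil0", "dil5", "dil10", "dil100"])
    def test_balanced_design_totals(self, name):
        cm = load_fixture_confusion(name)
        assert cm.total == 80
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [20, 20, 20, 20])

    def test_dil0_matrix_exact(self):
        cm = load_fixture_confusion("dil0")
        np.testing.assert_array_equal(
            cm.counts,
            [[20, 0, 0, 0], [0, 18, 0, 2], [1, 0, 19, 0], [0, 1, 0, 19]],
        )

    def test_dil100_diagonal(self):
        cm = load_fixture_confusion("dil100")
        np.testing.assert_array_equal(np.diag(cm.counts), [3, 1, 1, 1])

    def test_dil10_crossclass_entry(self):
        cm = load_fixture_confusion("dil10")
        i = cm.classes.index("XiuShui134")
        j = cm.classes.index("JiaHe218")
        assert cm.counts[i, j] == 7

    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError):
            load_fixture_confusion("dil42")


class TestConfusionMatrix:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(counts=np.diag([1, 1, 1, -1]))

    def test_from_codes_accumulates_in_code_order(self):
        cm = ConfusionMatrix.from_codes([1, 2, 3, 4, 4], [1, 3, 3, 4, 1])
        assert cm.trace == 3
        assert cm.counts[3, 0] == 1  # expected 4, predicted 1
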