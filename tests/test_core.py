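"""Domain types, feature naming, table round-trips and manifest loading."""

import numpy as np
import pandas as pd
import pytest

from mieeg import (
    BandDefinition,
    EEGSegment,
    FeatureMatrix,
    RunConfig,
    SegmentSet,
    feature_names,
    load_segments,
    read_feature_table,
    write_feature_table,
)
from mieeg.core import (
    FormatError,
    LoadError,
    StructuralError,
    ValidationError,
    validate_bands,
)

CH22 = [f"ch{i:02d}" for i in range(22)]


class TestFeatureNames:
    @pytest.mark.parametrize(
        "channels, config_kwargs, expected",
        [
            (CH22, {}, 1364),                       # 22 x (24+15+15+8)
            (["Cz"], {}, 62),                        # 24+15+15+8
            (CH22, {"poincare_lags": (1,)}, 1276),   # 22 x (24+15+15+4)
        ],
    )
    def test_counts(self, channels, config_kwargs, expected):
        names = feature_names(channels, RunConfig(**config_kwargs))
        assert len(names) == expected
        assert len(set(names)) == expected

    def test_layout_is_channel_major_and_deterministic(self):
        names = feature_names(["A", "B"], RunConfig())
        assert names[:62] == [n for n in names[:62] if n.startswith("A__")]
        assert names[62].startswith("B__time__")
        assert names == feature_names(["A", "B"], RunConfig())

    def test_family_order(self):
        names = feature_names(["Cz"], RunConfig())
        fams = [n.split("__")[1] for n in names]
        seen = list(dict.fromkeys(fams))
        assert seen == ["time", "fft", "wpd", "poincare"]

    def test_duplicate_channels_rejected(self):
        with pytest.raises(ValidationError):
            feature_names(["Cz", "Cz"], RunConfig())


class TestSegmentTypes:
    def test_segment_invariants(self):
        with pytest.raises(ValidationError):
            EEGSegment(np.full((2, 10), np.nan), 250.0, ("a", "b"))
        with pytest.raises(ValidationError):
            EEGSegment(np.zeros((2, 10)), -1.0, ("a", "b"))
        with pytest.raises(ValidationError):
            EEGSegment(np.zeros((2, 10)), 250.0, ("a",))

    def test_segmentset_enforces_shared_layout(self):
        a = EEGSegment(np.zeros((2, 10)), 250.0, ("a", "b"), label="LH")
        bad_fs = EEGSegment(np.zeros((2, 10)), 100.0, ("a", "b"), label="RH")
        with pytest.raises(StructuralError):
            SegmentSet([a, bad_fs])

    def test_class_names_in_order_of_appearance(self):
        segs = [
            EEGSegment(np.zeros((1, 5)), 10.0, ("x",), label=lab)
            for lab in ("RH", "LH", "RH")
        ]
        assert SegmentSet(segs).class_names == ("RH", "LH")


class TestBands:
    def test_default_bands_partition(self):
        cfg = RunConfig()
        validate_bands(cfg.bands)
        edges = [(b.low_hz, b.high_hz) for b in cfg.bands]
        assert edges == [(0.5, 4), (4, 8), (8, 13), (13, 30), (30, 100)]

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError):
            validate_bands((BandDefinition("a", 1, 5), BandDefinition("b", 4, 8)))

    def test_inverted_edges_rejected(self):
        with pytest.raises(ValidationError):
            BandDefinition("bad", 10, 5)


class TestRunConfig:
    def test_json_round_trip(self, tmp_path):
        cfg = RunConfig(wavelet_level=6, poincare_lags=(2, 5), alpha=0.01, seed=9)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert RunConfig.from_json(path) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [{"wavelet_level": 0}, {"alpha": 0.0}, {"alpha": 1.0},
         {"cv_folds": 1}, {"cv_repeats": 0}, {"poincare_lags": (0,)}],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            RunConfig(**kwargs)


class TestFeatureTableRoundTrip:
    def test_round_trip_preserves_values(self, tmp_path, rng):
        names = tuple(f"f{i}" for i in range(20))
        fm = FeatureMatrix(rng.normal(size=(3, 20)) * 1e3, names,
                           ("LH", "RH", "LH"))
        path = tmp_path / "features.csv"
        write_feature_table(fm, path)
        back = read_feature_table(path)
        assert back.names == fm.names
        assert back.labels == fm.labels
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)

    def test_empty_matrix_round_trip(self, tmp_path):
        fm = FeatureMatrix(np.empty((0, 3)), ("a", "b", "c"), ())
        path = tmp_path / "empty.csv"
        write_feature_table(fm, path)
        back = read_feature_table(path)
        assert back.n_rows == 0
        assert back.names == ("a", "b", "c")

    def test_missing_label_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1.0], "not_label": ["x"]}).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_feature_table(path)


class TestLoadSegments:
    @staticmethod
    def _write(tmp_path, shapes, labels):
        records = []
        for i, (shape, lab) in enumerate(zip(shapes, labels)):
            fname = f"seg{i}.csv"
            np.savetxt(tmp_path / fname, np.random.default_rng(i).normal(size=shape),
                       delimiter=",")
            records.append({"file": fname, "label": lab, "subject": "S1", "fs": 250})
        manifest = tmp_path / "manifest.csv"
        pd.DataFrame(records).to_csv(manifest, index=False)
        return manifest

    def test_loads_matrix_manifest(self, tmp_path):
        manifest = self._write(tmp_path, [(4, 100)] * 3, ["LH", "RH", "LH"])
        segset = load_segments(manifest, format="matrix")
        assert len(segset) == 3
        assert segset.class_names == ("LH", "RH")
        assert segset[0].data.shape == (4, 100)

    def test_missing_file_is_load_error(self, tmp_path):
        manifest = self._write(tmp_path, [(4, 100)], ["LH"])
        (tmp_path / "seg0.csv").unlink()
        with pytest.raises(LoadError, match="seg0"):
            load_segments(manifest)

    def test_inconsistent_channel_count_is_structural_error(self, tmp_path):
        manifest = self._write(tmp_path, [(4, 100), (3, 100)], ["LH", "RH"])
        with pytest.raises(StructuralError):
            load_segments(manifest)

    def test_non_finite_samples_rejected(self, tmp_path):
        data = np.zeros((2, 50))
        data[0, 0] = np.inf
        np.savetxt(tmp_path / "seg.csv", data, delimiter=",")
        pd.DataFrame(
            [{"file": "seg.csv", "label": "LH", "subject": "S1", "fs": 250}]
        ).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ValidationError):
            load_segments(tmp_path / "m.csv")
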