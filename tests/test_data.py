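"""Label-table readers, uncertain-label policies, split handling, and
image preprocessing."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from mbranet.data import (CHESTXRAY14_CLASSES, LabelPolicy, SampleRecord,
                          preprocess, read_chestxray14_csv, read_chexpert_csv,
                          split_records)


class TestChestXray14Reader:
    def _write(self, tmp_path, rows):
        df = pd.DataFrame(rows)
        path = tmp_path / "labels.csv"
        df.to_csv(path, index=False)
        return path

    def test_pipe_separated_findings(self, tmp_path):
        path = self._write(tmp_path, [
            {"Image Index": "a.png", "Finding Labels": "Atelectasis|Effusion",
             "Patient ID": "1"},
            {"Image Index": "b.png", "Finding Labels": "No Finding",
             "Patient ID": "2"},
        ])
        recs = read_chestxray14_csv(path)
        expected = np.zeros(14); expected[[0, 2]] = 1
        np.testing.assert_array_equal(recs[0].labels, expected)
        np.testing.assert_array_equal(recs[1].labels, 0.0)
        assert recs[0].patient_id == "1"

    def test_unknown_label_is_reported_by_name(self, tmp_path):
        path = self._write(tmp_path, [
            {"Image Index": "a.png", "Finding Labels": "Dragonpox", "Patient ID": "1"}])
        with pytest.raises(ValueError, match="Dragonpox"):
            read_chestxray14_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = self._write(tmp_path, [{"Image Index": "a.png"}])
        with pytest.raises(ValueError, match="Finding Labels"):
            read_chestxray14_csv(path)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert read_chestxray14_csv(path) == []


class TestCheXpertReader:
    CLASSES = ("Cardiomegaly", "Edema", "Consolidation")

    def _fixture(self, tmp_path):
        rows = [
            {"Path": "patient001/s1/view1.jpg", "Cardiomegaly": 1,
             "Edema": -1, "Consolidation": 0},
            {"Path": "patient002/s1/view1.jpg", "Cardiomegaly": -1,
             "Edema": 0, "Consolidation": None},
            {"Path": "patient003/s1/view1.jpg", "Cardiomegaly": None,
             "Edema": None, "Consolidation": None},
            {"Path": "patient004/s1/view1.jpg", "Cardiomegaly": 0,
             "Edema": -1, "Consolidation": 1},
            {"Path": "patient005/s1/view1.jpg", "Cardiomegaly": 1,
             "Edema": 1, "Consolidation": 0},
            {"Path": "patient006/s1/view1.jpg", "Cardiomegaly": 0,
             "Edema": 0, "Consolidation": -1},
        ]
        path = tmp_path / "chexpert.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    def test_uones_and_uzeros_differ_only_at_uncertain_cells(self, tmp_path):
        path = self._fixture(tmp_path)
        ones, n1 = read_chexpert_csv(path, self.CLASSES, LabelPolicy("u_ones"),
                                     return_remap_count=True)
        zeros, n0 = read_chexpert_csv(path, self.CLASSES, LabelPolicy("u_zeros"),
                                      return_remap_count=True)
        assert n1 == n0 == 4
        lo = np.stack([r.labels for r in ones])
        lz = np.stack([r.labels for r in zeros])
        diff = lo != lz
        assert diff.sum() == 4
        assert np.all(lo[diff] == 1.0) and np.all(lz[diff] == 0.0)

    def test_blank_row_maps_to_zero_vector(self, tmp_path):
        recs = read_chexpert_csv(self._fixture(tmp_path), self.CLASSES)
        np.testing.assert_array_equal(recs[2].labels, 0.0)

    def test_patient_id_parsed_from_path(self, tmp_path):
        recs = read_chexpert_csv(self._fixture(tmp_path), self.CLASSES)
        assert recs[0].patient_id == "patient001"

    def test_invalid_value_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame([{"Path": "p/x.jpg", "Cardiomegaly": 3,
                       "Edema": 0, "Consolidation": 0}]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="invalid label value"):
            read_chexpert_csv(path, self.CLASSES)

    def test_invalid_policy_mode(self):
        with pytest.raises(ValueError):
            LabelPolicy("u_halves")


def _records(n_patients, images_per_patient):
    recs = []
    for p in range(n_patients):
        for i in range(images_per_patient):
            recs.append(SampleRecord(f"img_{p}_{i}.png", "none",
                                     np.zeros(14), patient_id=str(p)))
    return recs


class TestSplits:
    def test_patient_grouped_counts(self):
        recs = _records(10, 2)
        tr, va, te = split_records(recs, "patient_grouped_ratio",
                                  (0.7, 0.1, 0.2), seed=0)
        assert (len(tr), len(va), len(te)) == (14, 2, 4)

    def test_no_patient_straddles_splits(self):
        recs = _records(23, 3)
        parts = split_records(recs, seed=5)
        patients = [set(r.patient_id for r in part) for part in parts]
        assert not (patients[0] & patients[1])
        assert not (patients[0] & patients[2])
        assert not (patients[1] & patients[2])

    def test_official_lists_partition(self):
        recs = _records(6, 1)
        ids = [r.image_id for r in recs]
        parts = split_records(recs, "official_lists",
                              official_lists=(ids[:3], ids[3:4], ids[4:]))
        assert [len(p) for p in parts] == [3, 1, 2]

    def test_overlapping_official_lists_rejected(self):
        recs = _records(4, 1)
        ids = [r.image_id for r in recs]
        with pytest.raises(ValueError, match="two official lists"):
            split_records(recs, "official_lists",
                          official_lists=(ids[:2], ids[1:3], ids[3:]))

    def test_unknown_id_rejected(self):
        recs = _records(2, 1)
        with pytest.raises(ValueError, match="unknown ids"):
            split_records(recs, "official_lists",
                          official_lists=([recs[0].image_id], ["ghost.png"], []))


class TestPreprocess:
    def _png(self, tmp_path, size=96, mode="L"):
        arr = (np.linspace(0, 255, size * size).reshape(size, size)).astype(np.uint8)
        img = Image.fromarray(arr, mode="L").convert(mode)
        path = tmp_path / "img.png"
        img.save(path)
        return path

    def test_output_shape_and_dtype(self, tmp_path):
        out = preprocess(self._png(tmp_path), "eval_deterministic")
        assert out.shape == (3, 224, 224) and out.dtype == np.float32

    def test_grayscale_replicated_before_normalisation(self, tmp_path):
        out = preprocess(self._png(tmp_path), "eval_deterministic")
        # identical raw channels produce channel-wise affine copies
        raw = out * np.array([0.229, 0.224, 0.225])[:, None, None] \
            + np.array([0.485, 0.456, 0.406])[:, None, None]
        np.testing.assert_allclose(raw[0], raw[1], atol=1e-6)

    def test_train_crops_reproducible_under_fixed_seed(self, tmp_path):
        path = self._png(tmp_path)
        a = preprocess(path, "train", rng=np.random.default_rng(5))
        b = preprocess(path, "train", rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)
        c = preprocess(path, "train", rng=np.random.default_rng(6))
        assert not np.array_equal(a, c)

    def test_eval_paper_uses_random_crop(self, tmp_path):
        path = self._png(tmp_path)
        crops = {preprocess(path, "eval_paper",
                            rng=np.random.default_rng(s)).tobytes()
                 for s in range(5)}
        assert len(crops) > 1

    def test_unknown_phase_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="phase"):
            preprocess(self._png(tmp_path), "test_time_augment")

    def test_undecodable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.png"
        bad.write_bytes(b"not a png")
        with pytest.raises(Exception):
            preprocess(bad, "eval_deterministic")
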