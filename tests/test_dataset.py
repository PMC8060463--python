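"""Segment tiling, balancing, normalization, padding, fold assignment."""

import numpy as np
import pytest

from sdcae import (
    Recording,
    Segment,
    assign_stratified_folds,
    balance_dataset,
    build_dataset,
    extract_segments,
    normalize_dataset,
    pad_channel_dim,
)
from sdcae.dataset import (
    ICTAL,
    INTERICTAL,
    DegenerateDataError,
    ImbalanceError,
    StratificationError,
    load_dataset,
    save_dataset,
)
from sdcae.types import AnnotationSet, SeizureInterval, ValidationError


def flat_recording(duration_s, n_channels=23, sr=256, seed=0):
    rng = np.random.default_rng(seed)
    sig = rng.normal(size=(int(duration_s * sr), n_channels))
    return Recording("t", sig, float(sr), [f"C{i}" for i in range(n_channels)])


class TestExtractSegments:
    def test_ictal_tiling_anchored_at_onset(self):
        rec = flat_recording(60)
        ann = AnnotationSet("t", [SeizureInterval(10, 30)])
        segs = [s for s in extract_segments(rec, ann, 4) if s.label == ICTAL]
        assert [s.start_s for s in segs] == [10, 14, 18, 22, 26]

    def test_minimum_length_seizure(self):
        rec = flat_recording(60)
        ann = AnnotationSet("t", [SeizureInterval(20, 30)])
        segs = [s for s in extract_segments(rec, ann, 4) if s.label == ICTAL]
        assert len(segs) == 2

    def test_exhaustive_tiling_counts(self):
        rec = flat_recording(3600, n_channels=2)
        ann = AnnotationSet("t", [SeizureInterval(1000, 1060)])
        segs = extract_segments(rec, ann, 1, buffer_s=0.0)
        n_ictal = sum(s.label == ICTAL for s in segs)
        n_inter = sum(s.label == INTERICTAL for s in segs)
        assert (n_ictal, n_inter) == (60, 3540)

    def test_segment_length_is_rate_times_duration(self):
        rec = flat_recording(20)
        for d, L in ((1, 256), (2, 512), (4, 1024)):
            segs = extract_segments(rec, AnnotationSet("t", []), d)
            assert all(s.data.shape == (L, 23) for s in segs)

    def test_short_recording_gives_empty(self):
        rec = flat_recording(2)
        assert extract_segments(rec, AnnotationSet("t", []), 4) == []

    def test_invalid_duration(self):
        with pytest.raises(ValidationError):
            extract_segments(flat_recording(10), AnnotationSet("t", []), 3)

    def test_buffer_excludes_neighbouring_windows(self):
        rec = flat_recording(100)
        ann = AnnotationSet("t", [SeizureInterval(40, 60)])
        no_buf = [s for s in extract_segments(rec, ann, 2, 0.0) if s.label == INTERICTAL]
        buf = [s for s in extract_segments(rec, ann, 2, 10.0) if s.label == INTERICTAL]
        assert len(buf) == len(no_buf) - 10
        assert all(s.start_s + 2 <= 30 or s.start_s >= 70 for s in buf)

    def test_no_interictal_window_touches_a_seizure(self, toy_cohort):
        for rec, intervals in toy_cohort:
            ann = AnnotationSet(rec.subject_id, list(intervals))
            for seg in extract_segments(rec, ann, 2):
                if seg.label == INTERICTAL:
                    t0, t1 = seg.start_s, seg.start_s + 2
                    assert not any(t0 < iv.end_s and iv.start_s < t1 for iv in intervals)


def _seg(value, label, n=8):
    return Segment(np.full((n, 23), float(value)), label, "s", 0.0)


class TestBalance:
    def test_downsamples_to_equal_counts(self, rng):
        ictal = [_seg(i, ICTAL) for i in range(100)]
        inter = [_seg(i, INTERICTAL) for i in range(3540)]
        out = balance_dataset(ictal, inter, seed=0)
        labels = [s.label for s in out]
        assert len(out) == 200
        assert labels.count(ICTAL) == labels.count(INTERICTAL) == 100

    def test_equal_counts_identity(self):
        ictal = [_seg(i, ICTAL) for i in range(5)]
        inter = [_seg(i, INTERICTAL) for i in range(5)]
        out = balance_dataset(ictal, inter, seed=1)
        assert {id(s) for s in out} == {id(s) for s in ictal + inter}

    def test_seed_determinism(self):
        ictal = [_seg(i, ICTAL) for i in range(10)]
        inter = [_seg(i, INTERICTAL) for i in range(50)]
        a = balance_dataset(ictal, inter, seed=3)
        b = balance_dataset(ictal, inter, seed=3)
        assert [id(s) for s in a] == [id(s) for s in b]

    def test_imbalance_error(self):
        with pytest.raises(ImbalanceError):
            balance_dataset([_seg(0, ICTAL)] * 3, [_seg(0, INTERICTAL)] * 2, 0)


class TestNormalize:
    def test_two_point_distribution(self):
        segs = [_seg(0, INTERICTAL), _seg(10, ICTAL)]
        ds, params = normalize_dataset(segs)
        assert params.mu == 5.0 and params.sigma == 5.0
        assert (params.min_z, params.max_z) == (-1.0, 1.0)
        np.testing.assert_array_equal(np.unique(ds.X), [0.0, 1.0])

    def test_constant_dataset_rejected(self):
        with pytest.raises(DegenerateDataError):
            normalize_dataset([_seg(2, ICTAL), _seg(2, INTERICTAL)])

    def test_pooled_moments_and_range(self, rng):
        segs = [Segment(rng.normal(3, 7, (16, 23)), i % 2, "s", 0.0) for i in range(50)]
        ds, params = normalize_dataset(segs)
        z = (np.stack([s.data for s in segs]) - params.mu) / params.sigma
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9
        assert ds.X.min() == 0.0 and ds.X.max() == 1.0


class TestPadding:
    def _ds(self, rng):
        segs = [Segment(rng.normal(size=(16, 23)), i % 2, "s", 0.0) for i in range(4)]
        return normalize_dataset(segs)[0]

    def test_zero_policy(self, rng):
        ds = pad_channel_dim(self._ds(rng))
        assert ds.X.shape[2] == 24
        assert np.all(ds.X[:, :, 23, :] == 0)

    def test_replicate_policy(self, rng):
        base = self._ds(rng)
        ds = pad_channel_dim(base, "replicate-last")
        np.testing.assert_array_equal(ds.X[:, :, 23, :], ds.X[:, :, 22, :])

    def test_original_columns_unchanged(self, rng):
        base = self._ds(rng)
        ds = pad_channel_dim(base)
        np.testing.assert_array_equal(ds.X[:, :, :23, :], base.X)

    def test_wrong_width_rejected(self, rng):
        ds = self._ds(rng)
        with pytest.raises(ValidationError):
            pad_channel_dim(pad_channel_dim(ds))


class TestStratifiedFolds:
    def test_exact_division(self):
        y = np.array([0] * 200 + [1] * 200)
        folds = assign_stratified_folds(y, k=10, seed=0)
        for f in range(10):
            assert np.sum((folds == f) & (y == 0)) == 20
            assert np.sum((folds == f) & (y == 1)) == 20

    def test_partition(self, rng):
        y = (rng.random(137) < 0.5).astype(int)
        y[:10] = 0
        y[10:20] = 1
        folds = assign_stratified_folds(y, k=10, seed=1)
        assert folds.min() >= 0 and folds.max() == 9
        assert len(folds) == len(y)

    def test_uneven_counts(self):
        y = np.array([0] * 101 + [1] * 101)
        folds = assign_stratified_folds(y, k=10, seed=2)
        for f in range(10):
            for c in (0, 1):
                assert np.sum((folds == f) & (y == c)) in (10, 11)

    def test_too_few_members(self):
        with pytest.raises(StratificationError):
            assign_stratified_folds(np.array([0] * 5 + [1] * 50), k=10)
        with pytest.raises(StratificationError):
            assign_stratified_folds(np.zeros(30, dtype=int), k=10)


class TestEndToEnd:
    def test_dataset_invariants(self, toy_dataset):
        ds = toy_dataset
        n = len(ds)
        assert ds.X.shape == (n, 256, 24, 1)
        assert np.sum(ds.y == 1) == np.sum(ds.y == 0)
        assert ds.X.min() >= 0.0 and ds.X.max() <= 1.0
        per_class = np.sum(ds.y == 1)
        for f in range(10):
            for c in (0, 1):
                cnt = np.sum((ds.fold_of == f) & (ds.y == c))
                assert per_class // 10 <= cnt <= per_class // 10 + 1

    def test_builder_determinism(self, toy_cohort):
        a = build_dataset(toy_cohort, duration_s=2, seed=9)
        b = build_dataset(toy_cohort, duration_s=2, seed=9)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)

    def test_save_load_round_trip(self, toy_dataset, tmp_path):
        path = tmp_path / "ds.npz"
        save_dataset(toy_dataset, path)
        back = load_dataset(path)
        np.testing.assert_array_equal(back.X, toy_dataset.X)
        np.testing.assert_array_equal(back.y, toy_dataset.y)
        np.testing.assert_array_equal(back.fold_of, toy_dataset.fold_of)
        assert back.norm == toy_dataset.norm
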