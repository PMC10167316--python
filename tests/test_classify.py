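"""Windowing, splits, training protocols and the leakage demonstration."""

import numpy as np
import pytest

from eegvuln.classify import (
    ModelSpec,
    SplitSpec,
    WindowedDataset,
    benchmark,
    concat_windows,
    make_kfold,
    make_splits,
    train_eval,
    window_sequences,
)

from conftest import make_epochs, make_recording

ALL_FAMILIES = ["dt", "mlp", "cnn1d", "lstm", "blstm"]


def small_model(family):
    return ModelSpec(family=family, max_depth=5, hidden=(8,), conv_filters=(4, 8),
                     lstm_hidden=6, dense_head=(8,), max_epochs=30, patience=5, lr=0.01)


def gaussian_windows(rng, n_per_class=150, n_ch=3, window=32, shift=2.0, n_subjects=10):
    """Two-class windows with a per-feature class mean shift; subjects split evenly."""
    x = rng.standard_normal((2 * n_per_class, n_ch, window))
    y = np.array([1] * n_per_class + [0] * n_per_class)
    x[y == 1] += shift
    sids = np.array([f"S{(i % n_subjects) + (10 * y[i])}" for i in range(len(y))], dtype=object)
    return WindowedDataset(x, y, sids)


class TestWindowing:
    def test_tiling_window_count(self):
        ep = make_epochs(np.zeros((4, 2, 320)), group="high")
        ds = window_sequences(ep, window=32, stride=32)
        assert ds.n_windows == 4 * 10
        assert ds.x.shape == (40, 2, 32)
        assert np.all(ds.y == 1)

    def test_window_count_formula_per_trial(self, rng):
        L, w, s = 500, 64, 17
        ep = make_epochs(rng.standard_normal((3, 2, L)), group="low")
        ds = window_sequences(ep, window=w, stride=s)
        per_trial = (L - w) // s + 1
        assert ds.n_windows == 3 * per_trial

    def test_windows_never_cross_trial_boundaries(self):
        data = np.zeros((2, 1, 100))
        data[0] = 1.0  # trial 0 all ones, trial 1 all zeros
        ep = make_epochs(data, group="high")
        ds = window_sequences(ep, window=50, stride=25)
        for w in ds.x:
            assert w.min() == w.max()  # each window from a single trial

    def test_recording_source_and_too_long_window(self):
        rec = make_recording(np.zeros((2, 100)), group="low")
        ds = window_sequences(rec, window=50)
        assert ds.n_windows == 2
        with pytest.raises(ValueError):
            window_sequences(rec, window=101)


class TestSplits:
    def test_sample_level_60_20_20_sizes(self, rng):
        ds = gaussian_windows(rng, n_per_class=50)
        tr, va, te = make_splits(ds, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (60, 20, 20)
        all_idx = np.sort(np.concatenate([tr, va, te]))
        assert np.array_equal(all_idx, np.arange(100))

    def test_sample_level_splits_are_stratified(self, rng):
        ds = gaussian_windows(rng, n_per_class=50)
        tr, va, te = make_splits(ds, SplitSpec(seed=3))
        for part in (tr, va, te):
            assert np.mean(ds.y[part]) == pytest.approx(0.5, abs=0.01)

    def test_subject_level_keeps_subjects_whole(self, rng):
        ds = gaussian_windows(rng, n_per_class=150, n_subjects=10)
        tr, va, te = make_splits(ds, SplitSpec(mode="subject_level", seed=1))
        parts = [set(ds.subject_ids[p]) for p in (tr, va, te)]
        assert not (parts[0] & parts[1]) and not (parts[0] & parts[2]) and not (parts[1] & parts[2])
        assert len(tr) + len(va) + len(te) == ds.n_windows

    def test_subject_level_needs_three_subjects_per_class(self, rng):
        ds = gaussian_windows(rng, n_per_class=20, n_subjects=2)
        with pytest.raises(ValueError):
            make_splits(ds, SplitSpec(mode="subject_level"))

    def test_kfold_partitions_disjoint_and_exhaustive(self, rng):
        ds = gaussian_windows(rng, n_per_class=50)
        folds = make_kfold(ds, SplitSpec(k=5, seed=0))
        assert len(folds) == 5
        tests = [set(te) for _, te in folds]
        assert sum(len(t) for t in tests) == 100
        assert set().union(*tests) == set(range(100))
        for t in tests:
            assert len(t) == 20

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(mode="leaky")
        with pytest.raises(ValueError):
            SplitSpec(ratios=(0.5, 0.3, 0.3))
        with pytest.raises(ValueError):
            SplitSpec(k=1)


class TestTrainEval:
    def test_separable_gaussians_dt_accuracy_high(self, rng):
        ds = gaussian_windows(rng, shift=4.0)
        splits = make_splits(ds, SplitSpec(seed=0))
        rep = train_eval(ds, ModelSpec(family="dt", max_depth=3), splits, seed=0)
        assert rep.accuracy >= 0.95

    def test_confusion_matrix_contract(self, rng):
        ds = gaussian_windows(rng)
        splits = make_splits(ds, SplitSpec(seed=2))
        rep = train_eval(ds, small_model("dt"), splits, seed=2)
        te = splits[2]
        assert rep.confusion.sum() == rep.n_test == len(te)
        assert rep.confusion[0].sum() == (ds.y[te] == 0).sum()
        assert rep.confusion[1].sum() == (ds.y[te] == 1).sum()
        acc = np.trace(rep.confusion) / rep.confusion.sum()
        assert rep.accuracy == pytest.approx(acc)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_each_family_learns_separable_data(self, rng, family):
        ds = gaussian_windows(rng, n_per_class=100, shift=4.0)
        splits = make_splits(ds, SplitSpec(seed=1))
        rep = train_eval(ds, small_model(family), splits, seed=1)
        assert rep.accuracy >= 0.9, f"{family} failed on separable data: {rep.accuracy}"

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_permuted_labels_give_chance_accuracy(self, family):
        rng = np.random.default_rng(99)
        ds = gaussian_windows(rng, n_per_class=100, shift=4.0)
        perm = rng.permutation(len(ds.y))
        ds = WindowedDataset(ds.x, ds.y[perm], ds.subject_ids, ds.band, ds.kind)
        splits = make_splits(ds, SplitSpec(seed=5))
        rep = train_eval(ds, small_model(family), splits, seed=5)
        # binomial 99% interval around the majority-class rate on test
        y_te = ds.y[splits[2]]
        p0 = max(np.mean(y_te), 1 - np.mean(y_te))
        half = 2.58 * np.sqrt(p0 * (1 - p0) / len(y_te))
        assert rep.accuracy <= p0 + half + 0.05, f"{family} above chance on permuted labels"

    def test_non_finite_input_rejected(self, rng):
        ds = gaussian_windows(rng, n_per_class=20)
        ds.x[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            train_eval(ds, small_model("dt"), make_splits(ds, SplitSpec(seed=0)), 0)


class TestLeakage:
    def _subject_signature_dataset(self, seed, n_subjects=40, windows_per_subject=30):
        """Subject-specific offsets, labels assigned to subjects with NO group effect."""
        rng = np.random.default_rng(seed)
        xs, ys, sids = [], [], []
        for s in range(n_subjects):
            label = s % 2  # arbitrary: no signal links the offset to the label
            offset = rng.standard_normal((2, 1)) * 3.0  # the subject's signature
            x = rng.standard_normal((windows_per_subject, 2, 16)) + offset[None, :, :]
            xs.append(x)
            ys.append(np.full(windows_per_subject, label))
            sids.extend([f"S{s:02d}"] * windows_per_subject)
        return WindowedDataset(np.concatenate(xs), np.concatenate(ys),
                               np.array(sids, dtype=object))

    def test_sample_level_split_inflates_accuracy_subject_level_does_not(self):
        accs_sample, accs_subject = [], []
        for seed in range(5):
            ds = self._subject_signature_dataset(seed)
            model = ModelSpec(family="dt", max_depth=12)
            rep_s = train_eval(ds, model, make_splits(ds, SplitSpec(seed=seed)), seed)
            rep_g = train_eval(
                ds, model,
                make_splits(ds, SplitSpec(mode="subject_level", seed=seed)), seed,
                split_mode="subject_level",
            )
            accs_sample.append(rep_s.accuracy)
            accs_subject.append(rep_g.accuracy)
        # windows of known subjects leak the subject->label mapping
        assert np.mean(accs_sample) >= 0.65
        # held-out subjects carry no label information at all
        assert np.mean(accs_subject) <= 0.60


class TestBenchmark:
    def test_empty_model_list_gives_empty_table(self, rng):
        ds = gaussian_windows(rng, n_per_class=30)
        table = benchmark([ds], [], SplitSpec(seed=0))
        assert len(table) == 0

    def test_benchmark_rerun_identical(self, rng):
        ds = gaussian_windows(rng, n_per_class=40)
        models = [small_model("dt"), small_model("mlp")]
        t1 = benchmark([ds], models, SplitSpec(seed=4))
        t2 = benchmark([ds], models, SplitSpec(seed=4))
        assert t1.equals(t2)

    def test_band_specific_effect_favors_that_band(self):
        # effect planted only in the delta dataset; raw-gamma dataset is null
        rng = np.random.default_rng(11)
        ds_delta = gaussian_windows(rng, n_per_class=100, shift=2.0)
        ds_delta.band = "delta"
        null = gaussian_windows(rng, n_per_class=100, shift=0.0)
        ds_gamma = WindowedDataset(null.x, null.y, null.subject_ids, band="gamma")
        accs = {"delta": [], "gamma": []}
        for seed in range(5):
            for ds in (ds_delta, ds_gamma):
                rep = train_eval(ds, ModelSpec(family="dt", max_depth=4),
                                 make_splits(ds, SplitSpec(seed=seed)), seed)
                accs[ds.band].append(rep.accuracy)
        assert np.median(accs["delta"]) >= np.median(accs["gamma"])

    def test_concat_windows_preserves_provenance(self, rng):
        a = gaussian_windows(rng, n_per_class=10)
        b = gaussian_windows(rng, n_per_class=15)
        ds = concat_windows([a, b])
        assert ds.n_windows == a.n_windows + b.n_windows
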