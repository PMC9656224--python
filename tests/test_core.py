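import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emograph.core import (
    EMOTIV_14,
    EEG_32,
    PERIPHERAL_8,
    Recording,
    Trial,
    dichotomize,
    ratings_frame,
    read_array_recording,
    read_recording,
    select_channels,
    slide_windows,
    write_recording,
    write_ratings_csv,
)


def make_trial(n_eeg=4, n_per=2, n_samples=512, valence=3.0, arousal=7.0, seed=0):
    rng = np.random.default_rng(seed)
    return Trial(
        trial_id="t0",
        eeg=rng.standard_normal((n_eeg, n_samples)),
        eeg_channels=tuple(f"E{i}" for i in range(n_eeg)),
        peripheral=rng.standard_normal((n_per, n_samples)),
        peripheral_channels=tuple(f"P{i}" for i in range(n_per)),
        valence=valence,
        arousal=arousal,
    )


class TestDichotomize:
    @pytest.mark.parametrize(
        "rating,expected",
        [(4.5, "low"), (4.6, "high"), (1.0, "low"), (9.0, "high"), (4.4999, "low")],
    )
    def test_threshold(self, rating, expected):
        assert dichotomize(rating) == expected

    @pytest.mark.parametrize("rating", [0.5, 9.5, -1.0, 100.0])
    def test_out_of_range(self, rating):
        with pytest.raises(ValueError):
            dichotomize(rating)

    @given(st.floats(1.0, 9.0), st.floats(1.0, 9.0))
    def test_monotone(self, r1, r2):
        order = {"low": 0, "high": 1}
        if r1 <= r2:
            assert order[dichotomize(r1)] <= order[dichotomize(r2)]


class TestSlideWindows:
    def test_counts_60s(self):
        trial = make_trial(n_samples=60 * 128)
        windows = slide_windows(trial, 128, 4, 2)
        assert len(windows) == 29  # floor((60-4)/2)+1

    def test_window_equals_trial(self):
        trial = make_trial(n_samples=4 * 128)
        windows = slide_windows(trial, 128, 4, 2)
        assert len(windows) == 1
        assert windows[0].start_s == 0.0

    def test_too_short_raises(self):
        trial = make_trial(n_samples=3 * 128)
        with pytest.raises(ValueError, match="window"):
            slide_windows(trial, 128, 4, 2)

    def test_labels_inherited(self):
        trial = make_trial(n_samples=6 * 128, valence=2.5, arousal=8.5)
        for w in slide_windows(trial, 128, 4, 2, subject_id="sX"):
            assert (w.valence, w.arousal) == (2.5, 8.5)
            assert w.source == ("sX", "t0")

    def test_segments_are_contiguous_slices(self):
        trial = make_trial(n_samples=8 * 128)
        for w in slide_windows(trial, 128, 4, 2):
            start = int(w.start_s * 128)
            np.testing.assert_array_equal(
                w.eeg, trial.eeg[:, start : start + 512]
            )

    @given(
        t_s=st.integers(4, 240),
        window_s=st.integers(1, 20),
        step_s=st.integers(1, 20),
    )
    @settings(max_examples=40, deadline=None)
    def test_count_formula(self, t_s, window_s, step_s):
        if t_s < window_s:
            return
        rate = 8
        trial = make_trial(n_eeg=2, n_per=1, n_samples=t_s * rate)
        windows = slide_windows(trial, rate, window_s, step_s)
        # independent enumeration of valid left-aligned offsets
        expected = len(
            [s for s in range(0, t_s * rate, step_s * rate)
             if s + window_s * rate <= t_s * rate]
        )
        assert len(windows) == expected == (t_s - window_s) // step_s + 1

    def test_step_equals_window_partitions_prefix(self):
        rate = 16
        trial = make_trial(n_samples=10 * rate)
        windows = slide_windows(trial, rate, 3, 3)
        covered = np.concatenate([w.eeg[0] for w in windows])
        np.testing.assert_array_equal(covered, trial.eeg[0, : len(covered)])
        assert len(covered) == (10 // 3) * 3 * rate


class TestSelectChannels:
    def _trial32(self):
        rng = np.random.default_rng(0)
        return Trial(
            trial_id="t",
            eeg=rng.standard_normal((32, 64)),
            eeg_channels=EEG_32,
            peripheral=rng.standard_normal((8, 64)),
            peripheral_channels=PERIPHERAL_8,
            valence=5.0,
            arousal=5.0,
        )

    def test_emotiv_default(self):
        out = select_channels(self._trial32())
        assert out.eeg_channels == EMOTIV_14
        assert out.eeg.shape == (14, 64)

    def test_order_follows_wanted(self):
        trial = self._trial32()
        out = select_channels(trial, ["O2", "AF3"])
        assert out.eeg_channels == ("O2", "AF3")
        np.testing.assert_array_equal(out.eeg[0], trial.eeg[EEG_32.index("O2")])

    def test_identity(self):
        trial = self._trial32()
        out = select_channels(trial, list(trial.eeg_channels))
        np.testing.assert_array_equal(out.eeg, trial.eeg)

    def test_unknown_label_named(self):
        with pytest.raises(KeyError, match="XX"):
            select_channels(self._trial32(), ["AF3", "XX"])


class TestInvariants:
    def test_rating_bounds_enforced(self):
        with pytest.raises(ValueError, match="valence"):
            make_trial(valence=0.5)

    def test_sample_mismatch(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="samples"):
            Trial(
                trial_id="t",
                eeg=rng.standard_normal((2, 100)),
                eeg_channels=("a", "b"),
                peripheral=rng.standard_normal((1, 99)),
                peripheral_channels=("p",),
                valence=5,
                arousal=5,
            )

    def test_recording_channel_consistency(self):
        t1 = make_trial()
        t2 = make_trial(n_eeg=5)
        t2.trial_id = "t1"
        with pytest.raises(ValueError, match="channel sets"):
            Recording("s", [t1, t2], 128.0)

    def test_rate_positive(self):
        with pytest.raises(ValueError, match="rate_hz"):
            Recording("s", [make_trial()], 0.0)


class TestNativeIO:
    def test_round_trip(self, tmp_path, small_recordings):
        rec = small_recordings[0]
        path = tmp_path / "rec.h5"
        write_recording(rec, path)
        back = read_recording(path)
        assert back.subject_id == rec.subject_id
        assert back.rate_hz == rec.rate_hz
        assert len(back.trials) == len(rec.trials)
        for a, b in zip(rec.trials, back.trials):
            assert a.trial_id == b.trial_id
            assert a.eeg_channels == b.eeg_channels
            assert a.peripheral_channels == b.peripheral_channels
            assert a.valence == b.valence and a.arousal == b.arousal
            np.testing.assert_array_equal(a.eeg, b.eeg)
            np.testing.assert_array_equal(a.peripheral, b.peripheral)

    def test_missing_rating_attr_named(self, tmp_path, small_recordings):
        import h5py

        path = tmp_path / "broken.h5"
        write_recording(small_recordings[0], path)
        with h5py.File(path, "a") as f:
            first = list(f["trials"])[0]
            del f["trials"][first].attrs["valence"]
        with pytest.raises(ValueError, match="valence"):
            read_recording(path)

    def test_missing_trials_group(self, tmp_path):
        import h5py

        path = tmp_path / "empty.h5"
        with h5py.File(path, "w") as f:
            f.attrs["subject_id"] = "s"
            f.attrs["rate_hz"] = 128.0
            f.attrs["trial_order"] = []
        with pytest.raises(ValueError, match="trials"):
            read_recording(path)

    def test_ratings_csv(self, tmp_path, small_recordings):
        frame = ratings_frame(small_recordings)
        assert list(frame.columns) == ["subject_id", "trial_id", "valence", "arousal"]
        assert len(frame) == sum(len(r.trials) for r in small_recordings)
        out = tmp_path / "ratings.csv"
        write_ratings_csv(small_recordings, out)
        assert out.exists()


class TestArrayAdapter:
    def test_published_shape(self, tmp_path):
        import pickle

        rng = np.random.default_rng(0)
        data = rng.standard_normal((40, 40, 8064)).astype(np.float32)
        labels = rng.uniform(1, 9, size=(40, 4))
        path = tmp_path / "s01.dat"
        with open(path, "wb") as fh:
            pickle.dump({"data": data, "labels": labels}, fh)
        rec = read_array_recording(path)
        assert rec.subject_id == "s01"
        assert rec.rate_hz == 128.0
        assert len(rec.trials) == 40
        assert len(rec.eeg_channels) == 32
        assert rec.eeg_channels == EEG_32
        assert rec.peripheral_channels == PERIPHERAL_8
        assert rec.trials[3].valence == pytest.approx(labels[3, 0])

    def test_npz_variant(self, tmp_path):
        rng = np.random.default_rng(1)
        path = tmp_path / "s02.npz"
        np.savez(
            path,
            data=rng.standard_normal((3, 36, 256)),
            labels=rng.uniform(1, 9, size=(3, 4)),
        )
        rec = read_array_recording(path)
        assert len(rec.trials) == 3
        assert len(rec.peripheral_channels) == 4

    def test_missing_key(self, tmp_path):
        import pickle

        path = tmp_path / "bad.dat"
        with open(path, "wb") as fh:
            pickle.dump({"data": np.zeros((2, 34, 64))}, fh)
        with pytest.raises(ValueError, match="labels"):
            read_array_recording(path)
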