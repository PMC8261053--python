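"""Channel harmonization: scaling, amplitude channel, resampling, montages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from bendr.harmonization import (CANONICAL_19, ChannelMap, DatasetStats,
                                 DegenerateDatasetError, HarmonizedSequence,
                                 RawRecording, UnmappableRecordingError,
                                 amplitude_value, apply_antialias,
                                 compute_dataset_stats, extract_trials,
                                 harmonize, harmonize_recording,
                                 read_text_recording, resample_to_target,
                                 scale_sequence, window_pretrain,
                                 write_text_recording)


def _rec(data, sfreq=256.0, names=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return RawRecording(data=data, sfreq=sfreq, ch_names=names)


class TestDatasetStats:
    def test_min_max_over_union_of_recordings(self):
        stats = compute_dataset_stats([_rec(np.arange(-3, 4)),
                                       _rec(np.arange(-1, 6))])
        assert (stats.global_min, stats.global_max) == (-3, 5)

    def test_range_used_downstream(self):
        stats = compute_dataset_stats([_rec([-400.0, 600.0])])
        assert stats.range == 1000.0

    def test_constant_dataset_rejected(self):
        with pytest.raises(DegenerateDatasetError):
            compute_dataset_stats([_rec([5.0, 5.0, 5.0])])

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateDatasetError):
            compute_dataset_stats([])


class TestScaleSequence:
    @pytest.mark.parametrize("x,expected", [
        ([0.0, 2.0, 4.0], [-1.0, 0.0, 1.0]),
        ([-1.0, 1.0], [-1.0, 1.0]),
    ])
    def test_endpoint_mapping(self, x, expected):
        scaled, lo, hi, degen = scale_sequence(x)
        np.testing.assert_allclose(scaled, expected)
        assert (lo, hi) == (min(x), max(x))
        assert not degen

    def test_constant_maps_to_zeros_with_flag(self):
        scaled, lo, hi, degen = scale_sequence([5.0, 5.0, 5.0])
        assert degen
        np.testing.assert_array_equal(scaled, 0.0)

    def test_joint_scaling_preserves_channel_ratios(self):
        x = np.array([[0.0, 1.0], [0.0, 4.0]])
        scaled, *_ = scale_sequence(x)
        # one weight/offset over all channels: channel 0 does not hit +-1
        assert scaled.max() == 1.0 and scaled.min() == -1.0
        assert scaled[0].max() < 1.0

    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=50)
           .filter(lambda v: max(v) > min(v)))
    @settings(deadline=None, max_examples=50)
    def test_idempotent_on_nonconstant(self, values):
        once, *_ = scale_sequence(values)
        twice, *_ = scale_sequence(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)


class TestAmplitudeValue:
    def test_ratio_of_ranges(self):
        stats = DatasetStats(-400.0, 600.0)
        assert amplitude_value(-50.0, 150.0, stats) == pytest.approx(0.2)

    def test_full_range_trial_is_one(self):
        stats = DatasetStats(-2.0, 2.0)
        assert amplitude_value(-2.0, 2.0, stats) == 1.0

    def test_constant_trial_is_zero(self):
        assert amplitude_value(3.0, 3.0, DatasetStats(0.0, 10.0)) == 0.0

    def test_out_of_range_trial_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            v = amplitude_value(0.0, 20.0, DatasetStats(0.0, 10.0))
        assert v == 1.0


class TestResample:
    def test_identity_at_target(self):
        rec = _rec(np.random.default_rng(0).normal(size=(2, 512)))
        out = resample_to_target(rec)
        assert out.sfreq == 256.0 and out.n_samples == 512

    def test_2048_is_exact_decimation_by_8(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 4096))
        out = resample_to_target(_rec(x, sfreq=2048.0))
        assert out.n_samples == 512
        np.testing.assert_array_equal(out.data, x[:, ::8])

    def test_160_uses_whole_multiple_320(self):
        # oracle: enumerate integer multiples/divisors, pick argmin distance
        candidates = [160 * m for m in range(1, 5)]
        best = min(candidates, key=lambda r: abs(r - 256))
        assert best == 320
        rec = _rec(np.arange(160.0)[None, :], sfreq=160.0)
        out = resample_to_target(rec)
        assert out.sfreq == 256.0
        # one second of input stays one second of output
        assert abs(out.n_samples / 256.0 - 1.0) <= 1 / 256.0

    @pytest.mark.parametrize("sfreq", [100.0, 160.0, 200.0, 250.0, 256.0, 2048.0])
    def test_duration_preserved_within_one_sample(self, sfreq):
        n = int(sfreq * 3.0)
        rec = _rec(np.random.default_rng(2).normal(size=(1, n)), sfreq=sfreq)
        out = resample_to_target(rec)
        assert abs(out.n_samples / 256.0 - rec.duration_s) <= 1 / 256.0

    def test_nearest_neighbor_takes_existing_samples(self):
        rec = _rec(np.arange(250.0)[None, :], sfreq=250.0)
        out = resample_to_target(rec)
        assert set(np.unique(out.data)) <= set(np.arange(250.0))


class TestAntialias:
    def test_passband_tone_preserved(self):
        t = np.arange(4096) / 2048.0
        rec = _rec(np.sin(2 * np.pi * 10.0 * t)[None, :], sfreq=2048.0)
        out = apply_antialias(rec, 120.0)
        f, p_in = signal.periodogram(rec.data[0], fs=2048.0)
        _, p_out = signal.periodogram(out.data[0], fs=2048.0)
        band = (f > 8) & (f < 12)
        assert p_out[band].sum() == pytest.approx(p_in[band].sum(), rel=0.01)

    def test_stopband_tone_attenuated_40db(self):
        t = np.arange(4096) / 2048.0
        rec = _rec(np.sin(2 * np.pi * 500.0 * t)[None, :], sfreq=2048.0)
        out = apply_antialias(rec, 120.0)
        f, p_in = signal.periodogram(rec.data[0], fs=2048.0)
        _, p_out = signal.periodogram(out.data[0], fs=2048.0)
        band = (f > 480) & (f < 520)
        assert 10 * np.log10(p_out[band].sum() / p_in[band].sum()) <= -40.0

    def test_cutoff_at_or_above_nyquist_is_noop(self):
        rec = _rec(np.random.default_rng(3).normal(size=(1, 256)), sfreq=256.0)
        with pytest.warns(UserWarning, match="skipped"):
            out = apply_antialias(rec, 200.0)
        np.testing.assert_array_equal(out.data, rec.data)


class TestChannelMapping:
    def test_superset_montage_keeps_20_rows(self):
        rng = np.random.default_rng(4)
        names = list(CANONICAL_19) + [f"AUX{i}" for i in range(45)]
        rec = _rec(rng.normal(size=(64, 256)), names=names)
        stats = DatasetStats(-10.0, 10.0)
        seq = harmonize_recording(rec, ChannelMap.build(names), stats)
        assert seq.data.shape[0] == 20

    def test_two_electrode_sleep_montage(self):
        rng = np.random.default_rng(5)
        names = ["FPz-Cz", "Pz-Oz"]
        rec = _rec(rng.normal(size=(2, 256)), names=names)
        seq = harmonize_recording(rec, ChannelMap.build(names),
                                  DatasetStats(-10.0, 10.0))
        populated = np.flatnonzero(np.any(seq.data[:19] != 0, axis=1))
        assert len(populated) == 2
        assert np.all(seq.data[19] == seq.data[19, 0])  # amplitude row constant

    def test_legacy_temporal_names_alias(self):
        cmap = ChannelMap.build(["T3", "T4", "T5", "T6"])
        idx = {CANONICAL_19[i]: i for i in
               cmap.source_to_canonical.values()}  # pragma: no branch
        assert set(idx) == {"T7", "T8", "P7", "P8"}

    def test_unmappable_recording_rejected(self):
        names = ["EOG1", "ECG"]
        rec = _rec(np.zeros((2, 10)) + [[1.0], [2.0]], names=names)
        with pytest.raises(UnmappableRecordingError):
            harmonize_recording(rec, ChannelMap.build(names),
                                DatasetStats(-10.0, 10.0))

    @pytest.mark.parametrize("names", [
        list(CANONICAL_19),
        ["Fpz-Cz", "Pz-Oz"],
        ["C3", "c4", "CZ"],
    ])
    def test_always_20_rows_and_scaled(self, names):
        rng = np.random.default_rng(6)
        rec = _rec(rng.normal(size=(len(names), 512)) * 40, names=names)
        seq = harmonize(rec, DatasetStats(-200.0, 200.0))
        assert seq.data.shape[0] == 20
        present = sorted(ChannelMap.build(names).source_to_canonical.values())
        sub = seq.data[present]
        assert sub.max() == pytest.approx(1.0, abs=1e-6)
        assert sub.min() == pytest.approx(-1.0, abs=1e-6)
        missing = sorted(set(range(19)) - set(present))
        assert np.all(seq.data[missing] == 0.0)


class TestWindowing:
    def test_130s_recording_gives_two_60s_windows(self):
        seq = HarmonizedSequence(data=np.random.default_rng(7)
                                 .normal(size=(20, 130 * 256)))
        wins = window_pretrain(seq, 60.0)
        assert len(wins) == 2
        assert all(w.n_samples == 15360 for w in wins)

    def test_too_short_recording_gives_empty_list(self):
        seq = HarmonizedSequence(data=np.zeros((20, 59 * 256)))
        assert window_pretrain(seq, 60.0) == []

    def test_windows_tile_without_overlap(self):
        data = np.tile(np.arange(120 * 256), (20, 1)).astype(float)
        seq = HarmonizedSequence(data=data)
        wins = window_pretrain(seq, 60.0)
        assert wins[0].data[0, 0] == 0 and wins[0].data[0, -1] == 15359
        assert wins[1].data[0, 0] == 15360 and wins[1].data[0, -1] == 30719


class TestTrialExtraction:
    def test_pre_stimulus_offset_floor_arithmetic(self):
        seq = HarmonizedSequence(data=np.tile(
            np.arange(20 * 256, dtype=float), (20, 1)))
        trials = extract_trials(seq, [(10.0, "err")], start_s=-0.7, length_s=2.0)
        assert len(trials) == 1
        start = int(np.floor(9.3 * 256))
        assert trials[0][0].shape == (20, 512)
        assert trials[0][0][0, 0] == start

    def test_trial_before_recording_start_dropped(self):
        seq = HarmonizedSequence(data=np.zeros((20, 2560)))
        trials = extract_trials(seq, [(0.5, "a")], start_s=-2.0, length_s=1.0)
        assert trials == []

    def test_sleep_epoch_length(self):
        seq = HarmonizedSequence(data=np.zeros((20, 50 * 256)))
        trials = extract_trials(seq, [(10.0, "N2")], start_s=0.0, length_s=30.0)
        assert trials[0][0].shape == (20, 7680)


class TestHdf5RoundTrip:
    def test_harmonized_batches_round_trip(self, tmp_path):
        from bendr.harmonization import load_harmonized, save_harmonized
        rng = np.random.default_rng(9)
        seqs = [HarmonizedSequence(data=rng.normal(size=(20, 256)),
                                   amplitude=0.4, subject_id="S1",
                                   dataset_id="demo")
                for _ in range(3)]
        path = tmp_path / "batch.h5"
        save_harmonized(path, seqs)
        back = load_harmonized(path)
        assert len(back) == 3
        for a, b in zip(seqs, back):
            np.testing.assert_array_equal(a.data, b.data)
            assert b.amplitude == 0.4 and b.subject_id == "S1"


def _write_minimal_edf(path, data, sfreq, ch_names):
    """Minimal single-purpose EDF writer for synthetic test fixtures.

    16-bit little-endian samples, one-second records, physical range
    [-1000, 1000] uV.
    """
    n_ch, n_samp = data.shape
    spr = int(sfreq)
    n_rec = n_samp // spr
    pmin, pmax, dmin, dmax = -1000.0, 1000.0, -32768, 32767

    def pad(s, n):
        return str(s)[:n].ljust(n).encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 * (1 + n_ch), 8), pad("", 44),
        pad(n_rec, 8), pad("1", 8), pad(n_ch, 4),
    ])
    hdr += b"".join(pad(n, 16) for n in ch_names)
    hdr += b"".join(pad("", 80) for _ in ch_names)
    hdr += b"".join(pad("uV", 8) for _ in ch_names)
    hdr += b"".join(pad(pmin, 8) for _ in ch_names)
    hdr += b"".join(pad(pmax, 8) for _ in ch_names)
    hdr += b"".join(pad(dmin, 8) for _ in ch_names)
    hdr += b"".join(pad(dmax, 8) for _ in ch_names)
    hdr += b"".join(pad("", 80) for _ in ch_names)
    hdr += b"".join(pad(spr, 8) for _ in ch_names)
    hdr += b"".join(pad("", 32) for _ in ch_names)
    digital = np.round((data - pmin) / (pmax - pmin)
                       * (dmax - dmin) + dmin).astype("<i2")
    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                f.write(digital[c, r * spr:(r + 1) * spr].tobytes())


class TestEdfReading:
    def test_edf_file_round_trips_through_reader(self, tmp_path):
        from bendr.harmonization import read_recording
        sfreq = 100.0
        t = np.arange(200) / sfreq
        data = np.stack([100 * np.sin(2 * np.pi * 5 * t),
                         50 * np.cos(2 * np.pi * 3 * t)])
        path = tmp_path / "rec.edf"
        _write_minimal_edf(path, data, sfreq, ["C3", "C4"])
        rec = read_recording(path, subject_id="S9")
        assert rec.sfreq == sfreq
        assert rec.ch_names == ["C3", "C4"]
        assert rec.subject_id == "S9"
        # mne reports volts; shape and waveform (up to scale) must survive
        assert rec.data.shape == (2, 200)
        corr = np.corrcoef(rec.data[0], data[0])[0, 1]
        assert corr > 0.999


class TestTextRoundTrip:
    def test_recording_round_trips_through_text(self, tmp_path):
        rng = np.random.default_rng(8)
        rec = RawRecording(data=rng.normal(size=(3, 100)), sfreq=250.0,
                           ch_names=["C3", "C4", "Cz"],
                           annotations=[(1.0, 0.5, "ev")])
        path = tmp_path / "rec.txt"
        write_text_recording(path, rec)
        back = read_text_recording(path)
        assert back.sfreq == 250.0
        assert back.ch_names == rec.ch_names
        assert back.annotations == rec.annotations
        np.testing.assert_allclose(back.data, rec.data, rtol=1e-6)
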