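"""Epoching arithmetic, window-enumeration oracles and filter behavior."""

import numpy as np
import pytest

from eegtrm.montage import load_layout
from eegtrm.preprocessing import (
    EpochingConfig,
    admissible_nontarget_starts,
    bandpass_downsample,
    epoch_nontargets,
    epoch_targets,
    epoch_trialwise,
)
from eegtrm.synthetic import ContinuousRecord, EventStreamConfig, make_event_stream


def make_record(n_channels=4, n_seconds=60.0, fs=200.0, markers=None, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n_channels, int(n_seconds * fs)))
    names = tuple(f"ch{i}" for i in range(n_channels))
    return ContinuousRecord(data, names, fs, markers or {})


def brute_force_nontarget_starts(record, config, marker_times):
    """Independent oracle: build the allowed time intervals around markers
    with interval arithmetic, then count lattice window starts inside them."""
    fs = record.sampling_rate
    win_n = int(round(config.nontarget_window_ms / 1000.0 * fs))
    step_n = int(round(config.nontarget_step_ms / 1000.0 * fs))
    excl = config.nontarget_exclusion_ms / 1000.0
    total = record.data.shape[1]
    starts = []
    for s in range(0, total - win_n + 1, step_n):
        ts, te = s / fs, (s + win_n) / fs
        if all(te <= m - excl or ts >= m + excl for m in marker_times):
            starts.append(s)
    return np.array(starts, dtype=int)


class TestEpochTargets:
    def test_ebdsdd_style_shape(self):
        """59-channel record minus 4 ocular channels, default window: 55 x 280."""
        m = load_layout("ebdsdd-7x9")
        all_names = ("FP1", "FP2", "AF3", "AF4") + m.channel_names
        rng = np.random.default_rng(1)
        rec = ContinuousRecord(rng.normal(size=(59, 200 * 30)), all_names, 200.0,
                               {"response": np.array([5.0, 12.0, 20.0])})
        cfg = EpochingConfig(excluded_channels=("FP1", "FP2", "AF3", "AF4"))
        ep = epoch_targets(rec, cfg)
        assert ep.data.shape == (3, 55, 280)
        assert ep.channel_names == m.channel_names

    def test_keep_baseline_gives_300_samples(self):
        rec = make_record(markers={"response": np.array([10.0])})
        ep = epoch_targets(rec, EpochingConfig(discard_baseline=False))
        assert ep.data.shape[2] == 300  # 1500 ms at 200 Hz

    def test_constant_record_zeroed_by_baseline(self):
        rec = make_record(markers={"response": np.array([10.0, 20.0])})
        rec.data[...] = 3.14
        ep = epoch_targets(rec)
        assert np.abs(ep.data).max() == 0.0

    def test_baseline_span_mean_is_exactly_zero_before_discard(self):
        rec = make_record(markers={"response": np.array([10.0])})
        ep = epoch_targets(rec, EpochingConfig(discard_baseline=False))
        n_base = int(round(0.1 * rec.sampling_rate))
        np.testing.assert_allclose(ep.data[..., :n_base].mean(axis=-1), 0.0,
                                   atol=1e-12)

    def test_marker_near_edge_skipped_with_warning(self):
        rec = make_record(n_seconds=5.0,
                          markers={"response": np.array([0.5, 3.0])})
        with pytest.warns(UserWarning, match="skipped 1 target"):
            ep = epoch_targets(rec)
        assert ep.data.shape[0] == 1

    def test_channel_exclusion_preserves_order(self):
        rec = make_record(markers={"response": np.array([10.0])})
        ep = epoch_targets(rec, EpochingConfig(excluded_channels=("ch1",)))
        assert ep.channel_names == ("ch0", "ch2", "ch3")


class TestEpochNontargets:
    def test_window_regions_respect_exclusion(self):
        """Markers at 10 s and 40 s: windows only inside [0,7], [13,37], [43,60]."""
        rec = make_record(n_seconds=60.0,
                          markers={"response": np.array([10.0, 40.0])})
        cfg = EpochingConfig()
        starts = admissible_nontarget_starts(rec, cfg)
        ts, te = starts / 200.0, starts / 200.0 + 1.5
        ok = ((te <= 7.0) | ((ts >= 13.0) & (te <= 37.0)) | (ts >= 43.0))
        assert ok.all()
        np.testing.assert_array_equal(
            starts, brute_force_nontarget_starts(rec, cfg, [10.0, 40.0])
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_counts_match_enumeration_on_random_marker_layouts(self, seed):
        rng = np.random.default_rng(seed)
        n_markers = int(rng.integers(0, 8))
        markers = np.sort(rng.uniform(0, 60, size=n_markers))
        rec = make_record(n_channels=2, n_seconds=60.0,
                          markers={"response": markers})
        cfg = EpochingConfig()
        got = admissible_nontarget_starts(rec, cfg)
        expected = brute_force_nontarget_starts(rec, cfg, markers)
        np.testing.assert_array_equal(got, expected)

    def test_balance_subsamples_to_target_count(self):
        rec = make_record(n_seconds=120.0, markers={"response": np.array([60.0])})
        ep = epoch_nontargets(rec, EpochingConfig(seed=1), n_keep=5)
        assert ep.data.shape[0] == 5

    def test_total_exclusion_yields_empty_set(self):
        rec = make_record(n_seconds=30.0, markers={"response": np.array([15.0])})
        cfg = EpochingConfig(nontarget_exclusion_ms=60_000.0)
        with pytest.warns(UserWarning, match="no admissible"):
            ep = epoch_nontargets(rec, cfg)
        assert ep.data.shape[0] == 0

    def test_stimulus_and_response_markers_both_excluded(self, small_montage):
        stream = make_event_stream(
            EventStreamConfig(small_montage, n_events=4, sampling_rate=200.0, seed=4)
        )
        cfg = EpochingConfig()
        starts = admissible_nontarget_starts(stream, cfg)
        all_markers = stream.all_marker_times()
        expected = brute_force_nontarget_starts(stream, cfg, all_markers)
        np.testing.assert_array_equal(starts, expected)


class TestEpochTrialwise:
    def test_hgd_style_shape(self):
        """4 s trials at 250 Hz on 44 channels: 44 x 1000 segments."""
        m = load_layout("hgd-7x7")
        rng = np.random.default_rng(2)
        rec = ContinuousRecord(rng.normal(size=(44, 250 * 40)), m.channel_names, 250.0)
        onsets = np.array([1.0, 8.0, 15.0, 22.0])
        ep = epoch_trialwise(rec, onsets, 4.0, labels=np.array([0, 1, 2, 3]))
        assert ep.data.shape == (4, 44, 1000)
        assert ep.labels.tolist() == [0, 1, 2, 3]

    def test_one_second_trials(self):
        rec = make_record(fs=250.0, n_seconds=10.0)
        ep = epoch_trialwise(rec, np.array([1.0, 3.0]), 1.0)
        assert ep.data.shape[2] == 250

    def test_zero_duration_rejected(self):
        rec = make_record()
        with pytest.raises(ValueError, match="positive"):
            epoch_trialwise(rec, np.array([1.0]), 0.0)

    def test_onset_near_end_skipped(self):
        rec = make_record(n_seconds=10.0)
        with pytest.warns(UserWarning, match="skipped 1 trial"):
            ep = epoch_trialwise(rec, np.array([1.0, 9.0]), 4.0,
                                 labels=np.array([0, 1]))
        assert ep.data.shape[0] == 1
        assert ep.labels.tolist() == [0]


class TestBandpassDownsample:
    def test_passband_sinusoid_preserved(self):
        """10 Hz probe through a 4-125 Hz band, 500 -> 250 Hz: amplitude
        within 1%."""
        fs = 500.0
        t = np.arange(int(20 * fs)) / fs
        rec = ContinuousRecord(np.sin(2 * np.pi * 10 * t)[None, :], ("p",), fs)
        out = bandpass_downsample(rec, 4.0, 125.0, 250.0)
        assert out.sampling_rate == 250.0
        mid = out.data[0, 500:-500]  # ignore filter edges
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_sinusoid_attenuated(self):
        """1 Hz probe is attenuated by >= 20 dB."""
        fs = 500.0
        t = np.arange(int(40 * fs)) / fs
        rec = ContinuousRecord(np.sin(2 * np.pi * 1.0 * t)[None, :], ("p",), fs)
        out = bandpass_downsample(rec, 4.0, 125.0, None)
        mid = out.data[0, 2000:-2000]
        assert np.abs(mid).max() < 0.1  # -20 dB relative to unit amplitude

    def test_dc_removed(self):
        rec = make_record(fs=500.0, n_seconds=10.0)
        rec.data[...] = 7.0
        out = bandpass_downsample(rec, 4.0, 125.0, 250.0)
        assert np.abs(out.data).max() < 1e-6

    def test_band_exceeding_resampled_nyquist_rejected(self):
        rec = make_record(fs=500.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_downsample(rec, 4.0, 200.0, 250.0)

    def test_marker_times_unchanged(self):
        rec = make_record(fs=500.0, markers={"response": np.array([5.0, 9.0])})
        out = bandpass_downsample(rec, 4.0, 125.0, 250.0)
        np.testing.assert_array_equal(out.markers["response"], [5.0, 9.0])
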