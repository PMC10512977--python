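"""Filtering, epoching, rejection, baseline and downsampling."""

import numpy as np
import pytest

from cvepauth.preprocess import (
    Epoch,
    EpochSet,
    RawRecording,
    bandpass_5_86,
    baseline_correct,
    downsample_avg4,
    extract_epochs,
    notch_50,
    reject_amplitude,
    run_pipeline,
    select_channels,
)


def _sine_recording(freq, fs=1000.0, seconds=4.0, channels=("Oz",)):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (len(channels), 1))
    return RawRecording(data=data, fs=fs, channels=tuple(channels))


def _band_power(x, freq, fs):
    f = np.fft.rfftfreq(len(x), 1 / fs)
    p = np.abs(np.fft.rfft(x)) ** 2
    band = (f > freq - 1) & (f < freq + 1)
    return p[band].sum()


class TestNotch:
    def test_50hz_attenuated(self):
        rec = _sine_recording(50.0)
        out = notch_50(rec).data[0]
        mid = slice(500, -500)  # avoid edge transients
        assert _band_power(out[mid], 50, 1000) < 0.01 * _band_power(rec.data[0][mid], 50, 1000)

    def test_10hz_passed_unity(self):
        rec = _sine_recording(10.0)
        out = notch_50(rec).data[0]
        mid = slice(500, -500)
        gain = np.sqrt(_band_power(out[mid], 10, 1000) / _band_power(rec.data[0][mid], 10, 1000))
        assert abs(gain - 1) < 0.01

    def test_zero_in_zero_out(self):
        rec = RawRecording(np.zeros((2, 1000)), 1000.0, ("Oz", "O1"))
        assert np.allclose(notch_50(rec).data, 0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            notch_50(RawRecording(np.zeros((1, 100)), 90.0, ("Oz",)))


class TestBandpass:
    def test_dc_removed(self):
        rec = RawRecording(np.full((1, 4000), 5.0), 1000.0, ("Oz",))
        out = bandpass_5_86(rec).data[0]
        assert abs(out[1000:-1000].mean()) < 1e-3 * 5.0

    def test_2hz_attenuated_20db(self):
        rec = _sine_recording(2.0, seconds=8.0)
        out = bandpass_5_86(rec).data[0]
        mid = slice(2000, -2000)
        gain = np.sqrt(_band_power(out[mid], 2, 1000) / _band_power(rec.data[0][mid], 2, 1000))
        assert gain < 10 ** (-20 / 20)

    def test_40hz_within_1db(self):
        rec = _sine_recording(40.0)
        out = bandpass_5_86(rec).data[0]
        mid = slice(1000, -1000)
        gain = np.sqrt(_band_power(out[mid], 40, 1000) / _band_power(rec.data[0][mid], 40, 1000))
        assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            bandpass_5_86(RawRecording(np.zeros((1, 1000)), 150.0, ("Oz",)))


class TestSelectChannels:
    def _rec(self):
        names = ("F1", "Fz", "F2", "Pz", "PO5", "PO3", "POz", "PO4", "PO6",
                 "O1", "Oz", "O2", "P1", "P2")
        return RawRecording(np.arange(len(names) * 10, dtype=float).reshape(len(names), 10),
                            1000.0, names)

    def test_po9_order(self):
        out = select_channels(self._rec(), "PO9")
        assert out.channels == ("Pz", "PO5", "PO3", "POz", "PO4", "PO6", "O1", "Oz", "O2")

    @pytest.mark.parametrize("name,n", [("F3", 3), ("P3", 3), ("O3", 3), ("PO9", 9)])
    def test_named_subset_sizes(self, name, n):
        assert len(select_channels(self._rec(), name).channels) == n

    def test_missing_channel_named_in_error(self):
        with pytest.raises(KeyError, match="XX"):
            select_channels(self._rec(), ["Oz", "XX"])

    def test_data_follows_selection(self):
        rec = self._rec()
        out = select_channels(rec, ["Oz", "F1"])
        assert np.array_equal(out.data[0], rec.data[rec.channels.index("Oz")])
        assert np.array_equal(out.data[1], rec.data[rec.channels.index("F1")])


class TestExtractEpochs:
    def _rec(self, n=20000):
        data = np.arange(n, dtype=float)[None, :]
        return RawRecording(data, 1000.0, ("Oz",))

    def test_window_arithmetic(self):
        rec = self._rec()
        es = extract_epochs(rec, [(10000, "left", True)])
        assert len(es) == 1
        e = es.epochs[0]
        assert e.data.shape == (1, 1050)
        assert e.data[0, 0] == 10140 and e.data[0, -1] == 11189

    def test_incorrect_trial_excluded(self):
        es = extract_epochs(self._rec(), [(1000, "left", False), (2000, "top", True)])
        assert len(es) == 1 and es.epochs[0].position == "top"
        assert es.provenance["n_incorrect"] == 1

    def test_truncated_event_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            es = extract_epochs(self._rec(n=1500), [(1000, "left", True)])
        assert len(es) == 0 and es.provenance["n_truncated"] == 1

    def test_all_correct_events_extracted(self):
        events = [(1000 * k, "left", True) for k in range(1, 15)]
        es = extract_epochs(self._rec(), events)
        assert len(es) == es.provenance["extracted"] == 14


class TestRejectBaselineDownsample:
    def _epochset(self, peaks):
        epochs = [
            Epoch(data=np.full((1, 8), p), channels=("Oz",), position="left")
            for p in peaks
        ]
        return EpochSet(epochs, {"extracted": len(epochs)})

    def test_rejection_boundary(self):
        es = reject_amplitude(self._epochset([99.0, 100.0, 101.0]))
        kept = [float(e.data.max()) for e in es]
        assert kept == [99.0, 100.0]  # exactly at threshold is kept
        assert es.provenance["n_rejected"] == 1

    def test_rejection_monotone_in_threshold(self):
        peaks = [10.0, 50.0, 99.0, 150.0, 300.0]
        kept = [len(reject_amplitude(self._epochset(peaks), th)) for th in (20, 60, 100, 400)]
        assert kept == sorted(kept)

    def test_baseline_zero_mean_and_idempotent(self, rng):
        es = EpochSet([Epoch(rng.normal(5, 1, (3, 100)), ("a", "b", "c"), "left")])
        once = baseline_correct(es)
        assert np.allclose(once.epochs[0].data.mean(axis=1), 0, atol=1e-9)
        twice = baseline_correct(once)
        assert np.allclose(once.epochs[0].data, twice.epochs[0].data)

    def test_downsample_block_means(self):
        es = EpochSet([Epoch(np.arange(1, 9, dtype=float)[None, :], ("Oz",), "left")])
        out = downsample_avg4(es).epochs[0].data
        assert out.tolist() == [[2.5, 6.5]]

    def test_downsample_1050_to_262(self):
        es = EpochSet([Epoch(np.zeros((2, 1050)), ("a", "b"), "left")])
        assert downsample_avg4(es).epochs[0].data.shape == (2, 262)

    def test_constant_preserved(self):
        es = EpochSet([Epoch(np.full((1, 12), 3.3), ("Oz",), "left")])
        assert np.allclose(downsample_avg4(es).epochs[0].data, 3.3)


def test_pipeline_preserves_evoked_shape_noise_free():
    """Filtering + epoching + downsampling keeps the projected kernel's
    waveform: pipeline output correlates > 0.99 with the directly computed
    evoked trace."""
    from cvepauth.simulate import (
        SessionConfig, sample_subject_profile, synthesize_session,
        _evoked_component,
    )
    from cvepauth.stimulus import build_code_set, build_session_schedule, code_to_frame_train

    profile = sample_subject_profile(5)
    sched = build_session_schedule(n_runs=2, trials_per_run=4, rng_seed=0)
    cfg = SessionConfig(
        channels=("Pz", "PO5", "PO3", "POz", "PO4", "PO6", "O1", "Oz", "O2"),
        noise=False, blinks=False, line_noise=False,
        slow_latency_scale=0.0, slow_amplitude_scale=0.0,
    )
    rec = synthesize_session(profile, sched, cfg)
    es = run_pipeline(rec, channels="PO9")
    pos = es.epochs[0].position
    got = es.epochs[0].data

    code = build_code_set()[pos]
    indicator = code_to_frame_train(code)
    evoked = _evoked_component(profile, pos, cfg, indicator)
    topo = profile.topography(pos, cfg.channels)
    # reference: the band-passed projected kernel, windowed and downsampled
    from cvepauth.preprocess import RawRecording, bandpass_5_86

    proj = RawRecording(topo[:, None] * evoked[None, :], 1000.0, cfg.channels)
    ref = bandpass_5_86(proj).data[:, 140:1190]
    ref = ref - ref.mean(axis=1, keepdims=True)
    ref = ref[:, : 262 * 4].reshape(ref.shape[0], 262, 4).mean(axis=2)
    r = np.corrcoef(got.ravel(), ref.ravel())[0, 1]
    assert r > 0.99


def test_pipeline_provenance_counts(tiny_cohort):
    # counts are tracked end to end: kept + rejected = extracted
    from cvepauth import preprocess, simulate
    from cvepauth.stimulus import build_session_schedule

    profile = simulate.sample_subject_profile(3)
    sched = build_session_schedule(n_runs=2, trials_per_run=6, rng_seed=2)
    rec = simulate.synthesize_session(
        profile, sched, simulate.SessionConfig(channels=("Oz", "O1", "O2"), rng_seed=4)
    )
    es = preprocess.run_pipeline(rec, channels=("Oz", "O1", "O2"))
    p = es.provenance
    assert p["n_kept"] + p["n_rejected"] == p["extracted"]
    assert p["extracted"] + p["n_incorrect"] + p["n_truncated"] == p["n_events"]
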