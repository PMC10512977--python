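"""Synthetic cohort generator: reproducibility, evoked model, noise law."""

from dataclasses import replace

import numpy as np
import pytest

from cvepauth.preprocess import run_pipeline
from cvepauth.simulate import (
    MONTAGE_64,
    PO9_SET,
    SessionConfig,
    sample_subject_profile,
    simulate_cohort,
    synthesize_session,
    synthesize_trial,
)
from cvepauth.stimulus import build_code_set, build_session_schedule, code_to_frame_train

CODE = build_code_set()["left"]
INDICATOR = code_to_frame_train(CODE)


class TestProfiles:
    def test_same_seed_reproduces_exactly(self):
        a = sample_subject_profile(7)
        b = sample_subject_profile(7)
        assert a == b

    def test_different_seeds_differ(self):
        a = sample_subject_profile(1)
        b = sample_subject_profile(2)
        ka = a.kernel_waveform("left")
        kb = b.kernel_waveform("left")
        r = np.corrcoef(ka, kb)[0, 1]
        assert r < 1.0 - 1e-6

    def test_zero_variability_collapses_to_population_mean(self):
        kernels = [sample_subject_profile(s, variability=0.0).kernels for s in (1, 2, 3)]
        assert kernels[0] == kernels[1] == kernels[2]

    def test_negative_variability_rejected(self):
        with pytest.raises(ValueError):
            sample_subject_profile(1, variability=-1)

    def test_topography_nonnegative_and_posterior_peaked(self):
        p = sample_subject_profile(3)
        for pos in ("left", "right", "top", "bottom"):
            w = p.topography(pos)
            assert np.all(w >= 0)
            peak = MONTAGE_64[int(np.argmax(w))]
            assert peak in PO9_SET


class TestTrials:
    CFG = SessionConfig(channels=("Pz", "PO5", "PO6", "Oz"), noise=False,
                        blinks=False, line_noise=False)

    def test_noise_free_trials_identical(self):
        p = sample_subject_profile(1)
        a = synthesize_trial(p, INDICATOR, self.CFG)
        b = synthesize_trial(p, INDICATOR, self.CFG)
        assert np.array_equal(a, b)

    def test_lateralized_asymmetry_flips(self):
        p = sample_subject_profile(1)
        left = synthesize_trial(p, INDICATOR, self.CFG, position="left")
        right = synthesize_trial(p, INDICATOR, self.CFG, position="right")
        i5, i6 = self.CFG.channels.index("PO5"), self.CFG.channels.index("PO6")
        asym_l = np.abs(left[i5]).sum() - np.abs(left[i6]).sum()
        asym_r = np.abs(right[i5]).sum() - np.abs(right[i6]).sum()
        # left stimulus drives the contralateral (right, PO6) side harder
        assert asym_l < 0 < asym_r

    def test_sqrt_n_averaging_law_white_noise(self):
        """With white background noise, averaging N trials improves SNR by
        ~sqrt(N) (Monte-Carlo, 200 trials, within 20%)."""
        p = replace(
            sample_subject_profile(2),
            noise_exponent=0.0, alpha_rel_power=0.0, line_amp_uv=0.0,
        )
        cfg = SessionConfig(channels=("POz", "Oz"), blinks=False, line_noise=False)
        clean = synthesize_trial(p, INDICATOR, replace(cfg, noise=False))
        rng = np.random.default_rng(0)
        trials = np.stack([
            synthesize_trial(p, INDICATOR, cfg, rng=rng) for _ in range(200)
        ])
        sig = clean.std()

        def snr(n):
            groups = trials[: (200 // n) * n].reshape(-1, n, *clean.shape).mean(axis=1)
            resid = (groups - clean).std()
            return sig / resid

        for n in (4, 16):
            ratio = snr(n) / snr(1)
            assert abs(ratio - np.sqrt(n)) < 0.2 * np.sqrt(n)


class TestSessions:
    def test_zero_error_rate_all_correct(self):
        p = replace(sample_subject_profile(1), behavioral_error_rate=0.0)
        sched = build_session_schedule(n_runs=2, trials_per_run=4, rng_seed=0)
        rec = synthesize_session(p, sched, SessionConfig(channels=("Oz",), rng_seed=1))
        assert all(correct for _, _, correct in rec.events)
        assert len(rec.events) == 8

    def test_session2_gains_differ(self):
        p = sample_subject_profile(1)
        sched = build_session_schedule(n_runs=2, trials_per_run=2, rng_seed=0)
        cfg1 = SessionConfig(channels=("Oz", "O1"), session_index=1, rng_seed=5,
                             noise=False, blinks=False, line_noise=False,
                             slow_latency_scale=0, slow_amplitude_scale=0)
        cfg2 = replace(cfg1, session_index=2)
        r1 = synthesize_session(p, sched, cfg1)
        r2 = synthesize_session(p, sched, cfg2)
        assert not np.allclose(r1.data, r2.data)

    def test_blinks_trigger_amplitude_rejection(self):
        p = replace(sample_subject_profile(4), blink_rate_hz=0.3)
        sched = build_session_schedule(n_runs=2, trials_per_run=20, rng_seed=0)
        rec = synthesize_session(
            p, sched, SessionConfig(channels=("Fpz", "Fz", "Oz", "POz"), rng_seed=9)
        )
        es = run_pipeline(rec, channels=("Fpz", "Fz", "Oz", "POz"))
        assert es.provenance["n_rejected"] >= 1

    def test_event_windows_fit_recording(self):
        p = sample_subject_profile(1)
        sched = build_session_schedule(n_runs=2, trials_per_run=4, rng_seed=0)
        rec = synthesize_session(p, sched, SessionConfig(channels=("Oz",), rng_seed=1))
        for onset, _, _ in rec.events:
            assert onset + int(1.19 * rec.fs) <= rec.n_samples


class TestCohort:
    def test_minimum_two_subjects(self):
        with pytest.raises(ValueError):
            simulate_cohort(1)

    def test_cohort_counts_and_determinism(self):
        sched = build_session_schedule(n_runs=2, trials_per_run=2, rng_seed=0)
        cfg = SessionConfig(channels=("Oz", "POz"))
        a = simulate_cohort(3, rng_seed=5, schedule=sched, cfg_template=cfg)
        b = simulate_cohort(3, rng_seed=5, schedule=sched, cfg_template=cfg)
        assert len(a) == 3
        assert all(e.session1.session_id == 1 and e.session2.session_id == 2 for e in a)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.session1.data, eb.session1.data)
            assert np.array_equal(ea.session2.data, eb.session2.data)

    def test_cohort_written_to_disk_roundtrips(self, tmp_path):
        import json

        from cvepauth.simulate import read_recording

        sched = build_session_schedule(n_runs=2, trials_per_run=2, rng_seed=0)
        cfg = SessionConfig(channels=("Oz", "POz"))
        entries = simulate_cohort(2, rng_seed=8, schedule=sched,
                                  cfg_template=cfg, out_dir=tmp_path)
        manifest = json.loads((tmp_path / "events.json").read_text())
        assert len(manifest["recordings"]) == 4
        back = read_recording(tmp_path / "S01_session1.h5")
        assert np.array_equal(back.data, entries[0].session1.data)
        assert back.events == entries[0].session1.events

    def test_identity_signal_exists(self, tiny_cohort):
        """Across-session within-subject average epochs correlate more than
        across-subject ones."""
        view1 = tiny_cohort.session_view(1, "PO9")
        view2 = tiny_cohort.session_view(2, "PO9")
        subs = list(view1)
        means1 = {s: np.concatenate([view1[s][p].mean(axis=0).ravel()
                                     for p in view1[s]]) for s in subs}
        means2 = {s: np.concatenate([view2[s][p].mean(axis=0).ravel()
                                     for p in view2[s]]) for s in subs}
        within = [np.corrcoef(means1[s], means2[s])[0, 1] for s in subs]
        across = [
            np.corrcoef(means1[a], means2[b])[0, 1]
            for a in subs for b in subs if a != b
        ]
        assert min(within) > max(across)
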