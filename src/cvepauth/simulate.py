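"""Synthetic MBCT EEG sessions with the structure the method assumes.

The forward model is the standard linear c-VEP superposition: each lit
stimulus frame triggers a copy of a subject- and position-specific evoked
kernel, delayed by the visual-pathway latency τ ≈ 0.14 s, spatially
projected onto the scalp by a parieto-occipital topography, and summed
with ongoing background activity,

    x_c(t) = g_c * sum_i bit_i * w_c[pos] * h_pos(t - i/60 - tau) + n_c(t).

Subject identity lives in the kernels: every subject draws damped-oscillation
component parameters (amplitude, latency, frequency, decay) around a shared
population mean, scaled by a ``variability`` knob, so that different
subjects produce reliably different c-VEP waveforms while remaining
physiologically alike — the premise of c-VEP biometrics.

Background activity is 1/f Gaussian noise (exponent ≈ 1) with an alpha-band
bump, a 50 Hz mains component, and sporadic frontal-dominant blink
transients; a fraction of the noise is common across channels.  A second
session applies kernel-amplitude, latency and channel-gain drift, emulating
across-day electrode shift and state changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .preprocess import RawRecording
from .stimulus import (
    CodeSet,
    FRAME_RATE,
    StimulusSchedule,
    build_code_set,
    build_session_schedule,
    code_to_frame_train,
)

__all__ = [
    "MONTAGE_64",
    "SubjectProfile",
    "SessionConfig",
    "CohortEntry",
    "sample_subject_profile",
    "synthesize_trial",
    "synthesize_session",
    "simulate_cohort",
]

#: 64-channel 10-10 montage (extended international layout, Neuroscan-style
#: naming: CB1/CB2 for the cerebellar sites, M1/M2 mastoids).
MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "CB1", "O1", "Oz", "O2", "CB2", "M1", "M2",
)

PO9_SET = ("Pz", "PO5", "PO3", "POz", "PO4", "PO6", "O1", "Oz", "O2")
POSITIONS = ("left", "right", "top", "bottom")

VISUAL_PATH_DELAY_S = 0.14
KERNEL_SUPPORT_S = 0.5

# Population-mean evoked components: (amplitude µV, latency s, frequency Hz,
# decay s).  Three components roughly spanning the canonical VEP complex.
_POP_COMPONENTS = (
    (4.5, 0.045, 7.5, 0.10),
    (5.8, 0.080, 11.0, 0.08),
    (3.2, 0.120, 16.0, 0.06),
)
# Per-position multiplicative tilt of the population means, so the four
# ring positions evoke related but non-identical responses.
_POSITION_TILT = {"left": 1.00, "right": 0.95, "top": 1.05, "bottom": 0.90}

# Scalp weighting: relative strength per electrode row.  The response is
# parieto-occipital; anterior rows carry only weak volume-conducted leakage.
_ROW_WEIGHT = {
    "O": 1.0, "PO": 0.85, "P": 0.55, "CP": 0.20, "CB": 0.45,
    "C": 0.10, "T": 0.06, "TP": 0.10, "FC": 0.07, "FT": 0.05,
    "F": 0.09, "AF": 0.05, "Fp": 0.04, "M": 0.05,
}


@dataclass(frozen=True)
class SubjectProfile:
    """Everything idiosyncratic about one simulated participant."""

    subject_id: str
    kernels: dict  # position -> (amp, latency, freq, decay) component array
    spatial_signature: dict  # channel -> multiplicative weight idiosyncrasy
    lateralization: float  # contralateral emphasis for left/right stimuli
    noise_exponent: float  # 1/f spectral exponent
    noise_rms_uv: float  # broadband background RMS, µV
    alpha_rel_power: float  # alpha bump height relative to the 1/f floor
    line_amp_uv: float  # 50 Hz mains amplitude, µV
    blink_rate_hz: float
    behavioral_error_rate: float
    #: trait band of slow within-session response wandering: every session's
    #: latency/amplitude modulation stays inside this subject-level range,
    #: so enrollment data naturally spans the variation seen at verification
    slow_latency_band_s: float = 0.010
    slow_amplitude_band: float = 0.15
    visual_delay_s: float = VISUAL_PATH_DELAY_S

    def kernel_waveform(self, position: str, fs: float = 1000.0,
                        amp_scale: float = 1.0, latency_shift_s: float = 0.0) -> np.ndarray:
        """Sampled evoked kernel h_pos(t) on [0, 0.5) s.

        ``amp_scale`` and ``latency_shift_s`` implement session drift.
        """
        n = int(round(KERNEL_SUPPORT_S * fs))
        t = np.arange(n) / fs
        out = np.zeros(n)
        for amp, lat, freq, decay in self.kernels[position]:
            lat = lat + latency_shift_s
            tt = t - lat
            m = tt > 0
            out[m] += amp * np.exp(-tt[m] / decay) * np.sin(2 * np.pi * freq * tt[m])
        # cosine taper over the last 20% keeps the kernel finite-support smooth
        edge = int(0.8 * n)
        out[edge:] *= 0.5 * (1 + np.cos(np.pi * np.arange(n - edge) / (n - edge)))
        return amp_scale * out

    def topography(self, position: str, channels: Sequence[str] = MONTAGE_64) -> np.ndarray:
        """Nonnegative scalp weights for one stimulus position.

        Peaks over the parieto-occipital row; left/right stimuli weight the
        contralateral hemisphere more strongly, top stimuli tilt parietal and
        bottom stimuli tilt occipital.
        """
        w = np.zeros(len(channels))
        for i, ch in enumerate(channels):
            row = ch.rstrip("z0123456789")
            base = _ROW_WEIGHT.get(row, 0.0)
            if base == 0.0:
                continue
            if ch.endswith("z"):
                hemi = 0.0
            else:
                hemi = -1.0 if int(ch[len(row):]) % 2 == 1 else 1.0  # odd = left
            scale = 1.0
            if position == "left":
                scale = 1.0 + self.lateralization * hemi  # contralateral: right hemi
            elif position == "right":
                scale = 1.0 - self.lateralization * hemi
            elif position == "top":
                scale = 1.15 if row in ("P", "CP") else 0.95
            elif position == "bottom":
                scale = 1.15 if row in ("O", "CB") else 0.95
            w[i] = max(base * scale * self.spatial_signature.get(ch, 1.0), 0.0)
        # the response focus stays parieto-occipital for every subject: no
        # channel outside the nine PO sites may carry the peak weight
        members = [i for i, ch in enumerate(channels) if ch in PO9_SET]
        if members:
            cap = 0.95 * max(w[members])
            for i, ch in enumerate(channels):
                if ch not in PO9_SET:
                    w[i] = min(w[i], cap)
        return w


@dataclass(frozen=True)
class SessionConfig:
    """Acquisition and drift settings for one simulated session."""

    fs: float = 1000.0
    channels: tuple[str, ...] = MONTAGE_64
    session_index: int = 1
    amplitude_jitter: float = 0.15  # session-2 kernel amplitude drift, fraction
    latency_jitter_s: float = 0.005  # session-2 latency drift, seconds
    gain_jitter: float = 0.10  # session-2 per-channel gain drift, fraction
    # slow within-session nonstationarity (attention / impedance drift over
    # the ~25 min run): sinusoidal modulation of kernel latency and
    # amplitude across the trial sequence, in both sessions; these scales
    # multiply the subject's trait bands (0 disables the modulation)
    slow_latency_scale: float = 1.0
    slow_amplitude_scale: float = 1.0
    noise: bool = True
    blinks: bool = True
    line_noise: bool = True
    rng_seed: int = 0


@dataclass(frozen=True)
class CohortEntry:
    profile: SubjectProfile
    session1: RawRecording
    session2: RawRecording


def sample_subject_profile(
    rng_seed: int, variability: float = 1.0, subject_id: str | None = None
) -> SubjectProfile:
    """Draw one subject's evoked kernels and noise profile.

    ``variability`` scales the spread of every kernel parameter around the
    population mean; 0 collapses all subjects onto the shared mean response.
    The draw is a pure function of ``(rng_seed, variability)``.
    """
    if variability < 0:
        raise ValueError("variability must be >= 0")
    rng = np.random.default_rng(rng_seed)
    kernels = {}
    for pos in POSITIONS:
        tilt = _POSITION_TILT[pos]
        comps = []
        for amp, lat, freq, decay in _POP_COMPONENTS:
            # spreads reflect plausible physiology: amplitudes and decay vary
            # a lot between people, component latencies by ~a dozen ms, and
            # the oscillatory frequencies only subtly — impostor responses
            # must stay morphologically similar, as real VEPs are.
            comps.append(
                (
                    max(amp * tilt * (1 + variability * rng.normal(0, 0.30)), 1.0),
                    float(np.clip(lat + variability * rng.normal(0, 0.007), 0.01, 0.25)),
                    max(freq * (1 + variability * rng.normal(0, 0.03)), 3.0),
                    float(np.clip(decay * (1 + variability * rng.normal(0, 0.25)), 0.02, 0.3)),
                )
            )
        kernels[pos] = tuple(comps)
    # individual scalp pattern: stable multiplicative channel weights — the
    # spatial counterpart of the kernel idiosyncrasies, and (unlike latency)
    # hardly touched by across-day drift
    signature = {
        ch: float(np.exp(variability * np.clip(rng.normal(0, 0.35), -1.8, 1.8)))
        for ch in MONTAGE_64
    }
    return SubjectProfile(
        subject_id=subject_id or f"S{rng_seed:03d}",
        kernels=kernels,
        spatial_signature=signature,
        lateralization=float(np.clip(0.35 + variability * rng.normal(0, 0.08), 0.05, 0.8)),
        noise_exponent=float(np.clip(1.0 + variability * rng.normal(0, 0.03), 0.9, 1.1)),
        noise_rms_uv=float(np.clip(10.0 * (1 + variability * rng.normal(0, 0.05)), 8.0, 12.0)),
        alpha_rel_power=float(np.clip(2.0 + variability * rng.normal(0, 0.2), 1.4, 2.6)),
        line_amp_uv=float(np.clip(2.0 + variability * rng.normal(0, 0.2), 1.0, 3.0)),
        blink_rate_hz=float(np.clip(0.12 + variability * rng.normal(0, 0.03), 0.02, 0.3)),
        behavioral_error_rate=float(rng.uniform(0.0, 0.05)),
        slow_latency_band_s=float(np.clip(rng.normal(0.010, 0.002), 0.008, 0.013)),
        slow_amplitude_band=float(np.clip(rng.normal(0.18, 0.05), 0.12, 0.30)),
    )


def _session_drift(profile: SubjectProfile, cfg: SessionConfig, rng: np.random.Generator):
    """Per-position (amp_scale, latency_shift) and per-channel gains.

    Session 1 is the enrollment reference (no drift); session 2 jitters
    kernel amplitude, latency and channel gains.
    """
    n_ch = len(cfg.channels)
    if cfg.session_index <= 1:
        return {p: (1.0, 0.0) for p in POSITIONS}, np.ones(n_ch)
    drift = {
        p: (
            1.0 + cfg.amplitude_jitter * rng.uniform(-1, 1),
            cfg.latency_jitter_s * rng.uniform(-1, 1),
        )
        for p in POSITIONS
    }
    gains = 1.0 + cfg.gain_jitter * rng.uniform(-1, 1, size=n_ch)
    return drift, gains


def _evoked_component(
    profile: SubjectProfile,
    position: str,
    cfg: SessionConfig,
    code_indicator: np.ndarray,
    amp_scale: float = 1.0,
    latency_shift_s: float = 0.0,
) -> np.ndarray:
    """Single-channel evoked waveform: bit-impulse train ⊛ kernel, delayed by τ."""
    fs = cfg.fs
    # impulses at the onsets of lit frames
    rising = np.flatnonzero(np.diff(np.concatenate(([0.0], code_indicator))) > 0)
    kernel = profile.kernel_waveform(position, fs, amp_scale, latency_shift_s)
    delay = int(round(profile.visual_delay_s * fs))
    out = np.zeros(len(code_indicator) + delay + len(kernel))
    for r in rising:
        out[delay + r : delay + r + len(kernel)] += kernel
    return out


def _colored_noise(
    rng: np.random.Generator, n_ch: int, n_samples: int, profile: SubjectProfile,
    fs: float, common_frac: float = 0.3,
) -> np.ndarray:
    """1/f background with an alpha bump, partially shared across channels."""
    nfft = n_samples
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-profile.noise_exponent / 2)
    shape[0] = 0.0
    shape = shape * (1 + profile.alpha_rel_power * np.exp(-((freqs - 10.0) ** 2) / (2 * 1.5**2)))
    out = np.empty((n_ch, n_samples), dtype=np.float32)
    common = None
    for c in range(n_ch + 1):
        spec = shape * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
        x = np.fft.irfft(spec, n=nfft)
        x *= profile.noise_rms_uv / x.std()
        if c == 0:
            common = x
        else:
            out[c - 1] = np.sqrt(1 - common_frac) * x + np.sqrt(common_frac) * common
    return out


_BLINK_FRONTAL = {"Fp": 1.0, "AF": 0.75, "F": 0.5, "FT": 0.3, "FC": 0.3,
                  "T": 0.15, "C": 0.15, "TP": 0.12, "CP": 0.12,
                  "P": 0.18, "PO": 0.18, "O": 0.18, "CB": 0.18, "M": 0.15}


def _inject_blinks(
    data: np.ndarray, channels: Sequence[str], rng: np.random.Generator,
    profile: SubjectProfile, fs: float,
) -> None:
    """Add raised-cosine blink transients, frontal-dominant but with enough
    posterior leakage that some epochs trip the ±100 µV rejection rule."""
    n_samples = data.shape[1]
    # fast ~60 ms rise, slower ~250 ms fall: the sharp edge is what survives
    # the 5 Hz high-pass and trips the amplitude screen
    rise, fall = int(0.06 * fs), int(0.25 * fs)
    width = rise + fall
    bump = np.concatenate([
        0.5 * (1 - np.cos(np.pi * np.arange(rise) / rise)),
        0.5 * (1 + np.cos(np.pi * np.arange(fall) / fall)),
    ])
    topo = np.array([_BLINK_FRONTAL.get(ch.rstrip("z0123456789"), 0.1) for ch in channels])
    n_blinks = rng.poisson(profile.blink_rate_hz * n_samples / fs)
    for _ in range(n_blinks):
        t0 = int(rng.integers(0, max(n_samples - width, 1)))
        amp = rng.lognormal(mean=np.log(300.0), sigma=0.55)  # µV at Fp
        data[:, t0 : t0 + width] += (amp * topo)[:, None] * bump[None, :]


def synthesize_trial(
    profile: SubjectProfile,
    code_indicator: np.ndarray,
    cfg: SessionConfig,
    position: str = "left",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One trial segment (channels × samples): deterministic evoked response
    plus, when ``cfg.noise``, fresh background noise from ``rng``."""
    drift, gains = _session_drift(
        profile, cfg, np.random.default_rng(cfg.rng_seed)
    )
    amp, lat = drift[position]
    evoked = _evoked_component(profile, position, cfg, code_indicator, amp, lat)
    topo = profile.topography(position, cfg.channels) * gains
    seg = topo[:, None] * evoked[None, :]
    if cfg.noise:
        rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
        seg = seg + _colored_noise(rng, len(cfg.channels), seg.shape[1], profile, cfg.fs)
    return seg


def synthesize_session(
    profile: SubjectProfile,
    schedule: StimulusSchedule,
    cfg: SessionConfig,
    code_set: CodeSet | None = None,
) -> RawRecording:
    """Render one continuous recording for a full MBCT session.

    Events carry the flicker-onset sample, ring position, and a correctness
    flag drawn at the profile's behavioural error rate (incorrect trials are
    later excluded by preprocessing, per the MBCT rule).
    """
    fs = cfg.fs
    rng = np.random.default_rng(cfg.rng_seed)
    code_set = code_set or build_code_set()
    indicators = {p: code_to_frame_train(code_set[p], FRAME_RATE, fs) for p in POSITIONS}
    drift, gains = _session_drift(profile, cfg, rng)
    topos = {p: profile.topography(p, cfg.channels) * gains for p in POSITIONS}
    # slow within-session modulation of the evoked response (phase and
    # magnitude drawn per session and position)
    slow = {
        p: (
            cfg.slow_latency_scale * profile.slow_latency_band_s
            * float(rng.uniform(0.75, 1.0)),
            cfg.slow_amplitude_scale * profile.slow_amplitude_band
            * float(rng.uniform(0.75, 1.0)),
            float(rng.uniform(0.5, 1.5)),
            float(rng.uniform(0, 2 * np.pi)),
        )
        for p in POSITIONS
    }
    n_trials = max(len(schedule.trials), 1)

    def trial_evoked(position: str, trial_index: int) -> np.ndarray:
        amp0, lat0 = drift[position]
        a_lat, a_amp, f_d, phi = slow[position]
        tau = trial_index / n_trials
        phase = np.sin(2 * np.pi * f_d * tau + phi)
        return _evoked_component(
            profile, position, cfg, indicators[position],
            amp_scale=amp0 * (1 + a_amp * phase),
            latency_shift_s=lat0 + a_lat * phase,
        )

    n_samples = int(np.ceil(schedule.duration * fs)) + int(2 * fs)
    n_ch = len(cfg.channels)
    if cfg.noise:
        data = _colored_noise(rng, n_ch, n_samples, profile, fs)
    else:
        data = np.zeros((n_ch, n_samples), dtype=np.float32)
    if cfg.noise and cfg.line_noise:
        t = np.arange(n_samples) / fs
        phase = rng.uniform(0, 2 * np.pi)
        data += (profile.line_amp_uv * np.sin(2 * np.pi * 50.0 * t + phase)).astype(
            np.float32
        )[None, :]
    if cfg.noise and cfg.blinks:
        _inject_blinks(data, cfg.channels, rng, profile, fs)

    events = []
    for trial in schedule.trials:
        onset = int(round(trial.onset_time * fs))
        pos = trial.ring_position
        wave = trial_evoked(pos, trial.trial_index)
        stop = min(onset + len(wave), n_samples)
        seg = (topos[pos][:, None] * wave[None, : stop - onset]).astype(np.float32)
        data[:, onset:stop] += seg
        correct = bool(rng.random() >= profile.behavioral_error_rate)
        events.append((onset, pos, correct))
    return RawRecording(
        data=data,
        fs=fs,
        channels=tuple(cfg.channels),
        events=tuple(events),
        subject_id=profile.subject_id,
        session_id=cfg.session_index,
    )


def write_recording(recording: RawRecording, path) -> None:
    """Write one recording to the compact array container (HDF5: named
    arrays ``data``, ``fs``, ``channels``, ``events``)."""
    import h5py
    import json

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data.astype(np.float32))
        f.create_dataset("fs", data=recording.fs)
        f.attrs["channels"] = json.dumps(list(recording.channels))
        f.attrs["subject_id"] = recording.subject_id
        f.attrs["session_id"] = recording.session_id
        ev = np.array(
            [(o, p, c) for o, p, c in recording.events],
            dtype=[("onset_sample", "i8"), ("position", "S8"), ("correct", "?")],
        )
        f.create_dataset("events", data=ev)


def read_recording(path) -> RawRecording:
    """Read a recording written by :func:`write_recording`."""
    import h5py
    import json

    with h5py.File(path, "r") as f:
        ev = f["events"][()]
        return RawRecording(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            channels=tuple(json.loads(f.attrs["channels"])),
            events=tuple(
                (int(r["onset_sample"]), r["position"].decode(), bool(r["correct"]))
                for r in ev
            ),
            subject_id=str(f.attrs["subject_id"]),
            session_id=int(f.attrs["session_id"]),
        )


def simulate_cohort(
    n_subjects: int = 17,
    rng_seed: int = 0,
    variability: float = 1.0,
    schedule: StimulusSchedule | None = None,
    cfg_template: SessionConfig | None = None,
    out_dir=None,
) -> list[CohortEntry]:
    """Simulate a two-session cohort: one enrollment and one verification
    recording per subject, reproducible from ``rng_seed``.

    Authentication needs impostors, so ``n_subjects >= 2``.  With
    ``out_dir`` the recordings are also written to the array container
    (one file per subject-session) next to a JSON event manifest.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects (genuine + impostor)")
    schedule = schedule or build_session_schedule()
    template = cfg_template or SessionConfig()
    ss = np.random.SeedSequence(rng_seed)
    entries = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        seeds = child.generate_state(3) % (2**31)
        profile = sample_subject_profile(
            int(seeds[0]), variability=variability, subject_id=f"S{i + 1:02d}"
        )
        rec1 = synthesize_session(
            profile, schedule, replace(template, session_index=1, rng_seed=int(seeds[1]))
        )
        rec2 = synthesize_session(
            profile, schedule, replace(template, session_index=2, rng_seed=int(seeds[2]))
        )
        entries.append(CohortEntry(profile=profile, session1=rec1, session2=rec2))
    if out_dir is not None:
        import json
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"rng_seed": rng_seed, "n_subjects": n_subjects,
                    "variability": variability, "recordings": []}
        for e in entries:
            for rec in (e.session1, e.session2):
                name = f"{rec.subject_id}_session{rec.session_id}.h5"
                write_recording(rec, out_dir / name)
                manifest["recordings"].append({
                    "file": name, "subject": rec.subject_id,
                    "session": rec.session_id,
                    "events": [[o, p, c] for o, p, c in rec.events],
                })
        (out_dir / "events.json").write_text(json.dumps(manifest))
    return entries
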