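"""Flicker-code generation and the MBCT session timeline.

The visual stimuli are modulated by maximal-length binary sequences
(m-sequences): the output of a linear-feedback shift register (LFSR) whose
feedback taps form a primitive polynomial over GF(2).  A degree-``n``
register cycles through all ``2^n - 1`` nonzero states, so the code has
period ``2^n - 1`` and near-ideal autocorrelation — the property that makes
c-VEP stimulation decodable.  At a 60 Hz refresh rate a 63-bit code
(degree 6) spans exactly 1.05 s; bit value 1 means the stimulus is lit for
that frame, 0 means dark.

A session of the mild-burdened cognitive task (MBCT) consists of four runs
of trials.  Each trial walks through cue (1 s), gaze (1.05 s, the flicker),
inquiry (up to 0.6 s, the behavioural response) and break (1 s) stages.
The first two runs present the ring left-vs-right, the last two
top-vs-bottom, with positions balanced within each run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MSequence",
    "CodeSet",
    "StimulusSchedule",
    "Trial",
    "PRIMITIVE_TAPS",
    "DEGREE6_PRIMITIVE_TAPS",
    "STAGE_DURATIONS",
    "FRAME_RATE",
    "generate_msequence",
    "build_code_set",
    "build_session_schedule",
    "code_to_frame_train",
]

FRAME_RATE = 60.0
"""Monitor refresh rate in Hz; one code bit per frame."""

STAGE_DURATIONS = {"cue": 1.0, "gaze": 63 / FRAME_RATE, "inquiry": 0.6, "break": 1.0}
"""MBCT stage durations in seconds.  The inquiry stage ends as soon as the
participant responds; for onset bookkeeping it is modelled at its 0.6 s cap."""

POSITIONS = ("left", "right", "top", "bottom")

#: One primitive-polynomial tap set per degree (taps are the exponents of the
#: nonzero feedback terms, excluding the constant term).  Used as defaults for
#: quick generation and for the balance property tests.
PRIMITIVE_TAPS: dict[int, tuple[int, ...]] = {
    2: (2, 1),
    3: (3, 2),
    4: (4, 3),
    5: (5, 3),
    6: (6, 5),
    7: (7, 6),
    8: (8, 6, 5, 4),
    9: (9, 5),
    10: (10, 7),
}

#: The six primitive polynomials of degree 6 over GF(2) (all of them), as
#: feedback tap sets.  Four distinct codes are drawn from this pool under the
#: ``distinct-polynomials`` strategy.
DEGREE6_PRIMITIVE_TAPS: tuple[tuple[int, ...], ...] = (
    (6, 1),
    (6, 5),
    (6, 5, 2, 1),
    (6, 4, 3, 1),
    (6, 5, 4, 1),
    (6, 5, 3, 2),
)


@dataclass(frozen=True)
class MSequence:
    """A full-period LFSR output.

    Parameters mirror the generating register: ``degree`` is the register
    length, ``taps`` the feedback positions (exponents of the primitive
    polynomial), ``seed`` the initial register state (most significant stage
    first), and ``bits`` the emitted 0/1 sequence of length ``2**degree - 1``.
    """

    degree: int
    taps: tuple[int, ...]
    seed: tuple[int, ...]
    bits: np.ndarray

    def __len__(self) -> int:
        return len(self.bits)

    def rotated(self, shift: int) -> "MSequence":
        """Return a copy with ``bits`` circularly rotated left by ``shift``."""
        return MSequence(self.degree, self.taps, self.seed, np.roll(self.bits, -shift))

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "taps": list(self.taps),
            "seed": list(self.seed),
            "bits": self.bits.astype(int).tolist(),
        }


@dataclass(frozen=True)
class CodeSet:
    """Four flicker codes keyed by ring position; pairwise distinct."""

    codes: dict[str, MSequence]

    def __post_init__(self) -> None:
        if set(self.codes) != set(POSITIONS):
            raise ValueError(f"code set must cover positions {POSITIONS}")
        bits = [tuple(self.codes[p].bits.tolist()) for p in POSITIONS]
        if len(set(bits)) != 4:
            raise ValueError("the four position codes must be pairwise distinct")

    def __getitem__(self, position: str) -> MSequence:
        return self.codes[position]

    def to_json(self) -> str:
        return json.dumps({p: c.to_dict() for p, c in self.codes.items()})


@dataclass(frozen=True)
class Trial:
    trial_index: int
    run_index: int
    mode: Literal["L-R", "T-B"]
    ring_position: str
    onset_time: float  # gaze-stage (flicker) onset, seconds from session start
    code_id: str


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered MBCT trial timeline for one session."""

    trials: tuple[Trial, ...]
    frame_rate: float = FRAME_RATE
    stage_durations: dict = field(default_factory=lambda: dict(STAGE_DURATIONS))

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def duration(self) -> float:
        """Total session duration in seconds (end of the last break stage)."""
        per_trial = sum(self.stage_durations.values())
        last = self.trials[-1]
        return last.onset_time - self.stage_durations["cue"] + per_trial

    def position_counts(self) -> dict[str, int]:
        counts = {p: 0 for p in POSITIONS}
        for t in self.trials:
            counts[t.ring_position] += 1
        return counts

    def to_json(self) -> str:
        return json.dumps(
            {
                "frame_rate": self.frame_rate,
                "stage_durations": self.stage_durations,
                "trials": [asdict(t) for t in self.trials],
            }
        )


def _lfsr_period(degree: int, taps: Sequence[int], seed: Sequence[int]) -> tuple[np.ndarray, int]:
    """Run a Fibonacci LFSR until the state recurs; return (bits, period)."""
    taps = tuple(sorted(set(int(t) for t in taps), reverse=True))
    state = tuple(int(b) & 1 for b in seed)
    full = 2**degree - 1
    bits = []
    seen_start = state
    for step in range(full + 1):
        # output the last stage; feedback = XOR of tapped stages.
        bits.append(state[-1])
        fb = 0
        for t in taps:
            fb ^= state[t - 1]
        state = (fb,) + state[:-1]
        if state == seen_start:
            return np.array(bits[: step + 1], dtype=np.uint8), step + 1
    raise RuntimeError("LFSR did not recur within the full period bound")  # pragma: no cover


def generate_msequence(
    degree: int, taps: Sequence[int] | None = None, seed: Sequence[int] | None = None
) -> MSequence:
    """Generate a maximal-length sequence from an LFSR specification.

    Parameters
    ----------
    degree
        Register length ``n >= 2``; the sequence has period ``2**n - 1``.
    taps
        Feedback tap positions (exponents of the primitive polynomial,
        e.g. ``(6, 5)`` for ``x^6 + x^5 + 1``).  Defaults to a built-in
        primitive polynomial for the degree.
    seed
        Initial register state, any nonzero 0/1 vector of length ``degree``.
        Defaults to all ones.

    Raises
    ------
    ValueError
        If the seed is all-zero, or the taps are not primitive (observed
        period < ``2**degree - 1``; the diagnostic reports the period).
    """
    if degree < 2:
        raise ValueError(f"degree must be >= 2, got {degree}")
    if taps is None:
        taps = PRIMITIVE_TAPS[degree]
    taps = tuple(sorted(set(int(t) for t in taps), reverse=True))
    if max(taps) != degree or min(taps) < 1:
        raise ValueError(f"taps {taps} must lie in 1..{degree} and include {degree}")
    if seed is None:
        seed = (1,) * degree
    seed = tuple(int(b) & 1 for b in seed)
    if len(seed) != degree:
        raise ValueError(f"seed length {len(seed)} != degree {degree}")
    if not any(seed):
        raise ValueError("all-zero seed is a fixed point of the LFSR; use a nonzero seed")
    bits, period = _lfsr_period(degree, taps, seed)
    full = 2**degree - 1
    if period != full:
        raise ValueError(
            f"taps {taps} are not primitive for degree {degree}: "
            f"observed period {period} < {full}"
        )
    return MSequence(degree=degree, taps=taps, seed=seed, bits=bits)


def build_code_set(
    strategy: Literal["distinct-polynomials", "circular-shifts"] = "distinct-polynomials",
    shift_step: int = 16,
    rng_seed: int | None = None,
    degree: int = 6,
) -> CodeSet:
    """Build the four position codes used by the flicker stimuli.

    ``distinct-polynomials`` (default) draws one m-sequence from each of four
    distinct primitive polynomials.  ``circular-shifts`` rotates a single
    m-sequence by ``0, shift_step, 2*shift_step, 3*shift_step`` bits — the
    classic time-shifted c-VEP layout.  ``rng_seed`` shuffles which
    polynomials (or base rotation) are used; ``None`` keeps the canonical
    assignment.
    """
    if degree == 6:
        pool = list(DEGREE6_PRIMITIVE_TAPS)
    else:
        pool = [PRIMITIVE_TAPS[degree]]
    length = 2**degree - 1
    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None

    if strategy == "distinct-polynomials":
        if len(pool) < 4:
            raise ValueError(
                f"need 4 distinct primitive polynomials of degree {degree}; "
                f"pool has {len(pool)}"
            )
        idx = list(range(len(pool)))
        if rng is not None:
            rng.shuffle(idx)
        chosen = [pool[i] for i in idx[:4]]
        codes = {p: generate_msequence(degree, taps) for p, taps in zip(POSITIONS, chosen)}
    elif strategy == "circular-shifts":
        shifts = [(i * shift_step) % length for i in range(4)]
        if len(set(shifts)) != 4:
            raise ValueError(
                f"shift_step={shift_step} collides modulo the code length "
                f"{length}: rotations {shifts} are not pairwise distinct"
            )
        base = generate_msequence(degree, pool[0])
        offset = int(rng.integers(length)) if rng is not None else 0
        codes = {
            p: base.rotated((offset + i * shift_step) % length)
            for i, p in enumerate(POSITIONS)
        }
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return CodeSet(codes=codes)


def build_session_schedule(
    n_runs: int = 4,
    trials_per_run: int = 100,
    rng_seed: int | None = 0,
) -> StimulusSchedule:
    """Lay out one MBCT session: runs 1–2 left/right, runs 3–4 top/bottom.

    Within each run the two positions occur equally often, in an order
    shuffled by ``rng_seed`` (deterministic for a fixed seed).  Onset times
    are the gaze-stage (flicker) onsets, spaced by the summed stage
    durations; runs follow each other back to back.
    """
    if trials_per_run % 2:
        raise ValueError(
            f"trials_per_run must be even for position balance, got {trials_per_run}"
        )
    rng = np.random.default_rng(rng_seed)
    per_trial = sum(STAGE_DURATIONS.values())
    trials: list[Trial] = []
    t = 0.0
    index = 0
    for run in range(n_runs):
        mode = "L-R" if run < n_runs / 2 else "T-B"
        pair = ("left", "right") if mode == "L-R" else ("top", "bottom")
        order = np.array([pair[0]] * (trials_per_run // 2) + [pair[1]] * (trials_per_run // 2))
        rng.shuffle(order)
        for pos in order:
            trials.append(
                Trial(
                    trial_index=index,
                    run_index=run,
                    mode=mode,
                    ring_position=str(pos),
                    onset_time=t + STAGE_DURATIONS["cue"],
                    code_id=str(pos),
                )
            )
            t += per_trial
            index += 1
    return StimulusSchedule(trials=tuple(trials))


def code_to_frame_train(
    code: MSequence | np.ndarray, frame_rate: float = FRAME_RATE, fs: float = 1000.0
) -> np.ndarray:
    """Expand a flicker code into an on/off indicator sampled at ``fs``.

    Each bit occupies one monitor frame.  Because ``fs / frame_rate`` is in
    general non-integer (1000/60 ≈ 16.67), bit edges are placed at the
    rounded exact edge times ``round(i * fs / frame_rate)`` (accumulated
    phase), so individual bits span 16 or 17 samples and the 63-bit code
    spans exactly ``round(63 * fs / 60) = 1050`` samples.
    """
    if fs < frame_rate:
        raise ValueError(f"fs={fs} must be >= frame_rate={frame_rate}")
    bits = code.bits if isinstance(code, MSequence) else np.asarray(code)
    n_bits = len(bits)
    edges = np.round(np.arange(n_bits + 1) * fs / frame_rate).astype(int)
    out = np.zeros(edges[-1], dtype=np.float64)
    for i, b in enumerate(bits):
        if b:
            out[edges[i] : edges[i + 1]] = 1.0
    return out
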