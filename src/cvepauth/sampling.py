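"""Epoch averaging and sample composition for verification.

A verification *sample* is a quadruple of one left, one right, one top and
one bottom epoch from the same subject and session.  To control SNR, the
epochs entering samples are N-point sliding-window averages of the original
per-class epoch streams (window length N, step 1), so M original epochs
yield M − N + 1 averaged epochs per class.  With 100 originals per class at
N = 1 the quadruple space has 100⁴ = 10⁸ elements; samples are drawn from
it uniformly without repeating a full quadruple (individual averaged epochs
may recur across samples).

A *training packet* for a claimed subject is a balanced labeled set:
positives composed from the claimed subject's enrollment session, negatives
composed from every other subject in equal shares (1600 + 16 × 100 at the
17-subject defaults).  Test sets are built the same way from the second
session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Sample",
    "TrainingPacket",
    "sliding_average",
    "sample_space_size",
    "compose_samples",
    "build_training_packet",
    "build_test_set",
    "acquisition_stimulus_time",
    "POSITIONS",
]

POSITIONS = ("left", "right", "top", "bottom")


@dataclass(frozen=True)
class Sample:
    """One four-position quadruple: array of shape (4, channels, time) in the
    fixed order left, right, top, bottom."""

    data: np.ndarray
    genuine: bool
    source_subject: str
    n_avg: int

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[0] != 4:
            raise ValueError(f"sample must be (4, C, T); got {self.data.shape}")


@dataclass
class TrainingPacket:
    """Balanced genuine/impostor training material for one claimed identity."""

    claimed_subject: str
    X: np.ndarray  # (n, 4, C, T) float32
    y: np.ndarray  # (n,) 1 = genuine, 0 = impostor
    n_avg: int
    rng_seed: int
    impostor_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.y)


def sliding_average(class_epochs: np.ndarray | Sequence[np.ndarray], n_avg: int) -> np.ndarray:
    """Average epochs in a length-``n_avg``, step-1 sliding window.

    ``class_epochs`` is ``(M, C, T)`` in trial order (same class, subject and
    session); the result is ``(M - n_avg + 1, C, T)``.
    """
    X = np.asarray(class_epochs)
    M = X.shape[0]
    if not 1 <= n_avg <= M:
        raise ValueError(f"n_avg={n_avg} outside 1..{M}")
    if n_avg == 1:
        return X.copy()
    c = np.cumsum(X, axis=0, dtype=np.float64)
    c = np.concatenate([np.zeros((1,) + X.shape[1:]), c], axis=0)
    return ((c[n_avg:] - c[:-n_avg]) / n_avg).astype(X.dtype)


def sample_space_size(pools: Mapping[str, np.ndarray]) -> int:
    """Number of distinct quadruples composable from per-position pools."""
    size = 1
    for pos in POSITIONS:
        size *= len(pools[pos])
    return size


def compose_samples(
    pools: Mapping[str, np.ndarray],
    count: int,
    rng_seed: int,
    genuine: bool = True,
    source_subject: str = "",
    n_avg: int = 1,
) -> list[Sample]:
    """Draw ``count`` distinct quadruples uniformly from the product space.

    Distinctness is at the quadruple level: the same averaged epoch may
    appear in many samples, but no full (left, right, top, bottom) index
    combination repeats.  Deterministic in ``rng_seed``.
    """
    for pos in POSITIONS:
        if pos not in pools or len(pools[pos]) == 0:
            raise ValueError(f"pool for position {pos!r} is empty")
    sizes = np.array([len(pools[p]) for p in POSITIONS], dtype=np.int64)
    space = int(np.prod(sizes))
    if count > space:
        raise ValueError(f"requested {count} samples but only {space} quadruples exist")
    rng = np.random.default_rng(rng_seed)
    if space <= 4 * count:
        flat = rng.choice(space, size=count, replace=False)
    else:
        chosen: set[int] = set()
        while len(chosen) < count:
            draw = rng.integers(0, space, size=2 * (count - len(chosen)))
            for v in draw:
                chosen.add(int(v))
                if len(chosen) == count:
                    break
        flat = np.array(sorted(chosen), dtype=np.int64)
        rng.shuffle(flat)
    idx = np.array(np.unravel_index(flat, sizes), dtype=np.int64).T
    samples = []
    for quad in idx:
        data = np.stack([pools[p][quad[k]] for k, p in enumerate(POSITIONS)])
        samples.append(
            Sample(
                data=data.astype(np.float32),
                genuine=genuine,
                source_subject=source_subject,
                n_avg=n_avg,
            )
        )
    return samples


def _averaged_pools(
    epochs_by_position: Mapping[str, np.ndarray], n_avg: int
) -> dict[str, np.ndarray]:
    return {p: sliding_average(epochs_by_position[p], n_avg) for p in POSITIONS}


def build_training_packet(
    claimed_subject: str,
    cohort_epochs: Mapping[str, Mapping[str, np.ndarray]],
    n_avg: int = 20,
    n_pos: int = 1600,
    n_neg_per_impostor: int = 100,
    rng_seed: int = 0,
    auto_balance: bool = False,
) -> TrainingPacket:
    """Compose the balanced enrollment packet for one claimed identity.

    ``cohort_epochs`` maps subject → position → ``(M, C, T)`` session-1
    epochs.  Positives come from the claimed subject; negatives are drawn in
    equal shares from every other subject (``n_neg_per_impostor`` each, the
    17-subject default being 16 × 100 against 1600 positives).  With
    ``auto_balance`` the per-impostor share is rescaled to
    ``ceil(n_pos / n_impostors)`` so smaller cohorts still yield a balanced
    packet; without it a mismatched total is an error.
    """
    others = [s for s in cohort_epochs if s != claimed_subject]
    if claimed_subject not in cohort_epochs or not others:
        raise ValueError("cohort must contain the claimed subject and >= 1 impostor")
    if n_neg_per_impostor * len(others) != n_pos:
        if not auto_balance:
            raise ValueError(
                f"{len(others)} impostors x {n_neg_per_impostor} != {n_pos} positives; "
                "set auto_balance=True to rescale the per-impostor share"
            )
        n_neg_per_impostor = int(np.ceil(n_pos / len(others)))
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(1 + len(others)) % (2**31)
    pos_pools = _averaged_pools(cohort_epochs[claimed_subject], n_avg)
    positives = compose_samples(
        pos_pools, n_pos, int(seeds[0]), genuine=True,
        source_subject=claimed_subject, n_avg=n_avg,
    )
    negatives: list[Sample] = []
    impostor_counts: dict[str, int] = {}
    for k, sub in enumerate(others):
        need = min(n_neg_per_impostor, n_pos - len(negatives))
        if need <= 0:
            break
        neg_pools = _averaged_pools(cohort_epochs[sub], n_avg)
        negatives.extend(
            compose_samples(
                neg_pools, need, int(seeds[1 + k]), genuine=False,
                source_subject=sub, n_avg=n_avg,
            )
        )
        impostor_counts[sub] = need
    X = np.stack([s.data for s in positives + negatives]).astype(np.float32)
    y = np.array([1] * len(positives) + [0] * len(negatives), dtype=np.int64)
    return TrainingPacket(
        claimed_subject=claimed_subject, X=X, y=y, n_avg=n_avg,
        rng_seed=rng_seed, impostor_counts=impostor_counts,
    )


def build_test_set(
    claimed_subject: str,
    cohort_epochs: Mapping[str, Mapping[str, np.ndarray]],
    n_avg: int = 20,
    n_pos: int = 100,
    n_neg: int = 100,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Compose the verification-session sample set for one claimed identity.

    Same composition procedure as the training packet, applied to the
    held-out session: ``n_pos`` genuine quadruples plus ``n_neg`` impostor
    quadruples spread as evenly as possible over the other subjects.
    Returns ``(X, y)`` with X of shape ``(n, 4, C, T)``.
    """
    others = [s for s in cohort_epochs if s != claimed_subject]
    if claimed_subject not in cohort_epochs or not others:
        raise ValueError("cohort must contain the claimed subject and >= 1 impostor")
    if n_neg == 0:
        warnings.warn("test set has no impostor samples; metrics will be degenerate")
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(1 + len(others)) % (2**31)
    samples = compose_samples(
        _averaged_pools(cohort_epochs[claimed_subject], n_avg),
        n_pos, int(seeds[0]), genuine=True, source_subject=claimed_subject, n_avg=n_avg,
    )
    shares = [n_neg // len(others)] * len(others)
    for k in range(n_neg - sum(shares)):
        shares[k] += 1
    for k, (sub, share) in enumerate(zip(others, shares)):
        if share == 0:
            continue
        samples.extend(
            compose_samples(
                _averaged_pools(cohort_epochs[sub], n_avg),
                share, int(seeds[1 + k]), genuine=False, source_subject=sub, n_avg=n_avg,
            )
        )
    X = np.stack([s.data for s in samples]).astype(np.float32)
    y = np.array([1 if s.genuine else 0 for s in samples], dtype=np.int64)
    return X, y


def acquisition_stimulus_time(n_avg: int, n_positions: int = 4, flash_s: float = 63 / 60) -> float:
    """Stimulus (flicker) time needed to collect one N-averaged sample:
    ``n_avg`` epochs for each of the four positions at 1.05 s of flashing
    per epoch — 46.2 s for the practical N = 11 operating point."""
    return n_avg * n_positions * flash_s
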