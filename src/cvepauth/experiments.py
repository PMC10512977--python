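"""Metrics, paired statistics, and the three study designs.

The studies mirror the published protocol on a synthetic cohort:

* **method comparison** — per subject, train a c-EEGNet and a TRCA model on
  enrollment (session-1) packets and verify both on session-2 sample sets;
  tabulate accuracy / precision / recall / F1 per subject and compare the
  two methods with Wilcoxon signed-rank tests;
* **SNR sweep** — repeat verification while varying N, the number of
  original epochs averaged per sample;
* **brain-area comparison** — repeat verification on the frontal, parietal,
  occipital and parieto-occipital channel subsets.

All drivers are deterministic given their seed: a manifest of seeds and
configuration reproduces every number in every report.  Default problem
sizes (cohort size, packet size, training epochs) are scaled for a
single-CPU workstation run; the full published protocol sizes remain
available through the function arguments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import preprocess, sampling, simulate
from .models import (
    CEEGNet,
    CEEGNetConfig,
    TrainConfig,
    train_ceegnet,
    trca_calibrate_threshold,
    trca_fit,
    trca_scores,
)
from .preprocess import CHANNEL_SUBSETS
from .sampling import POSITIONS, build_test_set, build_training_packet
from .stimulus import build_session_schedule

__all__ = [
    "MetricsReport",
    "PairedTestResult",
    "CohortEpochs",
    "compute_metrics",
    "round_half_up",
    "wilcoxon_signed_rank",
    "prepare_cohort_epochs",
    "run_method_comparison",
    "run_snr_sweep",
    "run_area_comparison",
    "PUBLISHED_BENCHMARK_17",
    "AREA_UNION_CHANNELS",
]

logger = logging.getLogger("cvepauth.experiments")

METRICS = ("accuracy", "precision", "recall", "f1")

#: Channels needed to run every named area subset from one simulation.
AREA_UNION_CHANNELS: tuple[str, ...] = (
    "F1", "Fz", "F2", "P1", "Pz", "P2",
    "PO5", "PO3", "POz", "PO4", "PO6", "O1", "Oz", "O2",
)

#: Published per-participant verification metrics of a 17-subject c-VEP
#: authentication benchmark (enrollment and verification on different days,
#: N = 20 averaged epochs; TRCA baseline vs the c-EEGNet deep model).
#: Row order is participant 1..17; used as reference input for metric and
#: paired-test arithmetic checks.
PUBLISHED_BENCHMARK_17: dict[str, dict[str, tuple[float, ...]]] = {
    "trca": {
        "accuracy": (0.8, 0.81, 0.85, 0.81, 0.88, 0.44, 0.88, 0.76, 0.83,
                     0.58, 0.9, 0.71, 0.83, 0.61, 0.88, 0.78, 0.83),
        "precision": (1, 1, 1, 1, 0.99, 0.46, 1, 0.77, 1, 0.57, 0.98, 0.72,
                      1, 0.6, 0.98, 0.8, 1),
        "recall": (0.6, 0.62, 0.71, 0.62, 0.77, 0.75, 0.76, 0.76, 0.67,
                   0.66, 0.81, 0.70, 0.66, 0.67, 0.78, 0.76, 0.66),
        "f1": (0.75, 0.77, 0.83, 0.76, 0.87, 0.57, 0.86, 0.76, 0.80, 0.61,
               0.89, 0.71, 0.79, 0.63, 0.87, 0.78, 0.79),
    },
    "ceegnet": {
        "accuracy": (0.98, 0.98, 0.97, 0.99, 0.99, 0.93, 0.99, 0.9, 0.75,
                     0.74, 0.99, 0.78, 0.99, 0.96, 0.99, 0.67, 0.99),
        "precision": (1, 1, 1, 0.99, 0.99, 1, 0.99, 1, 0.99, 0.97, 0.99, 1,
                      0.99, 0.93, 0.99, 1, 1),
        "recall": (0.97, 0.97, 0.94, 0.98, 1, 0.86, 0.99, 0.8, 0.51, 0.49,
                   1, 0.57, 1, 1, 0.99, 0.34, 0.98),
        "f1": (0.98, 0.98, 0.97, 0.99, 0.99, 0.92, 0.99, 0.89, 0.67, 0.65,
               0.99, 0.73, 0.99, 0.96, 0.99, 0.51, 0.98),
    },
}


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the four verification ratios.

    ``genuine`` is the positive class.  A ratio with a zero denominator is
    reported as 0 and listed in ``undefined``.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return asdict(self)

    def rounded(self, ndigits: int = 2) -> dict:
        return {m: round_half_up(getattr(self, m), ndigits) for m in METRICS}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Table-style rounding: half away from zero (0.775 -> 0.78)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def compute_metrics(decisions: Sequence, labels: Sequence) -> MetricsReport:
    """Confusion-matrix metrics for accept/reject decisions.

    ``decisions`` and ``labels`` accept booleans/0-1 integers or the strings
    ``accept``/``reject`` and ``genuine``/``impostor``.
    """
    def to_bool(v, true_words=("accept", "genuine", "1", "true")):
        if isinstance(v, str):
            return v.lower() in true_words
        return bool(v)

    dec = np.array([to_bool(d) for d in decisions])
    lab = np.array([to_bool(l) for l in labels])
    if len(dec) == 0 or len(dec) != len(lab):
        raise ValueError("decisions and labels must be equal-length and nonempty")
    tp = int((dec & lab).sum())
    fp = int((dec & ~lab).sum())
    fn = int((~dec & lab).sum())
    tn = int((~dec & ~lab).sum())
    undefined: list[str] = []
    accuracy = (tp + tn) / len(dec)
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        precision = 0.0
        undefined.append("precision")
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        recall = 0.0
        undefined.append("recall")
    if precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        undefined.append("f1")
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn, accuracy=accuracy,
                         precision=precision, recall=recall, f1=f1,
                         undefined=tuple(undefined))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    """Normal-approximation Wilcoxon signed-rank result.

    ``z`` uses the tie-corrected variance without continuity correction;
    ``exact_p`` (enumeration over all sign assignments) is filled for
    n <= 10 pairs.  Zero differences are dropped (``n`` counts the pairs
    used).
    """

    z: float
    p: float
    n: int
    w_plus: float
    tie_counts: tuple[int, ...] = ()
    exact_p: float | None = None
    degenerate: bool = False


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank test of ``a`` vs ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 5:
        raise ValueError("need equal-length 1-D inputs with >= 5 pairs")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return PairedTestResult(z=0.0, p=1.0, n=0, w_plus=0.0, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (counts**3 - counts).sum() / 48
    if var <= 0:
        return PairedTestResult(z=0.0, p=1.0, n=n, w_plus=w_plus,
                                tie_counts=tuple(int(c) for c in counts),
                                degenerate=True)
    z = (w_plus - mu) / np.sqrt(var)
    p = float(min(2 * stats.norm.sf(abs(z)), 1.0))
    exact_p = _exact_signed_rank_p(ranks, w_plus, mu) if n <= 10 else None
    return PairedTestResult(z=float(z), p=p, n=n, w_plus=w_plus,
                            tie_counts=tuple(int(c) for c in counts),
                            exact_p=exact_p)


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float, mu: float) -> float:
    """Two-sided exact p: fraction of sign assignments whose positive-rank
    sum is at least as far from its mean as the observed one."""
    n = len(ranks)
    extreme = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(np.dot(signs, ranks))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            extreme += 1
    return extreme / 2**n


# ---------------------------------------------------------------------------
# Cohort preparation
# ---------------------------------------------------------------------------

@dataclass
class CohortEpochs:
    """Preprocessed per-subject, per-session, per-position epochs.

    ``epochs[subject][session][position]`` is ``(M, C, T)`` (baseline-
    corrected, downsampled, channel axis ordered as ``channels``) *before*
    amplitude rejection; ``peaks[...]`` holds each epoch's per-channel
    absolute maximum at the full sampling rate.  Rejection is applied in
    :meth:`session_view`, so restricting to a channel subset reproduces the
    chain as if only those channels had been recorded — a frontal blink
    must not delete an occipital-only epoch.
    """

    epochs: dict[str, dict[int, dict[str, np.ndarray]]]
    peaks: dict[str, dict[int, dict[str, np.ndarray]]]
    channels: tuple[str, ...]
    reject_uv: float = preprocess.REJECT_UV
    manifest: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return list(self.epochs)

    def session_view(self, session: int, channels: Sequence[str] | str | None = None
                     ) -> dict[str, dict[str, np.ndarray]]:
        """subject -> position -> (M', C', T) for one session and channel
        subset, with the amplitude-rejection rule evaluated on that subset."""
        if channels is None:
            idx = list(range(len(self.channels)))
        else:
            names = CHANNEL_SUBSETS[channels] if isinstance(channels, str) else tuple(channels)
            missing = [c for c in names if c not in self.channels]
            if missing:
                raise KeyError(f"channels {missing} not simulated in this cohort")
            idx = [self.channels.index(c) for c in names]
        out: dict[str, dict[str, np.ndarray]] = {}
        for sub, sessions in self.epochs.items():
            out[sub] = {}
            for pos, arr in sessions[session].items():
                keep = self.peaks[sub][session][pos][:, idx].max(axis=1) <= self.reject_uv
                out[sub][pos] = arr[keep][:, idx]
        return out


def prepare_cohort_epochs(
    n_subjects: int = 8,
    rng_seed: int = 0,
    trials_per_run: int = 100,
    channels: Sequence[str] = AREA_UNION_CHANNELS,
    variability: float = 1.0,
) -> CohortEpochs:
    """Simulate a two-session cohort and run the preprocessing chain.

    Recordings are simulated subject by subject on the requested channel
    subset (filtering is per-channel, so restricting the montage before
    filtering is exact) and immediately reduced to epochs to bound memory.
    Amplitude rejection is deferred to :meth:`CohortEpochs.session_view`
    (see there); all other stages run in the standard order.
    """
    schedule = build_session_schedule(trials_per_run=trials_per_run, rng_seed=rng_seed)
    ss = np.random.SeedSequence(rng_seed)
    epochs: dict[str, dict[int, dict[str, np.ndarray]]] = {}
    peaks: dict[str, dict[int, dict[str, np.ndarray]]] = {}
    for i, child in enumerate(ss.spawn(n_subjects)):
        seeds = child.generate_state(3) % (2**31)
        profile = simulate.sample_subject_profile(
            int(seeds[0]), variability=variability, subject_id=f"S{i + 1:02d}"
        )
        epochs[profile.subject_id] = {}
        peaks[profile.subject_id] = {}
        for session in (1, 2):
            cfg = simulate.SessionConfig(
                channels=tuple(channels), session_index=session,
                rng_seed=int(seeds[session]),
            )
            rec = simulate.synthesize_session(profile, schedule, cfg)
            rec = preprocess.bandpass_5_86(preprocess.notch_50(rec))
            es = preprocess.extract_epochs(rec)
            del rec
            pk = {"left": [], "right": [], "top": [], "bottom": []}
            for e in es:
                pk[e.position].append(np.abs(e.data).max(axis=-1))
            es = preprocess.downsample_avg4(preprocess.baseline_correct(es))
            epochs[profile.subject_id][session] = {
                pos: arr.astype(np.float32) for pos, arr in es.by_position().items()
            }
            peaks[profile.subject_id][session] = {
                pos: np.array(v, dtype=np.float32) for pos, v in pk.items() if v
            }
    manifest = {
        "n_subjects": n_subjects, "rng_seed": rng_seed,
        "trials_per_run": trials_per_run, "channels": list(channels),
        "variability": variability,
    }
    return CohortEpochs(epochs=epochs, peaks=peaks, channels=tuple(channels),
                        manifest=manifest)


# ---------------------------------------------------------------------------
# Study drivers
# ---------------------------------------------------------------------------

#: Scaled study defaults: packet/test sizes and training settings chosen so
#: a full comparison + sweep + area study completes on one CPU core.
DEFAULT_N_POS = 128
DEFAULT_TEST_SIZE = (100, 100)
DEFAULT_TRAIN_CONFIG = TrainConfig(max_epochs=12, patience=4)


def _subject_seeds(rng_seed: int, subjects: Sequence[str]) -> dict[str, np.ndarray]:
    ss = np.random.SeedSequence(rng_seed)
    return {
        sub: child.generate_state(4) % (2**31)
        for sub, child in zip(subjects, ss.spawn(len(subjects)))
    }


def _evaluate_subject(
    claimed: str,
    train_view: Mapping[str, Mapping[str, np.ndarray]],
    test_view: Mapping[str, Mapping[str, np.ndarray]],
    n_avg: int,
    seeds: np.ndarray,
    methods: Sequence[str],
    n_pos: int,
    test_size: tuple[int, int],
    train_config: TrainConfig,
) -> dict[str, MetricsReport]:
    packet = build_training_packet(
        claimed, train_view, n_avg=n_avg, n_pos=n_pos,
        rng_seed=int(seeds[0]), auto_balance=True,
    )
    X_test, y_test = build_test_set(
        claimed, test_view, n_avg=n_avg, n_pos=test_size[0], n_neg=test_size[1],
        rng_seed=int(seeds[1]),
    )
    out: dict[str, MetricsReport] = {}
    for method in methods:
        if method == "ceegnet":
            n_ch = packet.X.shape[2]
            cfg = CEEGNetConfig(n_channels=n_ch, n_times=packet.X.shape[3])
            model = CEEGNet(cfg, rng_seed=int(seeds[2]))
            tc = TrainConfig(**{**asdict(train_config), "rng_seed": int(seeds[2])})
            train_ceegnet(model, packet, tc)
            decisions = model.predict_proba(X_test)[:, 1] >= 0.5
        elif method == "trca":
            model = trca_fit(train_view[claimed])
            trca_calibrate_threshold(model, packet.X, packet.y, rng_seed=int(seeds[3]))
            decisions = trca_scores(model, X_test) >= model.theta
        else:
            raise ValueError(f"unknown method {method!r}")
        out[method] = compute_metrics(decisions, y_test)
    return out


def _tabulate(results: Mapping[str, Mapping[str, MetricsReport]]) -> pd.DataFrame:
    rows = []
    for sub, by_method in results.items():
        for method, rep in by_method.items():
            rows.append({"subject": sub, "method": method, **{m: getattr(rep, m) for m in METRICS}})
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    table: pd.DataFrame
    means: dict[str, dict[str, float]]
    paired_tests: dict[str, PairedTestResult]
    manifest: dict


def run_method_comparison(
    cohort: CohortEpochs,
    n_avg: int = 20,
    rng_seed: int = 0,
    channels: str | Sequence[str] = "PO9",
    n_pos: int = DEFAULT_N_POS,
    test_size: tuple[int, int] = DEFAULT_TEST_SIZE,
    train_config: TrainConfig = DEFAULT_TRAIN_CONFIG,
    methods: Sequence[str] = ("ceegnet", "trca"),
) -> ComparisonResult:
    """Verify every cohort subject with both back-ends and compare them.

    Models are trained on session-1 packets and evaluated on session-2
    sample sets; paired Wilcoxon tests compare the methods on all four
    metrics across subjects.
    """
    train_view = cohort.session_view(1, channels)
    test_view = cohort.session_view(2, channels)
    seeds = _subject_seeds(rng_seed, cohort.subjects)
    results = {}
    for sub in cohort.subjects:
        results[sub] = _evaluate_subject(
            sub, train_view, test_view, n_avg, seeds[sub], methods,
            n_pos, test_size, train_config,
        )
        logger.info("method comparison %s: %s", sub,
                    {m: round_half_up(r.accuracy) for m, r in results[sub].items()})
    table = _tabulate(results)
    means = {
        method: {m: float(table[table.method == method][m].mean()) for m in METRICS}
        for method in methods
    }
    paired = {}
    if len(methods) == 2 and len(cohort.subjects) >= 5:
        a, b = methods
        for m in METRICS:
            paired[m] = wilcoxon_signed_rank(
                table[table.method == a].sort_values("subject")[m].to_numpy(),
                table[table.method == b].sort_values("subject")[m].to_numpy(),
            )
    manifest = {
        "cohort": cohort.manifest, "n_avg": n_avg, "rng_seed": rng_seed,
        "channels": channels if isinstance(channels, str) else list(channels),
        "n_pos": n_pos, "test_size": list(test_size),
        "train_config": asdict(train_config), "methods": list(methods),
        "n_comparisons": len(paired),
    }
    return ComparisonResult(table=table, means=means, paired_tests=paired, manifest=manifest)


@dataclass
class SweepResult:
    table: pd.DataFrame  # one row per (n_avg, metric means)
    f1_rank_correlation: float
    manifest: dict


def run_snr_sweep(
    cohort: CohortEpochs,
    n_values: Sequence[int] = (1, 2, 4, 8, 11, 20),
    rng_seed: int = 0,
    channels: str | Sequence[str] = "PO9",
    method: str = "ceegnet",
    n_pos: int = DEFAULT_N_POS,
    test_size: tuple[int, int] = DEFAULT_TEST_SIZE,
    train_config: TrainConfig = DEFAULT_TRAIN_CONFIG,
) -> SweepResult:
    """Verification performance as a function of N, the number of original
    epochs averaged per sample.  Reports per-N cohort means and the
    Spearman rank correlation of mean F1 against N."""
    train_view = cohort.session_view(1, channels)
    test_view = cohort.session_view(2, channels)
    max_m = min(
        arr.shape[0] for views in (train_view, test_view)
        for sub in views.values() for arr in sub.values()
    )
    rows = []
    for n_avg in n_values:
        if n_avg > max_m:
            logger.warning("skipping N=%d: only %d epochs available", n_avg, max_m)
            continue
        seeds = _subject_seeds(rng_seed + n_avg, cohort.subjects)
        per_subject = []
        for sub in cohort.subjects:
            rep = _evaluate_subject(
                sub, train_view, test_view, n_avg, seeds[sub], (method,),
                n_pos, test_size, train_config,
            )[method]
            per_subject.append(rep)
        rows.append({
            "n_avg": n_avg,
            **{m: float(np.mean([getattr(r, m) for r in per_subject])) for m in METRICS},
        })
        logger.info("sweep N=%d: %s", n_avg,
                    {m: round_half_up(rows[-1][m]) for m in METRICS})
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        rho = float(stats.spearmanr(table["n_avg"], table["f1"]).statistic)
    else:
        rho = float("nan")
    manifest = {
        "cohort": cohort.manifest, "n_values": list(n_values), "rng_seed": rng_seed,
        "channels": channels if isinstance(channels, str) else list(channels),
        "method": method, "n_pos": n_pos, "test_size": list(test_size),
        "train_config": asdict(train_config),
    }
    return SweepResult(table=table, f1_rank_correlation=rho, manifest=manifest)


@dataclass
class AreaResult:
    table: pd.DataFrame  # per subject x area metrics
    means: dict[str, dict[str, float]]
    paired_tests: dict[tuple[str, str, str], PairedTestResult]
    manifest: dict


def run_area_comparison(
    cohort: CohortEpochs,
    areas: Sequence[str] = ("F3", "P3", "O3", "PO9"),
    n_avg: int = 20,
    rng_seed: int = 0,
    method: str = "ceegnet",
    n_pos: int = DEFAULT_N_POS,
    test_size: tuple[int, int] = DEFAULT_TEST_SIZE,
    train_config: TrainConfig = DEFAULT_TRAIN_CONFIG,
) -> AreaResult:
    """Re-run the verification pipeline per channel subset and compare the
    brain areas pairwise (Wilcoxon on each metric)."""
    results: dict[str, dict[str, MetricsReport]] = {a: {} for a in areas}
    for area in areas:
        train_view = cohort.session_view(1, area)
        test_view = cohort.session_view(2, area)
        seeds = _subject_seeds(rng_seed, cohort.subjects)
        for sub in cohort.subjects:
            results[area][sub] = _evaluate_subject(
                sub, train_view, test_view, n_avg, seeds[sub], (method,),
                n_pos, test_size, train_config,
            )[method]
        logger.info("area %s mean accuracy %.3f", area,
                    np.mean([r.accuracy for r in results[area].values()]))
    rows = []
    for area in areas:
        for sub, rep in results[area].items():
            rows.append({"subject": sub, "area": area,
                         **{m: getattr(rep, m) for m in METRICS}})
    table = pd.DataFrame(rows)
    means = {
        area: {m: float(table[table.area == area][m].mean()) for m in METRICS}
        for area in areas
    }
    paired: dict[tuple[str, str, str], PairedTestResult] = {}
    if len(cohort.subjects) >= 5:
        for a, b in itertools.combinations(areas, 2):
            for m in METRICS:
                paired[(a, b, m)] = wilcoxon_signed_rank(
                    table[table.area == a].sort_values("subject")[m].to_numpy(),
                    table[table.area == b].sort_values("subject")[m].to_numpy(),
                )
    manifest = {
        "cohort": cohort.manifest, "areas": list(areas), "n_avg": n_avg,
        "rng_seed": rng_seed, "method": method, "n_pos": n_pos,
        "test_size": list(test_size), "train_config": asdict(train_config),
        "n_comparisons": len(paired),
    }
    return AreaResult(table=table, means=means, paired_tests=paired, manifest=manifest)
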