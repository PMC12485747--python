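"""Sliding-window PCA scan for recombination within the inversion.

Inversion heterozygotes and both homozygote classes separate along PC1
of the local genotype matrix wherever H1 and H2 haplotype pools are
divergent.  Scanning PC1 in non-overlapping 10 kb windows, computing
per-genotype quantile envelopes, and reassigning maximal runs of at
least two adjacent outlier windows exposes individuals whose sequence
locally matches the opposite inversion clade: interior runs flanked by
concordant windows are double crossover (or long gene-conversion)
events, runs reaching the analyzed region's edge are single events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Interval
from .inversion import GENOTYPES, InversionCall

__all__ = [
    "ScanConfig",
    "WindowPCAResult",
    "GroupStats",
    "RecombEvent",
    "windowed_pc1",
    "group_stats",
    "flag_ambiguous_windows",
    "detect_outlier_runs",
    "classify_events",
    "scan",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    region: Interval
    window: int = 10_000  # non-overlapping
    min_run: int = 2  # adjacent outlier windows required for reassignment
    low_percentile: float = 5.0
    high_percentile: float = 95.0
    min_variants: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.low_percentile < self.high_percentile < 100):
            raise ValueError("need 0 < low percentile < high percentile < 100")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.window <= 0:
            raise ValueError("window must be positive")


@dataclass
class WindowPCAResult:
    """Per-window PC1 scores, oriented so mean(H2/H2) >= mean(H1/H1)."""

    samples: list[str]
    genotypes: list[str]  # upstream inversion genotype per sample ("" if none)
    starts: np.ndarray
    ends: np.ndarray
    pc1: np.ndarray  # n_samples x n_windows, NaN in ambiguous windows
    variant_counts: np.ndarray
    ambiguous: np.ndarray  # bool per window (variant-poor / degenerate)
    contig: str = ""

    @property
    def n_windows(self) -> int:
        return len(self.starts)


@dataclass
class GroupStats:
    """Mean/median/quantile envelope of PC1 per window x inversion genotype."""

    frame: pd.DataFrame  # columns: window, genotype, n, mean, median, q_low, q_high

    def __post_init__(self) -> None:
        self._cache: dict[tuple[int, str], tuple[float, float] | None] = {}
        for r in self.frame.itertuples():
            key = (int(r.window), r.genotype)
            self._cache[key] = (
                None if np.isnan(r.q_low) else (float(r.q_low), float(r.q_high))
            )

    def envelope(self, window: int, genotype: str) -> tuple[float, float] | None:
        return self._cache.get((window, genotype))


@dataclass(frozen=True)
class RecombEvent:
    sample: str
    contig: str
    start: int  # first reassigned window's start
    end: int  # last reassigned window's end
    original: str
    reassigned: str
    event_class: str  # "single" or "double"
    population: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def _genotype_lookup(calls: list[InversionCall]) -> dict[str, str]:
    return {c.sample: c.genotype for c in calls if c.genotype in GENOTYPES}


def windowed_pc1(
    matrix: GenotypeMatrix, calls: list[InversionCall], config: ScanConfig
) -> WindowPCAResult:
    """PC1 of the centered genotype matrix in each non-overlapping window.

    Windows with fewer than ``min_variants`` sites or zero variance are
    marked ambiguous.  PC1 is computed by SVD (deterministic up to
    sign) and the sign fixed by requiring the H2/H2 group mean to be at
    least the H1/H1 group mean (falling back to heterozygotes against
    H1/H1 when a homozygote class is absent), which also makes the
    scores invariant to flipping the allele coding at any site.
    """
    lookup = _genotype_lookup(calls)
    genotypes = [lookup.get(s, "") for s in matrix.samples]
    for g in GENOTYPES:
        if sum(x == g for x in genotypes) >= 2:
            break
    else:
        raise ValueError("need at least one inversion-genotype group with >= 2 samples")
    region = config.region
    starts = np.arange(region.start, region.end - config.window + 1, config.window)
    ends = starts + config.window
    n, W = matrix.n_samples, len(starts)
    pc1 = np.full((n, W), np.nan)
    counts = np.zeros(W, dtype=int)
    ambiguous = np.zeros(W, dtype=bool)
    groups = {g: np.array([x == g for x in genotypes]) for g in GENOTYPES}
    for w in range(W):
        mask = (matrix.positions >= starts[w]) & (matrix.positions < ends[w])
        counts[w] = int(mask.sum())
        if counts[w] < config.min_variants:
            ambiguous[w] = True
            continue
        X = matrix.data[:, mask].astype(float)
        miss = X == MISSING
        if miss.any():
            col_means = np.where(
                miss.all(axis=0), 0.0,
                np.nanmean(np.where(miss, np.nan, X), axis=0),
            )
            X = np.where(miss, col_means[None, :], X)
        X = X - X.mean(axis=0, keepdims=True)
        if not np.any(X):
            ambiguous[w] = True
            continue
        # deterministic eigendecomposition: first left singular vector
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        scores = u[:, 0] * s[0]
        scores = _orient(scores, groups)
        if scores is None:
            ambiguous[w] = True
            continue
        pc1[:, w] = scores
    return WindowPCAResult(
        samples=list(matrix.samples),
        genotypes=genotypes,
        starts=starts,
        ends=ends,
        pc1=pc1,
        variant_counts=counts,
        ambiguous=ambiguous,
        contig=region.contig,
    )


def _orient(scores: np.ndarray, groups: dict[str, np.ndarray]) -> np.ndarray | None:
    """Fix the PC1 sign so higher scores mean more H2-like."""
    for lo_g, hi_g in (("H1/H1", "H2/H2"), ("H1/H1", "H1/H2"), ("H1/H2", "H2/H2")):
        lo, hi = groups[lo_g], groups[hi_g]
        if lo.any() and hi.any():
            delta = scores[hi].mean() - scores[lo].mean()
            if delta == 0.0:
                return None
            return scores if delta > 0 else -scores
    return None


def group_stats(result: WindowPCAResult, config: ScanConfig) -> GroupStats:
    """Mean, median and the configured quantiles of PC1 per window x genotype,
    over samples with confident upstream inversion calls only."""
    rows = []
    genotypes = np.array(result.genotypes)
    for w in range(result.n_windows):
        for g in GENOTYPES:
            scores = result.pc1[genotypes == g, w]
            scores = scores[~np.isnan(scores)]
            if len(scores) == 0:
                rows.append(
                    dict(window=w, genotype=g, n=0, mean=np.nan, median=np.nan,
                         q_low=np.nan, q_high=np.nan)
                )
                continue
            rows.append(
                dict(
                    window=w,
                    genotype=g,
                    n=len(scores),
                    mean=float(scores.mean()),
                    median=float(np.median(scores)),
                    q_low=float(np.percentile(scores, config.low_percentile)),
                    q_high=float(np.percentile(scores, config.high_percentile)),
                )
            )
    return GroupStats(pd.DataFrame(rows))


def flag_ambiguous_windows(
    result: WindowPCAResult, stats: GroupStats, config: ScanConfig
) -> np.ndarray:
    """Windows where any two genotype groups' quantile envelopes overlap.

    Returns the combined ambiguity mask (PCA-level ambiguity OR
    envelope overlap); overlapping envelopes mean group membership
    cannot be read off PC1 there.
    """
    ambiguous = result.ambiguous.copy()
    for w in range(result.n_windows):
        if ambiguous[w]:
            continue
        envs = []
        for g in GENOTYPES:
            env = stats.envelope(w, g)
            if env is not None:
                envs.append(env)
        if len(envs) < 2:
            ambiguous[w] = True
            continue
        for i in range(len(envs)):
            for j in range(i + 1, len(envs)):
                if max(envs[i][0], envs[j][0]) <= min(envs[i][1], envs[j][1]):
                    ambiguous[w] = True
    return ambiguous


@dataclass(frozen=True)
class _Run:
    sample: str
    original: str
    target: str
    first: int  # window indices, inclusive
    last: int
    n_windows: int  # outlier (non-ambiguous) windows inside the run


def detect_outlier_runs(
    result: WindowPCAResult,
    stats: GroupStats,
    config: ScanConfig,
    ambiguous: np.ndarray | None = None,
) -> list[_Run]:
    """Maximal runs of >= min_run adjacent outlier windows, reassigned.

    A sample is an outlier in a window when its PC1 exits its own
    genotype's [low, high]-percentile envelope toward another group:
    heterozygotes below their 5th percentile are reassigned toward
    H1/H1 and above their 95th toward H2/H2; homozygotes are reassigned
    toward H1/H2 when they cross the heterozygote envelope's near
    boundary.  Runs may bridge a single intervening ambiguous window
    (merged, logged); only non-ambiguous windows count toward min_run.
    """
    if ambiguous is None:
        ambiguous = flag_ambiguous_windows(result, stats, config)
    runs: list[_Run] = []
    for i, sample in enumerate(result.samples):
        g = result.genotypes[i]
        if g not in GENOTYPES:
            continue
        targets: list[tuple[int, str]] = []  # (window index, target genotype)
        for w in range(result.n_windows):
            if ambiguous[w] or np.isnan(result.pc1[i, w]):
                continue
            t = _window_target(result.pc1[i, w], g, w, stats)
            targets.append((w, t))
        runs.extend(_collect_runs(sample, g, targets, config))
    return runs


def _window_target(score: float, genotype: str, w: int, stats: GroupStats) -> str:
    """Reassignment target for one sample in one window ('' = concordant).

    PC1 space is partitioned among the genotype groups present in the
    window by the midpoints of the gaps between adjacent quantile
    envelopes; a sample falling in another group's slot is an outlier
    toward that group.  Merely leaving one's own envelope (expected for
    ~10% of samples per window by construction of the 5-95% envelopes)
    does not cross a midpoint and is not evidence of membership
    elsewhere; conversely a truly converted tract sits deep inside the
    target slot even in windows where it strays outside the target's
    own envelope.
    """
    present = [
        (g, env) for g in GENOTYPES if (env := stats.envelope(w, g)) is not None
    ]
    if len(present) < 2 or all(g != genotype for g, _ in present):
        return ""
    own = dict(present)[genotype]
    if own[0] <= score <= own[1]:
        return ""
    # cut points between consecutive envelopes (non-ambiguous windows
    # have disjoint envelopes ordered H1/H1 < H1/H2 < H2/H2)
    assigned = present[0][0]
    for (g_lo, env_lo), (g_hi, env_hi) in zip(present, present[1:]):
        cut = 0.5 * (env_lo[1] + env_hi[0])
        if score > cut:
            assigned = g_hi
    return assigned if assigned != genotype else ""


def _collect_runs(
    sample: str, genotype: str, targets: list[tuple[int, str]], config: ScanConfig
) -> list[_Run]:
    runs: list[_Run] = []
    current: list[tuple[int, str]] = []

    def flush() -> None:
        if current and len(current) >= config.min_run:
            runs.append(
                _Run(
                    sample=sample,
                    original=genotype,
                    target=current[0][1],
                    first=current[0][0],
                    last=current[-1][0],
                    n_windows=len(current),
                )
            )
        current.clear()

    for w, t in targets:
        if not t:
            flush()
            continue
        if current and (t != current[-1][1] or w - current[-1][0] > 2):
            # different target, or a gap of more than one ambiguous window
            flush()
        elif current and w - current[-1][0] == 2:
            log.info(
                "%s: outlier run bridges ambiguous window %d", sample, current[-1][0] + 1
            )
        current.append((w, t))
    flush()
    return runs


def classify_events(
    runs: list[_Run],
    result: WindowPCAResult,
    config: ScanConfig,
    ambiguous: np.ndarray | None = None,
    populations: dict[str, str] | None = None,
) -> list[RecombEvent]:
    """Classify reassigned runs as single or double recombination events.

    A run flanked on both sides by at least one usable (non-ambiguous)
    window — necessarily concordant, runs being maximal — is a double
    event; a run reaching either boundary of the analyzed region is a
    single event.
    """
    if ambiguous is None:
        stats = group_stats(result, config)
        ambiguous = flag_ambiguous_windows(result, stats, config)
    populations = populations or {}
    usable = ~ambiguous
    events = []
    for run in runs:
        i = result.samples.index(run.sample)
        left = np.any(usable[: run.first] & ~np.isnan(result.pc1[i, : run.first]))
        right = np.any(
            usable[run.last + 1 :] & ~np.isnan(result.pc1[i, run.last + 1 :])
        )
        event_class = "double" if (left and right) else "single"
        events.append(
            RecombEvent(
                sample=run.sample,
                contig=result.contig,
                start=int(result.starts[run.first]),
                end=int(result.ends[run.last]),
                original=run.original,
                reassigned=run.target,
                event_class=event_class,
                population=populations.get(run.sample, ""),
            )
        )
    return events


def scan(
    matrix: GenotypeMatrix,
    calls: list[InversionCall],
    config: ScanConfig,
    populations: dict[str, str] | None = None,
) -> tuple[list[RecombEvent], WindowPCAResult, GroupStats, np.ndarray]:
    """Full scan: windowed PC1 -> envelopes -> outlier runs -> events."""
    result = windowed_pc1(matrix, calls, config)
    stats = group_stats(result, config)
    ambiguous = flag_ambiguous_windows(result, stats, config)
    runs = detect_outlier_runs(result, stats, config, ambiguous)
    events = classify_events(runs, result, config, ambiguous, populations)
    return events, result, stats, ambiguous


def events_to_frame(events: list[RecombEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [e.sample for e in events],
            "contig": [e.contig for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "class": [e.event_class for e in events],
            "from": [e.original for e in events],
            "to": [e.reassigned for e in events],
            "length": [e.length for e in events],
            "population": [e.population for e in events],
        }
    )
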