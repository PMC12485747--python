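"""Read-depth based copy-number estimation of segmental duplications.

Depth is averaged in 1,000 bp sliding windows advanced in 100 bp
steps, normalized to the mean depth of a copy-number-invariant control
region, and averaged over the windows inside each duplication's unique
sector; twice the normalized sector mean is the diploid copy number.
NSF, present in two copies in the reference, is estimated by summing
the normalized depth over its two target regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import Interval

__all__ = [
    "SectorDef",
    "DepthConfig",
    "DepthTrack",
    "CNEstimate",
    "GRCH38_SECTORS",
    "window_depth",
    "windows_from_table",
    "normalize",
    "sector_cn",
    "nsf_cn",
    "estimate_all",
]


@dataclass(frozen=True)
class SectorDef:
    name: str
    interval: Interval


#: sectors on GRCh38 used for real data: the α/β KANSL1-unique regions,
#: the two NSF copies, and the CN-invariant control region.
GRCH38_SECTORS: dict[str, SectorDef] = {
    "alpha": SectorDef("alpha", Interval("chr17", 46_143_000, 46_238_000)),
    "beta": SectorDef("beta", Interval("chr17", 46_095_000, 46_123_000)),
    "nsf_1": SectorDef("nsf_1", Interval("chr17", 46_336_376, 46_489_410)),
    "nsf_2": SectorDef("nsf_2", Interval("chr17", 46_564_311, 46_707_123)),
    "control": SectorDef("control", Interval("chr17", 42_800_000, 46_000_000)),
}


@dataclass(frozen=True)
class DepthConfig:
    window_size: int = 1000
    step: int = 100
    cn_max_kansl1: float = 20.0  # QC cap on the α/β (KANSL1) estimates
    cn_max_nsf: float = 50.0
    statistic: str = "mean"  # control normalization statistic
    min_control_windows: int = 100
    min_sector_windows: int = 10

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if self.cn_max_kansl1 <= 0 or self.cn_max_nsf <= 0:
            raise ValueError("CN caps must be positive")
        if self.statistic not in ("mean", "median"):
            raise ValueError("statistic must be 'mean' or 'median'")


@dataclass
class DepthTrack:
    """Windowed depth for one sample; ``normalized`` is None until
    :func:`normalize` has run.  Missing windows are NaN."""

    contig: str
    starts: np.ndarray
    ends: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray | None = None
    control_stat: float | None = None
    sample: str = ""

    def __post_init__(self) -> None:
        if not (len(self.starts) == len(self.ends) == len(self.raw)):
            raise ValueError("window arrays must have equal length")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("windows must be sorted and strictly increasing")


@dataclass(frozen=True)
class CNEstimate:
    sample: str
    sector: str
    cn: float  # continuous diploid copy number (NaN for no-call)
    call: int | None  # nearest integer, half away from zero
    qc_pass: bool
    reason: str = ""


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def window_depth(
    depth: pd.DataFrame, config: DepthConfig, region: Interval
) -> DepthTrack:
    """Average per-base depth in sliding windows across ``region``.

    ``depth`` holds contig/start/end/value intervals of per-base (or
    piecewise-constant) coverage.  Bases not covered by any interval
    are missing; a window containing any missing base is marked missing
    (NaN) and excluded from downstream sector means.  Trailing partial
    windows are dropped.
    """
    span = len(region)
    if span < config.window_size:
        raise ValueError("region shorter than one window")
    per_base = np.full(span, np.nan)
    sub = depth[depth["contig"].isin([region.contig, "."])]
    for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
        a = max(int(start), region.start) - region.start
        b = min(int(end), region.end) - region.start
        if b > a:
            per_base[a:b] = value
    starts = np.arange(0, span - config.window_size + 1, config.step, dtype=np.int64)
    # window sums via cumulative sums; windows touching a coverage gap
    # are flagged missing through a parallel gap count
    gap = np.isnan(per_base)
    csum = np.concatenate([[0.0], np.cumsum(np.where(gap, 0.0, per_base))])
    gsum = np.concatenate([[0], np.cumsum(gap)])
    means = (csum[starts + config.window_size] - csum[starts]) / config.window_size
    means[gsum[starts + config.window_size] - gsum[starts] > 0] = np.nan
    return DepthTrack(
        contig=region.contig,
        starts=starts + region.start,
        ends=starts + region.start + config.window_size,
        raw=means,
    )


def windows_from_table(track: pd.DataFrame, sample: str = "") -> DepthTrack:
    """Adopt an already-windowed depth table (contig/start/end/value)."""
    return DepthTrack(
        contig=str(track["contig"].iloc[0]),
        starts=track["start"].to_numpy(dtype=np.int64),
        ends=track["end"].to_numpy(dtype=np.int64),
        raw=track["value"].to_numpy(dtype=float),
        sample=sample,
    )


def _contained_mask(track: DepthTrack, sector: SectorDef) -> np.ndarray:
    # windows fully inside the sector: boundary windows mix sector and
    # flanking copy number and would bias the mean toward 2
    iv = sector.interval
    if iv.contig != track.contig:
        return np.zeros(len(track.starts), dtype=bool)
    return (track.starts >= iv.start) & (track.ends <= iv.end)


def normalize(track: DepthTrack, control: SectorDef, config: DepthConfig) -> DepthTrack:
    """Divide every window's depth by the control-region statistic."""
    mask = _contained_mask(track, control)
    vals = track.raw[mask]
    vals = vals[~np.isnan(vals)]
    if len(vals) < config.min_control_windows:
        raise ValueError(
            f"only {len(vals)} usable control windows "
            f"(need >= {config.min_control_windows})"
        )
    stat = float(np.mean(vals) if config.statistic == "mean" else np.median(vals))
    if stat <= 0:
        raise ValueError(f"control depth statistic is {stat}; cannot normalize")
    return replace(track, normalized=track.raw / stat, control_stat=stat)


def _sector_mean(track: DepthTrack, sector: SectorDef, config: DepthConfig) -> float | None:
    if track.normalized is None:
        raise ValueError("track must be normalized before sector CN estimation")
    vals = track.normalized[_contained_mask(track, sector)]
    vals = vals[~np.isnan(vals)]
    if len(vals) < config.min_sector_windows:
        return None
    return float(np.mean(vals))


def sector_cn(track: DepthTrack, sector: SectorDef, config: DepthConfig) -> CNEstimate:
    """Diploid CN of a single-copy-baseline sector: 2 x mean normalized depth."""
    mean = _sector_mean(track, sector, config)
    if mean is None:
        return CNEstimate(track.sample, sector.name, float("nan"), None, False,
                          "too few usable sector windows")
    cn = 2.0 * mean
    qc = cn <= config.cn_max_kansl1
    return CNEstimate(
        track.sample, sector.name, cn, _round_half_away(cn), qc,
        "" if qc else f"CN {cn:.1f} exceeds cap {config.cn_max_kansl1:g}",
    )


def nsf_cn(
    track: DepthTrack, nsf_1: SectorDef, nsf_2: SectorDef, config: DepthConfig
) -> CNEstimate:
    """Diploid NSF CN: 2 x (sum of the two target regions' normalized means).

    Two reference copies per haploid genome put the diploid baseline at
    4 when both regions sit at normalized depth 1.
    """
    m1 = _sector_mean(track, nsf_1, config)
    m2 = _sector_mean(track, nsf_2, config)
    if m1 is None or m2 is None:
        return CNEstimate(track.sample, "nsf", float("nan"), None, False,
                          "an NSF target region has too few usable windows")
    cn = 2.0 * (m1 + m2)
    qc = cn <= config.cn_max_nsf
    return CNEstimate(
        track.sample, "nsf", cn, _round_half_away(cn), qc,
        "" if qc else f"CN {cn:.1f} exceeds cap {config.cn_max_nsf:g}",
    )


def estimate_all(
    track: DepthTrack, sectors: dict[str, SectorDef], config: DepthConfig
) -> dict[str, CNEstimate]:
    """Normalize against the control sector and estimate α, β and NSF CN."""
    norm = normalize(track, sectors["control"], config)
    out = {
        "alpha": sector_cn(norm, sectors["alpha"], config),
        "beta": sector_cn(norm, sectors["beta"], config),
    }
    if "nsf_1" in sectors and "nsf_2" in sectors:
        out["nsf"] = nsf_cn(norm, sectors["nsf_1"], sectors["nsf_2"], config)
    return out
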