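"""Synthetic cohort generator with known truth.

Emulates, at the level the pipeline consumes, the data a short-read
cohort provides at the 17q21.31 locus: tag-SNP genotypes linked to
inversion state, windowed read-depth tracks whose sector means scale
with duplication copy number under Poisson noise, inversion-interior
SNP matrices drawn from two divergent haplotype pools (so windowed PCA
separates the three inversion genotypes), implanted recombination
tracts, and sample ages drawn against a multinomial-logit frequency
trajectory.

The default configuration uses a compact synthetic contig with the
same geometry as the real locus (a copy-number-invariant control
region, the β- and α-unique KANSL1 sectors, two NSF sectors, and an
inversion interior) scaled down so whole cohorts simulate in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, Interval
from .haplotypes import StructuralHaplotype, parse_label

__all__ = [
    "SimConfig",
    "Trajectory",
    "RecombTract",
    "CohortTruth",
    "default_sim_sectors",
    "draw_cohort",
    "simulate_tag_genotypes",
    "simulate_depth",
    "simulate_inversion_snps",
    "simulate_cohort",
]

#: synthetic contig name used by the default configuration
SIM_CONTIG = "chr17_sim"

#: haplotype frequencies emulating a present-day European cohort:
#: the unduplicated H1 background remains the major haplotype while the
#: KANSL1-duplication haplotypes (H1.β2+, H2.α2+) segregate at the
#: frequencies reported for modern Europe (~29% and ~21%).
DEFAULT_FREQS: dict[str, float] = {
    "H1.β1": 0.45,
    "H1.β2": 0.29,
    "H2.α1": 0.05,
    "H2.α2": 0.21,
}


def default_sim_sectors(locus: Interval | None = None) -> dict[str, Interval]:
    """Sector layout on the compact synthetic locus.

    Mirrors the real locus geometry: control region first, then the β
    and α KANSL1-unique sectors, then the two NSF sectors, with the
    inversion interior occupying the distal part of the contig.
    """
    c = locus.contig if locus is not None else SIM_CONTIG
    return {
        "control": Interval(c, 0, 140_000),
        "beta": Interval(c, 150_000, 170_000),
        "alpha": Interval(c, 200_000, 230_000),
        "nsf_1": Interval(c, 300_000, 340_000),
        "nsf_2": Interval(c, 360_000, 400_000),
        "inversion": Interval(c, 140_000, 500_000),
    }


@dataclass(frozen=True)
class RecombTract:
    """A tract implanted on one haplotype of one individual.

    The tract's sequence is drawn from the ``donor`` inversion clade's
    allele pool, emulating a double crossover / long gene conversion
    that copied the opposite clade into an interior interval.
    """

    individual: int
    interval: Interval
    donor: str  # "H1" or "H2"


@dataclass(frozen=True)
class Trajectory:
    """Multinomial-logit haplotype-frequency trajectory through time.

    Logits are linear in time expressed in kiloyears oriented toward
    the present (``t = -age_bp / 1000``), so a positive slope means the
    category rises toward the present.  Category probability at age a:
    ``softmax(intercept_c + slope_c * t)`` over the configured labels.
    """

    time_range_bp: tuple[float, float]  # (youngest, oldest) in years BP
    intercepts: Mapping[str, float]
    slopes: Mapping[str, float]

    def probabilities(self, age_bp: np.ndarray, labels: Sequence[str]) -> np.ndarray:
        t = -np.asarray(age_bp, dtype=float)[:, None] / 1000.0
        eta = np.array([[self.intercepts[l] for l in labels]]) + t * np.array(
            [[self.slopes[l] for l in labels]]
        )
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic cohort; seed-determined."""

    n_individuals: int = 200
    haplotype_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FREQS)
    )
    n_tag_snps: int = 500
    tag_error_rate: float = 0.01
    mean_coverage: float = 30.0
    locus: Interval = field(default_factory=lambda: Interval(SIM_CONTIG, 0, 500_000))
    snp_density: float = 1.0  # SNPs per kb inside the inversion
    haplotype_divergence: float = 0.8
    recomb_tracts: tuple[RecombTract, ...] = ()
    trajectory: Trajectory | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = dict(self.haplotype_freqs)
        if not freqs:
            raise ValueError("haplotype_freqs must be non-empty")
        vals = np.array(list(freqs.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("haplotype frequencies must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {vals.sum()}, not 1")
        for label in freqs:
            parse_label(label)  # validates
        if self.n_tag_snps < 1:
            raise ValueError("n_tag_snps must be >= 1")
        if not (0.0 <= self.tag_error_rate < 1.0):
            raise ValueError("tag_error_rate must be in [0, 1)")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if not (0.0 <= self.haplotype_divergence <= 1.0):
            raise ValueError("haplotype_divergence must be in [0, 1]")
        for tract in self.recomb_tracts:
            if tract.interval.contig != self.locus.contig or not (
                self.locus.start <= tract.interval.start
                and tract.interval.end <= self.locus.end
            ):
                raise ValueError(f"tract {tract.interval} outside locus {self.locus}")
            if tract.donor not in ("H1", "H2"):
                raise ValueError("tract donor must be H1 or H2")
            if not (0 <= tract.individual < self.n_individuals):
                raise ValueError("tract individual index out of range")

    @property
    def labels(self) -> list[str]:
        return list(self.haplotype_freqs.keys())


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort."""

    config: SimConfig
    sample_ids: list[str]
    haplotypes: list[tuple[StructuralHaplotype, StructuralHaplotype]]
    ages_bp: np.ndarray | None  # None when no trajectory is simulated
    tracts: tuple[RecombTract, ...]

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def inversion_genotype(self, i: int) -> str:
        n_h2 = sum(h.inversion_state == "H2" for h in self.haplotypes[i])
        return ("H1/H1", "H1/H2", "H2/H2")[n_h2]

    def sector_cn(self) -> pd.DataFrame:
        """True diploid copy numbers per sector (alpha, beta, nsf, control)."""
        rows = []
        for sid, (a, b) in zip(self.sample_ids, self.haplotypes):
            rows.append(
                {
                    "sample": sid,
                    "alpha": a.alpha_copies + b.alpha_copies,
                    "beta": a.beta_copies + b.beta_copies,
                    "nsf": a.nsf_copies + b.nsf_copies,
                    "control": 2,
                }
            )
        return pd.DataFrame(rows).set_index("sample")

    def metadata(self, population: str = "SIM") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "population": population,
                "age_bp": self.ages_bp if self.ages_bp is not None else 0.0,
            }
        )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent streams per output so adding one output never
    # perturbs another
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def draw_cohort(config: SimConfig) -> CohortTruth:
    """Draw diploid individuals from the configured haplotype frequencies.

    With a trajectory configured, each sample receives a uniform age in
    the trajectory's time range and its two haplotypes are drawn from
    the logit model evaluated at that age; otherwise haplotypes are
    i.i.d. from ``haplotype_freqs``.
    """
    rng = _rng(config, 0)
    labels = config.labels
    haps = [parse_label(l) for l in labels]
    n = config.n_individuals
    if config.trajectory is not None:
        lo, hi = config.trajectory.time_range_bp
        ages = rng.uniform(min(lo, hi), max(lo, hi), size=n)
        probs = config.trajectory.probabilities(ages, labels)
        draws = np.array([rng.choice(len(labels), size=2, p=p) for p in probs])
    else:
        ages = None
        p = np.array([config.haplotype_freqs[l] for l in labels], dtype=float)
        p = p / p.sum()
        draws = rng.choice(len(labels), size=(n, 2), p=p)
    pairs = [(haps[i], haps[j]) for i, j in draws]
    sample_ids = [f"sim{i:04d}" for i in range(n)]
    # a tract donated by a clade both haplotypes already belong to is
    # statistically invisible; reject it as a configuration error
    for tract in config.recomb_tracts:
        a, b = pairs[tract.individual]
        if a.inversion_state == tract.donor and b.inversion_state == tract.donor:
            raise ValueError(
                f"tract for individual {tract.individual}: both haplotypes are "
                f"already {tract.donor}; nothing to convert"
            )
    return CohortTruth(config, sample_ids, pairs, ages, config.recomb_tracts)


def simulate_tag_genotypes(
    truth: CohortTruth, config: SimConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Tag-SNP genotypes: alternate-allele dosage equals the H2 count.

    Each haplotype contributes its H2 indicator at every panel SNP,
    flipped independently with probability ``tag_error_rate`` per site
    per haplotype.  Returns the genotype matrix and the panel table
    (contig, pos, tag_allele, polarity).
    """
    rng = _rng(config, 1)
    n, m = truth.n, config.n_tag_snps
    h2 = np.array(
        [[h.inversion_state == "H2" for h in pair] for pair in truth.haplotypes],
        dtype=np.int8,
    )  # n x 2
    alleles = np.repeat(h2[:, :, None], m, axis=2)  # n x 2 x m
    if config.tag_error_rate > 0:
        flips = rng.random((n, 2, m)) < config.tag_error_rate
        alleles = np.where(flips, 1 - alleles, alleles)
    geno = alleles.sum(axis=1).astype(np.int8)
    # panel positions spread across the locus, outside nothing in
    # particular — tag SNPs flank and span the inversion in reality
    span = len(config.locus)
    positions = config.locus.start + np.linspace(
        0.01 * span, 0.99 * span, m
    ).astype(np.int64)
    positions = np.unique(positions)
    if len(positions) < m:  # collisions only at absurd densities
        raise ValueError("locus too small for the requested tag panel size")
    matrix = GenotypeMatrix(truth.sample_ids, positions, geno, contig=config.locus.contig)
    panel = pd.DataFrame(
        {
            "contig": config.locus.contig,
            "pos": positions + 1,  # 1-based, as in VCF
            "tag_allele": "G",
            "polarity": "alt",
        }
    )
    return matrix, panel


def simulate_depth(
    truth: CohortTruth,
    sectors: Mapping[str, Interval],
    config: SimConfig,
    window_size: int = 1000,
    step: int = 100,
) -> dict[str, pd.DataFrame]:
    """Windowed raw depth per individual, Poisson around CN-scaled means.

    Window read counts are Poisson with mean
    ``coverage * (local diploid CN / 2) * window_size``; the returned
    value per window is count / window_size (a depth).  Local CN is the
    overlap-weighted mixture of sector CNs, 2 outside CN-variable
    sectors (the control region is CN 2 by construction).
    """
    if "control" not in sectors:
        raise ValueError("sectors must include a control sector")
    rng = _rng(config, 2)
    locus = config.locus
    starts = np.arange(locus.start, locus.end - window_size + 1, step, dtype=np.int64)
    ends = starts + window_size
    cn_true = truth.sector_cn()
    cn_sectors = [s for s in ("alpha", "beta", "nsf_1", "nsf_2") if s in sectors]
    # per-window overlap fraction with each CN-variable sector
    frac = {}
    for name in cn_sectors:
        iv = sectors[name]
        ov = np.clip(np.minimum(ends, iv.end) - np.maximum(starts, iv.start), 0, None)
        frac[name] = ov / window_size
    tracks: dict[str, pd.DataFrame] = {}
    for i, sid in enumerate(truth.sample_ids):
        cn = np.full(len(starts), 2.0)
        for name in cn_sectors:
            if name.startswith("nsf"):
                sector_cn = cn_true.loc[sid, "nsf"] / 2.0  # split across the 2 NSF regions
            else:
                sector_cn = float(cn_true.loc[sid, name])
            cn += frac[name] * (sector_cn - 2.0)
        lam = config.mean_coverage * (cn / 2.0) * window_size
        counts = rng.poisson(lam)
        tracks[sid] = pd.DataFrame(
            {
                "contig": locus.contig,
                "start": starts,
                "end": ends,
                "value": counts / window_size,
            }
        )
    return tracks


def simulate_inversion_snps(
    truth: CohortTruth, config: SimConfig, region: Interval | None = None
) -> GenotypeMatrix:
    """SNP genotypes inside the inversion drawn from two divergent pools.

    Each site gets an H1-pool and an H2-pool allele frequency separated
    by ``haplotype_divergence`` (pool identity of the high-frequency
    allele randomized per site); each haplotype draws alleles from the
    pool of its inversion clade.  Within an implanted tract the
    carrying haplotype draws from the donor clade's pool instead.
    """
    rng = _rng(config, 3)
    region = region if region is not None else default_sim_sectors(config.locus)["inversion"]
    n_sites = max(1, int(round(config.snp_density * len(region) / 1000.0)))
    positions = np.sort(
        rng.choice(np.arange(region.start, region.end), size=n_sites, replace=False)
    )
    d = config.haplotype_divergence
    hi, lo = 0.5 + d / 2.0, 0.5 - d / 2.0
    h1_high = rng.random(n_sites) < 0.5
    p_pool = {
        "H1": np.where(h1_high, hi, lo),
        "H2": np.where(h1_high, lo, hi),
    }
    n = truth.n
    geno = np.zeros((n, n_sites), dtype=np.int8)
    tracts_by_ind: dict[int, list[RecombTract]] = {}
    for tract in truth.tracts:
        tracts_by_ind.setdefault(tract.individual, []).append(tract)
    for i, pair in enumerate(truth.haplotypes):
        for k, hap in enumerate(pair):
            pools = np.repeat(hap.inversion_state, n_sites).astype(object)
            for tract in tracts_by_ind.get(i, ()):
                carrier = _tract_carrier(pair, tract.donor)
                if carrier == k:
                    inside = (positions >= tract.interval.start) & (
                        positions < tract.interval.end
                    )
                    pools[inside] = tract.donor
            p = np.where(pools == "H1", p_pool["H1"], p_pool["H2"])
            geno[i] += (rng.random(n_sites) < p).astype(np.int8)
    return GenotypeMatrix(truth.sample_ids, positions, geno, contig=region.contig)


def _tract_carrier(
    pair: tuple[StructuralHaplotype, StructuralHaplotype], donor: str
) -> int:
    """Index of the haplotype carrying the tract: the first whose clade
    differs from the donor (a tract replaces opposite-clade sequence)."""
    for k, hap in enumerate(pair):
        if hap.inversion_state != donor:
            return k
    raise ValueError("no haplotype differs from the tract donor")  # pre-checked


def simulate_cohort(config: SimConfig, outdir: str | None = None):
    """Convenience end-to-end simulation of every pipeline input.

    Returns (truth, tag matrix, panel, depth tracks, inversion-SNP
    matrix); when ``outdir`` is given, also writes VCFs, bedGraphs,
    metadata TSV and a truth TSV there.
    """
    from pathlib import Path

    from .io import write_bedgraph, write_vcf

    truth = draw_cohort(config)
    tags, panel = simulate_tag_genotypes(truth, config)
    sectors = default_sim_sectors(config.locus)
    depth = simulate_depth(truth, sectors, config)
    snps = simulate_inversion_snps(truth, config)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(
            out / "tags.vcf", tags, contig_length=config.locus.end,
            info_flags={j: "TAG" for j in range(tags.n_sites)},
        )
        write_vcf(out / "inversion_snps.vcf", snps, contig_length=config.locus.end)
        panel.to_csv(out / "panel.tsv", sep="\t", index=False)
        (out / "depth").mkdir(exist_ok=True)
        for sid, track in depth.items():
            write_bedgraph(
                out / "depth" / f"{sid}.bedgraph",
                config.locus.contig, track["start"].to_numpy(),
                track["end"].to_numpy(), track["value"].to_numpy(),
            )
        truth.metadata().to_csv(out / "metadata.tsv", sep="\t", index=False)
        truth_df = pd.DataFrame(
            {
                "sample": truth.sample_ids,
                "hap_a": [a.label for a, _ in truth.haplotypes],
                "hap_b": [b.label for _, b in truth.haplotypes],
            }
        )
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "sectors.bed", "w") as fh:
            for name, iv in sectors.items():
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\n")
    return truth, tags, panel, depth, snps
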