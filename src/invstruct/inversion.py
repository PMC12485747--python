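"""Tag-SNP based inversion genotyping.

Each individual's 0/1/2 genotype vector over an inversion tag-SNP
panel is compared by Euclidean distance to the three expected vectors
(all-0 for H1/H1, all-1 for H1/H2, all-2 for H2/H2, restricted per
sample to its non-missing sites); the genotype with the minimum
distance is assigned.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = [
    "GENOTYPES",
    "InversionCall",
    "load_panel",
    "load_genotypes",
    "genotype_inversion",
    "calls_to_frame",
]

log = logging.getLogger(__name__)

GENOTYPES = ("H1/H1", "H1/H2", "H2/H2")
NO_CALL = "no-call"


@dataclass(frozen=True)
class InversionCall:
    sample: str
    genotype: str  # one of GENOTYPES or "no-call"
    distances: tuple[float, float, float]  # to H1/H1, H1/H2, H2/H2
    n_snps_used: int
    margin: float  # runner-up minus best distance (>= 0)
    reason: str = ""

    @property
    def normalized_distances(self) -> tuple[float, float, float]:
        """Distances divided by sqrt(n_snps_used), comparable across samples."""
        if self.n_snps_used == 0:
            return (float("nan"),) * 3
        s = float(np.sqrt(self.n_snps_used))
        return tuple(d / s for d in self.distances)


def load_panel(path: str | os.PathLike) -> pd.DataFrame:
    """Load a tag-SNP panel TSV (contig, pos [1-based], tag_allele, polarity).

    ``polarity`` is ``alt`` when the alternate allele tags H2 and
    ``ref`` when the reference allele does.
    """
    panel = pd.read_csv(path, sep="\t")
    required = {"contig", "pos", "polarity"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    if panel.empty:
        raise ValueError("tag-SNP panel is empty")
    if panel.duplicated(["contig", "pos"]).any():
        raise ValueError("panel positions must be unique")
    bad = ~panel["polarity"].isin(["alt", "ref"])
    if bad.any():
        raise ValueError("panel polarity entries must be 'alt' or 'ref'")
    return panel


def load_genotypes(vcf_path: str | os.PathLike, panel: pd.DataFrame) -> GenotypeMatrix:
    """Extract panel-site genotypes from a VCF, polarity-corrected.

    One row per sample, one column per panel SNP, ordered as the panel;
    panel SNPs absent from the VCF (or multi-allelic, skipped with a
    warning) become missing.  After polarity correction an entry of 2
    always means two H2-tagging alleles.
    """
    from cyvcf2 import VCF

    panel_pos0 = panel["pos"].astype(int).to_numpy() - 1
    wanted = {(c, p) for c, p in zip(panel["contig"], panel_pos0)}
    found: dict[tuple[str, int], np.ndarray] = {}
    vcf = VCF(os.fspath(vcf_path), gts012=True)
    samples = list(vcf.samples)
    for rec in vcf:
        key = (rec.CHROM, rec.POS - 1)
        if key not in wanted:
            continue
        if len(rec.ALT) != 1:
            log.warning("skipping multi-allelic panel site %s:%d", rec.CHROM, rec.POS)
            continue
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        found[key] = g
    vcf.close()
    if not found:
        raise ValueError(f"no panel SNP found in {vcf_path}")
    n = len(samples)
    data = np.full((n, len(panel_pos0)), MISSING, dtype=np.int8)
    for j, (contig, pos0, polarity) in enumerate(
        zip(panel["contig"], panel_pos0, panel["polarity"])
    ):
        g = found.get((contig, pos0))
        if g is None:
            continue
        if polarity == "ref":  # reference allele tags H2: flip the dosage
            g = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
        data[:, j] = g
    return GenotypeMatrix(samples, panel_pos0, data, contig=str(panel["contig"].iloc[0]))


def genotype_inversion(
    matrix: GenotypeMatrix, min_call_fraction: float = 0.5
) -> list[InversionCall]:
    """Assign H1/H1, H1/H2 or H2/H2 by minimum Euclidean distance.

    Distances are computed per sample over its non-missing sites
    against the constant expected vectors restricted to those sites.
    A sample is a no-call when fewer than ``min_call_fraction`` of the
    panel sites are usable or when the two best distances tie exactly.
    """
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise ValueError("empty genotype matrix")
    calls: list[InversionCall] = []
    g = matrix.data.astype(float)
    obs = matrix.data != MISSING
    for i, sample in enumerate(matrix.samples):
        mask = obs[i]
        n_used = int(mask.sum())
        if n_used == 0:
            calls.append(
                InversionCall(sample, NO_CALL, (np.nan,) * 3, 0, 0.0, "no usable sites")
            )
            continue
        gi = g[i, mask]
        dists = tuple(
            float(np.sqrt(np.sum((gi - e) ** 2))) for e in (0.0, 1.0, 2.0)
        )
        order = np.argsort(dists, kind="stable")
        best, runner = order[0], order[1]
        margin = dists[runner] - dists[best]
        if n_used < min_call_fraction * matrix.n_sites:
            calls.append(
                InversionCall(
                    sample, NO_CALL, dists, n_used, margin,
                    f"only {n_used}/{matrix.n_sites} sites usable",
                )
            )
        elif margin == 0.0:
            calls.append(
                InversionCall(sample, NO_CALL, dists, n_used, margin, "distance tie")
            )
        else:
            calls.append(InversionCall(sample, GENOTYPES[best], dists, n_used, margin))
    return calls


def calls_to_frame(calls: list[InversionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "genotype": [c.genotype for c in calls],
            "d_H1H1": [c.distances[0] for c in calls],
            "d_H1H2": [c.distances[1] for c in calls],
            "d_H2H2": [c.distances[2] for c in calls],
            "n_snps": [c.n_snps_used for c in calls],
            "margin": [c.margin for c in calls],
            "reason": [c.reason for c in calls],
        }
    )
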