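"""Reading and writing the standard formats the pipeline exchanges.

VCF is written 1-based per the standard (internal coordinates are
0-based half-open); reading goes through cyvcf2.  Depth tracks travel
as bedGraph or two-column TSV; sectors as BED.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Interval

__all__ = [
    "write_vcf",
    "read_vcf_matrix",
    "write_bedgraph",
    "read_depth_table",
    "read_sector_bed",
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    path: str | os.PathLike,
    matrix: GenotypeMatrix,
    contig_length: int | None = None,
    info_flags: Mapping[int, str] | None = None,
    refs: Sequence[str] | None = None,
    alts: Sequence[str] | None = None,
) -> None:
    """Write a diploid genotype matrix as an uncompressed VCF 4.2 file.

    ``info_flags`` maps column index -> INFO flag string (e.g. ``"TAG"``
    for tag-panel sites).  Alleles default to A (ref) / G (alt).
    """
    info_flags = info_flags or {}
    refs = refs if refs is not None else ["A"] * matrix.n_sites
    alts = alts if alts is not None else ["G"] * matrix.n_sites
    length = contig_length if contig_length is not None else int(matrix.positions.max()) + 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.contig},length={length}>\n")
        fh.write('##INFO=<ID=TAG,Number=0,Type=Flag,Description="Inversion tag SNP">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in range(matrix.n_sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.data[:, j])
            info = info_flags.get(j, ".")
            fh.write(
                f"{matrix.contig}\t{matrix.positions[j] + 1}\t{matrix.site_ids[j]}\t"
                f"{refs[j]}\t{alts[j]}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_vcf_matrix(
    path: str | os.PathLike,
    region: Interval | None = None,
    positions: Iterable[int] | None = None,
) -> GenotypeMatrix:
    """Load biallelic diploid genotypes from a VCF into a GenotypeMatrix.

    ``positions`` (0-based) restricts to those sites; ``region``
    restricts to an interval.  Multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    wanted = set(int(p) for p in positions) if positions is not None else None
    vcf = VCF(os.fspath(path), gts012=True)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    pos_out: list[int] = []
    ids: list[str] = []
    contig = None
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        pos0 = rec.POS - 1
        if region is not None and not region.contains(rec.CHROM, pos0):
            continue
        if wanted is not None and pos0 not in wanted:
            continue
        contig = rec.CHROM
        # gts012: 0/1/2 dosage of ALT, 3 = unknown
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        cols.append(g)
        pos_out.append(pos0)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    vcf.close()
    if not cols:
        raise ValueError(f"no usable biallelic records read from {path}")
    data = np.stack(cols, axis=1)
    return GenotypeMatrix(samples, pos_out, data, contig=contig, site_ids=ids)


def write_bedgraph(
    path: str | os.PathLike,
    contig: str,
    starts: np.ndarray,
    ends: np.ndarray,
    values: np.ndarray,
) -> None:
    df = pd.DataFrame({"contig": contig, "start": starts, "end": ends, "value": values})
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_depth_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a depth input: 4-column bedGraph or 2-column TSV (pos, depth).

    Returns a frame with columns contig/start/end/value (0-based
    half-open); the 2-column dialect is interpreted as 1-based per-base
    positions and converted.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["contig", "start", "end", "value"]
        return df
    if df.shape[1] == 2:
        pos = df.iloc[:, 0].astype(int)
        return pd.DataFrame(
            {"contig": ".", "start": pos - 1, "end": pos, "value": df.iloc[:, 1]}
        )
    raise ValueError(f"unrecognized depth dialect ({df.shape[1]} columns) in {path}")


def read_sector_bed(path: str | os.PathLike) -> dict[str, Interval]:
    """Read sector definitions from a 4-column BED (name in column 4)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "name"],
    )
    return {
        str(r.name_): Interval(str(r.contig), int(r.start), int(r.end))
        for r in df.rename(columns={"name": "name_"}).itertuples()
    }
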