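"""Shared containers: genomic intervals and the 0/1/2 genotype matrix."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["Interval", "GenotypeMatrix", "MISSING"]

#: sentinel for a missing genotype in the int8 matrix
MISSING = -1


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end

    def overlap(self, other: "Interval") -> int:
        if other.contig != self.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenotypeMatrix:
    """Individuals x variant sites coded 0 (hom-ref), 1 (het), 2 (hom-alt).

    Missing genotypes are stored as -1.  Rows are samples, columns are
    sites; ``positions`` are 0-based site coordinates on ``contig``.
    """

    def __init__(
        self,
        samples: Sequence[str],
        positions: Sequence[int],
        data: np.ndarray,
        contig: str = "chr17",
        site_ids: Sequence[str] | None = None,
    ) -> None:
        data = np.asarray(data, dtype=np.int8)
        if data.shape != (len(samples), len(positions)):
            raise ValueError(
                f"data shape {data.shape} inconsistent with "
                f"{len(samples)} samples x {len(positions)} sites"
            )
        bad = ~np.isin(data, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries must be in {0, 1, 2, missing}")
        self.samples = list(samples)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.data = data
        self.contig = contig
        self.site_ids = (
            list(site_ids)
            if site_ids is not None
            else [f"{contig}:{p + 1}" for p in self.positions]
        )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def missing_mask(self) -> np.ndarray:
        return self.data == MISSING

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.samples,
            self.positions[mask],
            self.data[:, mask],
            contig=self.contig,
            site_ids=[s for s, keep in zip(self.site_ids, mask) if keep],
        )

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)
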