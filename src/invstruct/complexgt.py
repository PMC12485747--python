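"""Integration of inversion calls and KANSL1 copy numbers into diploid
complex structural genotypes.

The expectation table enumerates, for every unordered pair of
configured structural haplotypes, the α/β diploid copy numbers and the
inversion genotype that pair implies.  An individual is assigned the
pair matching its inversion call whose expected copy numbers are
nearest (L1) to the observed integer calls; exact ties are broken in
favour of commoner haplotypes (β1 > β2 > β3, α1 > α2 > α3), so a β CN
of 4 on an H1/H1 background resolves to β2/β2 rather than β1/β3.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import pandas as pd

from .depth import CNEstimate
from .haplotypes import parse_label
from .inversion import InversionCall

__all__ = [
    "DEFAULT_LABELS",
    "ExpectationTable",
    "DiploidStructuralGenotype",
    "integrate",
    "simplify",
    "trio_check",
]

#: default haplotype universe, in rarity order within each clade
#: (frequency order: unduplicated > one extra > two extra)
DEFAULT_LABELS: tuple[str, ...] = (
    "H1.β1", "H1.β2", "H1.β3", "H2.α1", "H2.α2", "H2.α3",
)

_INV_GENOTYPES = ("H1/H1", "H1/H2", "H2/H2")


@dataclass(frozen=True)
class TableEntry:
    pair: tuple[str, str]  # sorted labels
    inversion_genotype: str
    alpha_cn: int
    beta_cn: int
    # (rarest component's rank, rank sum): lower = commoner pair, so a
    # pair avoiding any very rare haplotype (β2/β2) beats one containing
    # it (β1/β3) even when the rank sums tie
    rarity_score: tuple[int, int]


class ExpectationTable:
    """Expected (α CN, β CN, inversion genotype) per haplotype pair."""

    def __init__(self, labels: tuple[str, ...] = DEFAULT_LABELS) -> None:
        self.labels = tuple(labels)
        haps = {l: parse_label(l) for l in labels}
        # rarity rank = extra-copy count within each clade's series
        rank = {l: haps[l].kansl1_dup for l in labels}
        self.entries: list[TableEntry] = []
        for a, b in combinations_with_replacement(sorted(labels), 2):
            ha, hb = haps[a], haps[b]
            n_h2 = (ha.inversion_state == "H2") + (hb.inversion_state == "H2")
            self.entries.append(
                TableEntry(
                    pair=(a, b),
                    inversion_genotype=_INV_GENOTYPES[n_h2],
                    alpha_cn=ha.alpha_copies + hb.alpha_copies,
                    beta_cn=ha.beta_copies + hb.beta_copies,
                    rarity_score=(max(rank[a], rank[b]), rank[a] + rank[b]),
                )
            )

    @classmethod
    def from_yaml(cls, path) -> "ExpectationTable":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(tuple(cfg["haplotypes"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hap_a": [e.pair[0] for e in self.entries],
                "hap_b": [e.pair[1] for e in self.entries],
                "inversion_genotype": [e.inversion_genotype for e in self.entries],
                "alpha_cn": [e.alpha_cn for e in self.entries],
                "beta_cn": [e.beta_cn for e in self.entries],
            }
        )


@dataclass(frozen=True)
class DiploidStructuralGenotype:
    """An unordered pair of structural-haplotype labels (phase unclaimed)."""

    sample: str
    hap_a: str  # sorted so hap_a <= hap_b; empty when unresolved
    hap_b: str
    confidence: str  # "high" (exact CN match), "low" (L1 distance 1), "unresolved"
    note: str = ""

    @property
    def resolved(self) -> bool:
        return self.confidence != "unresolved"

    @property
    def pair(self) -> tuple[str, str]:
        return (self.hap_a, self.hap_b)


def integrate(
    call: InversionCall,
    alpha: CNEstimate,
    beta: CNEstimate,
    table: ExpectationTable | None = None,
) -> DiploidStructuralGenotype:
    """Resolve a diploid structural genotype from the three upstream results.

    All three inputs must pass QC.  Candidates are the table entries
    whose inversion genotype matches the call; the entry minimizing the
    L1 distance between expected and observed (α, β) integer calls
    wins, with exact-distance ties resolved toward commoner haplotypes.
    No candidate within L1 distance 1 leaves the sample unresolved —
    including the case where the copy numbers contradict the inversion
    call (e.g. α > 2 in an H1/H1 individual).
    """
    table = table if table is not None else ExpectationTable()
    sample = call.sample
    if call.genotype not in _INV_GENOTYPES:
        return DiploidStructuralGenotype(sample, "", "", "unresolved",
                                         "no confident inversion call")
    if not (alpha.qc_pass and beta.qc_pass) or alpha.call is None or beta.call is None:
        return DiploidStructuralGenotype(sample, "", "", "unresolved",
                                         "copy-number QC failure")
    candidates = [e for e in table.entries if e.inversion_genotype == call.genotype]
    scored = sorted(
        candidates,
        key=lambda e: (
            abs(e.alpha_cn - alpha.call) + abs(e.beta_cn - beta.call),
            e.rarity_score,
            e.pair,
        ),
    )
    best = scored[0]
    dist = abs(best.alpha_cn - alpha.call) + abs(best.beta_cn - beta.call)
    if dist > 1:
        return DiploidStructuralGenotype(
            sample, "", "", "unresolved",
            f"observed CN (α={alpha.call}, β={beta.call}) inconsistent with "
            f"{call.genotype}: nearest expectation {best.pair} at L1 distance {dist}",
        )
    note = ""
    runners = [
        e for e in scored[1:]
        if abs(e.alpha_cn - alpha.call) + abs(e.beta_cn - beta.call) == dist
    ]
    if runners:
        note = (
            f"tie with {runners[0].pair} broken toward commoner haplotypes"
        )
    confidence = "high" if dist == 0 else "low"
    return DiploidStructuralGenotype(sample, best.pair[0], best.pair[1], confidence, note)


def simplify(genotype: DiploidStructuralGenotype) -> tuple[str, str]:
    """Collapse to the four short-read-reportable categories.

    Any haplotype carrying at least one extra KANSL1 duplicon copy maps
    to the open-ended "+" category; the mapping is total and idempotent
    on its output labels.
    """
    if not genotype.resolved:
        raise ValueError(f"cannot simplify unresolved genotype for {genotype.sample}")
    return tuple(sorted(_simplify_label(l) for l in genotype.pair))


def _simplify_label(label: str) -> str:
    if label.endswith("+"):
        return label  # already simplified
    return parse_label(label).simplified


def trio_check(
    child: DiploidStructuralGenotype,
    mother: DiploidStructuralGenotype,
    father: DiploidStructuralGenotype,
) -> bool:
    """Mendelian consistency: one child haplotype from each parent."""
    for ga, gb in ((0, 1), (1, 0)):
        if child.pair[ga] in mother.pair and child.pair[gb] in father.pair:
            return True
    return False
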