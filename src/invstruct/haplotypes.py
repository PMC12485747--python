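"""Structural haplotype labels for the 17q21.31 inversion locus.

A structural haplotype combines the inversion orientation clade (H1 or
H2) with the copy number of the partial *KANSL1* duplication carried on
that background (the β duplicon on H1, the α duplicon on H2) and the
per-haplotype *NSF* (γ) copy number.  Labels follow the established
nomenclature: ``H1.β1`` is an unduplicated direct-orientation
haplotype, ``H2.α2`` an inverted haplotype carrying one extra α copy,
and an optional ``.γk`` suffix records *NSF* copies when they differ
from the two copies present in the reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["StructuralHaplotype", "parse_label", "DEFAULT_NSF_COPIES"]

#: NSF copies per haplotype in the reference (GRCh38 carries two NSF copies).
DEFAULT_NSF_COPIES = 2

_LABEL_RE = re.compile(
    r"^H(?P<clade>[12])\.(?P<duplicon>[αβab])(?P<cn>\d+)"
    r"(?:\.(?:γ|g)(?P<nsf>\d+))?(?P<plus>\+)?$"
)

_DUPLICON_FOR_STATE = {"H1": "β", "H2": "α"}
_ASCII_DUPLICON = {"a": "α", "b": "β"}


@dataclass(frozen=True, order=True)
class StructuralHaplotype:
    """One structural haplotype: inversion clade + duplication content.

    Parameters
    ----------
    inversion_state :
        ``"H1"`` (direct) or ``"H2"`` (inverted).
    kansl1_dup :
        Extra copies of the clade-appropriate KANSL1 duplicon beyond the
        single copy every haplotype carries (β on H1, α on H2).  The
        label suffix is ``1 + kansl1_dup``: ``H1.β2`` has one extra β.
    nsf_copies :
        NSF duplicon copies on this haplotype (reference baseline 2).
    """

    inversion_state: str
    kansl1_dup: int = 0
    nsf_copies: int = DEFAULT_NSF_COPIES

    def __post_init__(self) -> None:
        if self.inversion_state not in ("H1", "H2"):
            raise ValueError(f"inversion_state must be H1 or H2, got {self.inversion_state!r}")
        if self.kansl1_dup < 0:
            raise ValueError("kansl1_dup must be >= 0")
        if self.nsf_copies < 0:
            raise ValueError("nsf_copies must be >= 0")

    @property
    def duplicon(self) -> str:
        """The KANSL1 duplicon this clade can carry: β on H1, α on H2."""
        return _DUPLICON_FOR_STATE[self.inversion_state]

    @property
    def label(self) -> str:
        base = f"{self.inversion_state}.{self.duplicon}{1 + self.kansl1_dup}"
        if self.nsf_copies != DEFAULT_NSF_COPIES:
            base += f".γ{self.nsf_copies}"
        return base

    # per-haplotype copies of each unique sector, used by the depth
    # simulator and the diploid expectation table
    @property
    def alpha_copies(self) -> int:
        """Copies of the α-unique sector (1 baseline, extras only on H2)."""
        return 1 + (self.kansl1_dup if self.inversion_state == "H2" else 0)

    @property
    def beta_copies(self) -> int:
        """Copies of the β-unique sector (1 baseline, extras only on H1)."""
        return 1 + (self.kansl1_dup if self.inversion_state == "H1" else 0)

    @property
    def simplified(self) -> str:
        """Collapse to the four reportable short-read categories.

        Haplotypes with any extra KANSL1 duplicon copy collapse to the
        open-ended "+" category (``H1.β2+`` / ``H2.α2+``); NSF content is
        dropped because short reads cannot phase it onto haplotypes.
        """
        if self.kansl1_dup == 0:
            return f"{self.inversion_state}.{self.duplicon}1"
        return f"{self.inversion_state}.{self.duplicon}2+"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    @classmethod
    def parse(cls, label: str) -> "StructuralHaplotype":
        return parse_label(label)


def parse_label(label: str) -> StructuralHaplotype:
    """Parse a haplotype label such as ``"H1.β2"`` or ``"H2.a1.g3"``.

    ASCII aliases (``a`` for α, ``b`` for β, ``g`` for γ) are accepted;
    the canonical formatted label always uses Greek letters.  A trailing
    ``+`` (the simplified open-ended category) is rejected because it
    does not denote a single haplotype.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"unparseable haplotype label: {label!r}")
    if m.group("plus"):
        raise ValueError(
            f"{label!r} is a simplified category, not a single haplotype label"
        )
    state = f"H{m.group('clade')}"
    duplicon = _ASCII_DUPLICON.get(m.group("duplicon"), m.group("duplicon"))
    if duplicon != _DUPLICON_FOR_STATE[state]:
        raise ValueError(
            f"{label!r}: the {duplicon} duplication cannot occur on {state} "
            f"(β is H1-specific, α is H2-specific)"
        )
    cn = int(m.group("cn"))
    if cn < 1:
        raise ValueError(f"{label!r}: duplicon suffix must be >= 1")
    nsf = int(m.group("nsf")) if m.group("nsf") else DEFAULT_NSF_COPIES
    return StructuralHaplotype(state, kansl1_dup=cn - 1, nsf_copies=nsf)
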