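"""Antiparallel RNA duplexes with exact end geometry.

Conventions
-----------
The *top* strand is drawn 5'->3' left to right; the *bottom* strand is
antiparallel, so its 5' end sits at the right edge. Two integers fix the
end geometry:

``left_ext``
    number of bottom-strand 3'-terminal nucleotides protruding past the
    top strand's 5' terminus at the left edge (negative: the top 5'
    protrudes instead).
``right_ext``
    number of top-strand 3'-terminal nucleotides protruding past the
    bottom strand's 5' terminus at the right edge (negative: the bottom
    5' protrudes). It is fully determined by the two strand lengths and
    ``left_ext`` through ``len(top) - right_ext == len(bottom) - left_ext``.

A positive extension at an end is the 3' overhang *o* the dicer prefers;
0 is a blunt end; negative means a 5' overhang, which the enzyme refuses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from .errors import ComplementarityError, GeometryError
from .strands import FivePrimeChem, RNAStrand, StrandSource, complement

_WOBBLE = {("G", "U"), ("U", "G")}


class End(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class WhichStrand(str, enum.Enum):
    TOP = "TOP"
    BOTTOM = "BOTTOM"


@dataclass(frozen=True)
class EndGeometry:
    """Everything the dicer senses at one duplex end."""

    end: End
    measured_strand: WhichStrand
    overhang: int
    m5_nt: str
    m5_chem: FivePrimeChem


@dataclass(frozen=True)
class Duplex:
    """Two antiparallel strands plus the registration fixing end overhangs.

    Complementarity over the paired region is validated on construction;
    untemplated 3' tail nucleotides are exempt (they were added without a
    template and may or may not pair). G.U wobble pairs are rejected
    unless ``allow_gu`` is set.
    """

    top: RNAStrand
    bottom: RNAStrand
    left_ext: int = 0
    allow_gu: bool = False

    @property
    def right_ext(self) -> int:
        return len(self.top) - len(self.bottom) + self.left_ext

    def __post_init__(self) -> None:
        lt, lb = len(self.top), len(self.bottom)
        re = self.right_ext
        paired = lt - max(re, 0) + min(self.left_ext, 0)
        if paired < 1:
            raise GeometryError(
                f"paired region of {paired} nt (< 1) for lengths "
                f"{lt}/{lb} with left_ext={self.left_ext}"
            )
        self._check_complementarity()

    def _pairs(self, i: int, j: int) -> bool:
        a, b = self.top.nt(i), self.bottom.nt(j)
        if complement(a) == b:
            return True
        return self.allow_gu and (a, b) in _WOBBLE

    def _check_complementarity(self) -> None:
        lt, lb = len(self.top), len(self.bottom)
        re = self.right_ext
        top_templated = lt - self.top.untemplated_tail_len
        bot_templated = lb - self.bottom.untemplated_tail_len
        i_lo = max(1, 1 - self.left_ext)
        i_hi = min(lt, lt - re)
        for i in range(i_lo, i_hi + 1):
            j = lt - re - i + 1
            if i > top_templated or j > bot_templated:
                continue  # untemplated tail: pairing not enforced
            if not self._pairs(i, j):
                raise ComplementarityError(
                    f"mismatch at top position {i} ({self.top.nt(i)}) vs "
                    f"bottom position {j} ({self.bottom.nt(j)})"
                )

    @property
    def paired_len(self) -> int:
        return len(self.top) - max(self.right_ext, 0) + min(self.left_ext, 0)

    def strand(self, which: WhichStrand) -> RNAStrand:
        return self.top if which is WhichStrand.TOP else self.bottom

    def nucleotide_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for nt in self.top.seq + self.bottom.seq:
            counts[nt] = counts.get(nt, 0) + 1
        return counts


def build_duplex(
    top_seq: str,
    bottom_seq: str,
    left_ext: int = 0,
    top_chem: FivePrimeChem = FivePrimeChem.MONO_P,
    bottom_chem: FivePrimeChem = FivePrimeChem.MONO_P,
    top_source: StrandSource = StrandSource.SYNTHETIC,
    bottom_source: StrandSource = StrandSource.SYNTHETIC,
    untemplated_tail_len: int = 0,
    allow_gu: bool = False,
) -> Duplex:
    """Build and validate a duplex from raw sequences.

    ``right_ext`` is derived from the two strand lengths and ``left_ext``.
    ``untemplated_tail_len`` refers to the bottom strand's 3' tail (the
    position an RDR2-added nucleotide occupies in the standard drawing).
    """
    top = RNAStrand(top_seq, five_prime_chem=top_chem, source=top_source)
    bottom = RNAStrand(
        bottom_seq,
        five_prime_chem=bottom_chem,
        source=bottom_source,
        untemplated_tail_len=untemplated_tail_len,
    )
    return Duplex(top, bottom, left_ext, allow_gu=allow_gu)


def end_geometry(d: Duplex, end: End) -> EndGeometry:
    """Measured strand identity, overhang and 5' features at one end.

    The measured strand is the one whose 5' terminus lies at the queried
    end: always TOP at LEFT and BOTTOM at RIGHT for antiparallel strands.
    """
    if end is End.LEFT:
        s = d.top
        return EndGeometry(end, WhichStrand.TOP, d.left_ext, s.five_prime_nt, s.five_prime_chem)
    s = d.bottom
    return EndGeometry(end, WhichStrand.BOTTOM, d.right_ext, s.five_prime_nt, s.five_prime_chem)


def _trim(strand: RNAStrand, five: int, three: int) -> RNAStrand:
    n = len(strand)
    if five + three >= n:
        raise GeometryError("single-strand trimming would leave an empty strand")
    return strand.subfragment(1 + five, n - three)


def s1_trim(d: Duplex) -> Duplex:
    """Remove all single-stranded terminal nucleotides (S1 nuclease).

    Overhanging 3' or 5' termini on either strand are digested, leaving
    a duplex blunt at both ends. Idempotent; provenance intervals of the
    trimmed strands are updated.
    """
    le, re = d.left_ext, d.right_ext
    new_top = _trim(d.top, five=max(0, -le), three=max(0, re))
    new_bottom = _trim(d.bottom, five=max(0, -re), three=max(0, le))
    trimmed = replace(d, top=new_top, bottom=new_bottom, left_ext=0)
    assert trimmed.right_ext == 0
    return trimmed
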