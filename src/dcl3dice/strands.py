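"""Single RNA strands with 5' chemistry and source provenance.

A strand is always written 5'->3'. Provenance is tracked with 1-based
inclusive coordinates along the original transcript the strand (or
fragment) derives from, so that a dicing product can later be asked
whether it retains the transcript's 5' or 3' terminus. Strands produced
by RDR2 may end in an untemplated 3' nucleotide added by the enzyme's
terminal transferase activity; that tail is flagged because it is exempt
from complementarity checks and is removed by single-strand nucleases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from .errors import GeometryError

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_DNA_TO_RNA_COMPLEMENT = {"A": "U", "T": "A", "C": "G", "G": "C"}


class FivePrimeChem(str, enum.Enum):
    """Chemical state of a strand's 5' terminus."""

    OH = "OH"
    MONO_P = "MONO_P"
    TRI_P = "TRI_P"


class StrandSource(str, enum.Enum):
    """Which polymerase (or chemical synthesis) produced the strand."""

    POL_IV = "POL_IV"
    RDR2 = "RDR2"
    SYNTHETIC = "SYNTHETIC"


def complement(nt: str) -> str:
    """Watson-Crick complement of a single RNA nucleotide."""
    return _RNA_COMPLEMENT[nt]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA sequence (5'->3' in, 5'->3' out)."""
    return "".join(_RNA_COMPLEMENT[nt] for nt in reversed(seq))


def transcribe_template(window: str) -> str:
    """RNA transcript of a DNA template window, antiparallel polarity.

    The transcript is the reverse complement of the template window with
    T->U, i.e. transcript[0] pairs the window's 3'-most base.
    """
    return "".join(_DNA_TO_RNA_COMPLEMENT[nt] for nt in reversed(window))


@dataclass(frozen=True)
class RNAStrand:
    """One RNA strand, 5'->3', with chemistry and provenance.

    Parameters
    ----------
    seq
        Nucleotide string over {A, C, G, U}.
    five_prime_chem
        5'-terminal chemistry: hydroxyl, monophosphate or triphosphate.
    source
        Originating polymerase, or SYNTHETIC for designed oligos.
    source_interval
        1-based inclusive coordinates of this strand within its original
        transcript; defaults to ``(1, len(seq))`` for a full transcript.
    source_len
        Total length of the original transcript, needed to decide whether
        a fragment retains the transcript's 3' terminus. Defaults to
        ``len(seq)`` (the strand *is* the transcript).
    untemplated_tail_len
        Number of 3'-terminal nucleotides added without a template.
    template_span
        Optional 0-based half-open interval on a DNA template the
        templated part of the strand maps to, with ``template_strand``
        giving the genomic strand sense.
    """

    seq: str
    five_prime_chem: FivePrimeChem = FivePrimeChem.MONO_P
    source: StrandSource = StrandSource.SYNTHETIC
    source_interval: tuple[int, int] | None = None
    source_len: int | None = None
    untemplated_tail_len: int = 0
    template_span: tuple[int, int] | None = None
    template_strand: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise GeometryError("strand sequence must be non-empty")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise GeometryError(f"non-RNA characters in sequence: {sorted(bad)}")
        if self.untemplated_tail_len < 0 or self.untemplated_tail_len > len(self.seq):
            raise GeometryError("untemplated_tail_len outside [0, len(seq)]")
        if self.source_interval is None:
            object.__setattr__(self, "source_interval", (1, len(self.seq)))
        s, e = self.source_interval
        if e - s + 1 != len(self.seq) or s < 1:
            raise GeometryError(
                f"source_interval {self.source_interval} does not match "
                f"strand length {len(self.seq)}"
            )
        if self.source_len is None:
            object.__setattr__(self, "source_len", e)
        if self.source_len < e:
            raise GeometryError("source_len shorter than source_interval end")

    def __len__(self) -> int:
        return len(self.seq)

    def nt(self, i: int) -> str:
        """Nucleotide at 1-based position *i* counted from the 5' end."""
        return self.seq[i - 1]

    @property
    def five_prime_nt(self) -> str:
        return self.seq[0]

    @property
    def three_prime_nt(self) -> str:
        return self.seq[-1]

    def subfragment(self, start: int, end: int) -> "RNAStrand":
        """Contiguous fragment (1-based inclusive strand coordinates).

        Provenance, untemplated tail and template span are propagated;
        the tail survives only where the slice reaches the strand's 3'
        terminus region.
        """
        n = len(self.seq)
        if not (1 <= start <= end <= n):
            raise GeometryError(f"fragment [{start}, {end}] outside [1, {n}]")
        s0, _ = self.source_interval
        new_interval = (s0 + start - 1, s0 + end - 1)
        templated = n - self.untemplated_tail_len
        new_tail = max(0, end - templated)
        new_tail = min(new_tail, end - start + 1)
        tspan = None
        tstrand = self.template_strand
        if self.template_span is not None:
            a, b = self.template_span
            # clip the slice to the templated part before mapping
            t_start, t_end = start, min(end, templated)
            if t_start <= t_end:
                if self.template_strand == "-":
                    tspan = (b - t_end, b - t_start + 1)
                else:
                    tspan = (a + t_start - 1, a + t_end)
            else:
                tstrand = None
        chem = self.five_prime_chem if start == 1 else FivePrimeChem.MONO_P
        return replace(
            self,
            seq=self.seq[start - 1 : end],
            five_prime_chem=chem,
            source_interval=new_interval,
            untemplated_tail_len=new_tail,
            template_span=tspan,
            template_strand=tstrand,
        )

    def prefix(self, k: int) -> "RNAStrand":
        """The 5'-most *k* nucleotides as a fragment."""
        return self.subfragment(1, k)

    def suffix(self, k: int) -> "RNAStrand":
        """The 3'-most *k* nucleotides as a fragment."""
        return self.subfragment(len(self.seq) - k + 1, len(self.seq))
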