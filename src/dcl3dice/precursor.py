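"""Generator of Pol IV-RDR2 double-stranded siRNA precursor ensembles.

Pol IV transcribes single-stranded DNA templates into short first-strand
RNAs (~25-40 nt in vivo) that preferentially start with a purine. RDR2
then copies each Pol IV transcript into a second strand, initiating 1 or
2 nt internal to the template's 3' end (leaving a 1-2 nt 3' overhang of
the Pol IV strand at one end) and frequently appending one untemplated
3' nucleotide by terminal transferase activity (leaving a 1-nt 3'
overhang of the RDR2 strand at the other end). Pol IV transcripts behave
as 5'-monophosphorylated, RDR2 transcripts as nascent 5'-triphosphates.

The default probabilities encode these qualitative findings; exact
frequency values are not established and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .duplex import Duplex
from .errors import PreconditionError, TemplateError
from .strands import (
    DNA_ALPHABET,
    FivePrimeChem,
    RNAStrand,
    StrandSource,
    reverse_complement,
    transcribe_template,
)

# a Pol IV transcript must at least reach one product length for its
# duplex to interact meaningfully with the measuring rule
MIN_POL_LEN = 25

_NTS = ("A", "C", "G", "U")


@dataclass
class PrecursorParams:
    """Tunable features of the Pol IV / RDR2 transcription step.

    ``delta_probs`` is the distribution of the RDR2 internal-initiation
    offset (1 or 2 nt inside the Pol IV transcript's 3' end);
    ``p_untemplated`` the probability that RDR2 appends one untemplated
    3' nucleotide.
    """

    pol_len_range: tuple[int, int] = (25, 40)
    start_nt_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.50, "G": 0.30, "C": 0.15, "U": 0.05}
    )
    delta_probs: dict[int, float] = field(default_factory=lambda: {1: 0.5, 2: 0.5})
    p_untemplated: float = 0.75
    untemplated_nt_probs: dict[str, float] = field(
        default_factory=lambda: {nt: 0.25 for nt in _NTS}
    )
    pol_5p_chem: FivePrimeChem = FivePrimeChem.MONO_P
    rdr2_5p_chem: FivePrimeChem = FivePrimeChem.TRI_P

    def __post_init__(self) -> None:
        lo, hi = self.pol_len_range
        if lo < MIN_POL_LEN or hi < lo:
            raise PreconditionError(
                f"pol_len_range must satisfy {MIN_POL_LEN} <= lo <= hi"
            )
        for name, probs in (
            ("start_nt_probs", self.start_nt_probs),
            ("delta_probs", self.delta_probs),
            ("untemplated_nt_probs", self.untemplated_nt_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise PreconditionError(f"{name} must sum to 1")
        if not set(self.delta_probs) <= {1, 2}:
            raise PreconditionError("delta support must be within {1, 2}")
        if not 0.0 <= self.p_untemplated <= 1.0:
            raise PreconditionError("p_untemplated must be a probability")


def _draw(rng: np.random.Generator, probs: dict) -> object:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=[probs[k] for k in keys])]


def sample_pol_iv_transcript(
    template: str | None,
    params: PrecursorParams,
    rng: np.random.Generator,
) -> RNAStrand:
    """Draw one Pol IV first-strand transcript.

    With a DNA template, a window compatible with the drawn 5' nucleotide
    is chosen and the transcript is the reverse complement of that window
    (T->U); without one, a random sequence honouring the start draw is
    produced. The transcript's 5' nucleotide pairs the template window's
    3'-most base, so compatible start sites are template positions whose
    base is the DNA complement of the drawn nucleotide.
    """
    lo, hi = params.pol_len_range
    n = int(rng.integers(lo, hi + 1))
    start_nt = str(_draw(rng, params.start_nt_probs))
    if template is None:
        body = "".join(_NTS[i] for i in rng.integers(0, 4, size=n - 1))
        return RNAStrand(
            start_nt + body,
            five_prime_chem=params.pol_5p_chem,
            source=StrandSource.POL_IV,
        )
    template = template.upper()
    bad = set(template) - DNA_ALPHABET
    if bad:
        raise TemplateError(f"non-DNA characters in template: {sorted(bad)}")
    if len(template) < hi:
        raise TemplateError("template shorter than the maximum transcript length")
    complement_dna = {"A": "U", "T": "A", "C": "G", "G": "C"}
    # template index i (0-based) is the base copied into the transcript 5' nt
    candidates = [
        i
        for i in range(n - 1, len(template))
        if complement_dna[template[i]] == start_nt
    ]
    if not candidates:
        raise TemplateError(
            f"no start site on the template yields a transcript beginning with {start_nt}"
        )
    i = int(candidates[rng.integers(0, len(candidates))])
    window = template[i - n + 1 : i + 1]
    seq = transcribe_template(window)
    assert seq[0] == start_nt
    return RNAStrand(
        seq,
        five_prime_chem=params.pol_5p_chem,
        source=StrandSource.POL_IV,
        template_span=(i - n + 1, i + 1),
        template_strand="-",
    )


def synthesize_rdr2_strand(
    pol: RNAStrand,
    params: PrecursorParams,
    rng: np.random.Generator,
) -> Duplex:
    """Copy a Pol IV transcript into its RDR2 second strand and pair them.

    The RDR2 strand is the reverse complement of the Pol IV transcript
    minus its 3'-terminal delta nucleotides (delta in {1, 2}), optionally
    extended by one untemplated 3' nucleotide. The duplex carries a
    delta-nt 3' overhang of the Pol IV strand at the RDR2-5' end and,
    when the tail was added, a 1-nt 3' overhang of the RDR2 strand at the
    Pol IV-5' end.
    """
    n = len(pol)
    if n < MIN_POL_LEN:
        raise PreconditionError(
            f"Pol IV transcript of {n} nt too short to template RDR2 (min {MIN_POL_LEN})"
        )
    delta = int(_draw(rng, params.delta_probs))
    core = reverse_complement(pol.seq[: n - delta])
    tail = 0
    seq = core
    if rng.random() < params.p_untemplated:
        seq = core + str(_draw(rng, params.untemplated_nt_probs))
        tail = 1
    tspan = None
    tstrand = None
    if pol.template_span is not None:
        a, b = pol.template_span
        # the RDR2 strand re-reads the template window minus its 3' part,
        # in the template's own sense
        tspan = (b - (n - delta), b)
        tstrand = "+"
    rdr2 = RNAStrand(
        seq,
        five_prime_chem=params.rdr2_5p_chem,
        source=StrandSource.RDR2,
        untemplated_tail_len=tail,
        template_span=tspan,
        template_strand=tstrand,
    )
    return Duplex(pol, rdr2, left_ext=tail)


def generate_ensemble(
    template: str | None,
    n: int,
    params: PrecursorParams,
    seed: int,
) -> list[Duplex]:
    """Sample *n* independent Pol IV-RDR2 duplexes, deterministically for
    a fixed seed."""
    if n < 1:
        raise PreconditionError("ensemble size must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        synthesize_rdr2_strand(sample_pol_iv_transcript(template, params, rng), params, rng)
        for _ in range(n)
    ]
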