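"""The DCL3 dicing rule engine.

The enzyme anchors the recessed 5' terminus of one strand (the *measured*
strand) at a preferred duplex end and makes up to two cuts:

* RNase III domain B cuts the measured strand after ``measure_len``
  nucleotides (24 by default) counted from that 5' terminus — but only if
  the strand extends beyond the cut site.
* RNase III domain A cuts the complementary strand at a register offset
  by ``cut_offset`` (2 nt) so that the product carries a 2-nt 3' overhang
  of the measured strand. The complementary product length is
  ``measure_len + jitter - cut_offset + o`` where *o* is the 3' overhang
  at the engaged end.

Duplexes whose geometry already matches a dicing product (no internal
cut available at either end) are refractory and returned intact, while
duplexes shorter than the measuring rule on both strands are degraded
into a ladder of 17+ nt pieces. End choice is scored from the overhang
class, the measured 5' nucleotide and its phosphorylation state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .duplex import Duplex, End, EndGeometry, WhichStrand, end_geometry
from .errors import GeometryError, PreconditionError
from .strands import FivePrimeChem, RNAStrand


class DicingMode(str, enum.Enum):
    DICED = "DICED"
    REFRACTORY = "REFRACTORY"
    DEGRADED = "DEGRADED"
    NO_CUT = "NO_CUT"


class EndChoiceMode(str, enum.Enum):
    DETERMINISTIC = "DETERMINISTIC"
    STOCHASTIC = "STOCHASTIC"


class Scenario(str, enum.Enum):
    S1 = "S1"
    S2 = "S2"
    S3 = "S3"
    OTHER = "OTHER"


DEFAULT_NT_WEIGHTS: dict[str, float] = {"A": 1.0, "U": 1.0, "C": 0.45, "G": 0.45}
DEFAULT_CHEM_WEIGHTS: dict[FivePrimeChem, float] = {
    FivePrimeChem.MONO_P: 1.0,
    FivePrimeChem.TRI_P: 0.9,
    FivePrimeChem.OH: 0.05,
}
# o in {1, 2} is the preferred geometry; blunt ends are tolerated but
# disfavoured; 5' overhangs and overhangs > 2 are refused.
DEFAULT_OVERHANG_WEIGHTS: dict[str, float] = {
    "overhang": 1.0,
    "blunt": 0.3,
    "other": 0.0,
}


@dataclass
class DicingParams:
    """All engine constants.

    The numeric preference weights encode the qualitative orderings the
    assays establish (A = U > C = G at the measured 5' nucleotide;
    monophosphate >= triphosphate >> hydroxyl; 1-2 nt 3' overhang >
    blunt); only the orderings are constrained, the values are
    configurable.
    """

    measure_len: int = 24
    cut_offset: int = 2
    blunt_jitter: tuple[int, ...] = (-1, 0, 1)
    w_nt: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NT_WEIGHTS))
    w_chem: dict[FivePrimeChem, float] = field(
        default_factory=lambda: dict(DEFAULT_CHEM_WEIGHTS)
    )
    w_overhang: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OVERHANG_WEIGHTS)
    )
    domain_a_active: bool = True
    domain_b_active: bool = True
    end_choice_mode: EndChoiceMode = EndChoiceMode.DETERMINISTIC
    degradation_min_len: int = 17
    enable_degradation: bool = True
    allow_redicing_of_fragments: bool = False

    def __post_init__(self) -> None:
        if not (self.measure_len > self.cut_offset >= 0):
            raise PreconditionError("require measure_len > cut_offset >= 0")
        if not (self.degradation_min_len < self.measure_len):
            raise PreconditionError("require degradation_min_len < measure_len")
        for table in (self.w_nt, self.w_chem, self.w_overhang):
            if any(w < 0 for w in table.values()):
                raise PreconditionError("preference weights must be >= 0")

    def overhang_weight(self, o: int) -> float:
        if o in (1, 2):
            return self.w_overhang["overhang"]
        if o == 0:
            return self.w_overhang["blunt"]
        return self.w_overhang["other"]


@dataclass(frozen=True)
class CutPlan:
    """Where the two RNase III domains would cleave at one end.

    ``measured_cut_after`` is the 1-based measured-strand position after
    which domain B cleaves (None: no cut). ``comp_product_len`` is the
    length of the complementary-strand product released by domain A
    (None: no cut). ``valid`` requires at least one internal cut.
    """

    end: End
    jitter: int
    measured_cut_after: int | None
    comp_product_len: int | None
    valid: bool
    reason: str | None = None


@dataclass
class DicingOutcome:
    """Result of presenting one duplex to the enzyme.

    ``product`` is the proximal siRNA duplex for DICED outcomes and the
    unchanged substrate for REFRACTORY/NO_CUT (and degenerate DEGRADED)
    outcomes; DEGRADED outcomes with cuts carry all pieces in
    ``fragments`` instead. Nucleotide conservation holds across product
    strands plus fragments.
    """

    substrate_id: str | None
    mode: DicingMode
    chosen_end: End | None
    cut_plan: CutPlan | None
    product: Duplex | None
    fragments: list[RNAStrand]
    substrate: Duplex | None = None
    scenario: Scenario | None = None
    notes: dict = field(default_factory=dict)


def _strands_at(d: Duplex, end: End) -> tuple[RNAStrand, RNAStrand]:
    """(measured, complementary) strand pair for an end."""
    if end is End.LEFT:
        return d.top, d.bottom
    return d.bottom, d.top


def compute_cut_plan(
    d: Duplex, end: End, params: DicingParams, jitter: int = 0
) -> CutPlan:
    """Cut-site arithmetic for one end at one measurement register.

    The register shift *jitter* models the loose anchoring of blunt ends
    and is only admissible when the end is blunt (o = 0).
    """
    geom = end_geometry(d, end)
    o = geom.overhang
    if jitter != 0 and o != 0:
        raise PreconditionError("measurement jitter only applies to blunt ends")
    if o < 0:
        return CutPlan(end, jitter, None, None, False, reason="five_prime_overhang")
    measured, comp = _strands_at(d, end)
    L = params.measure_len + jitter
    measured_cut = L if (params.domain_b_active and 0 < L < len(measured)) else None
    p = L - params.cut_offset + o
    comp_len = p if (params.domain_a_active and 0 < p < len(comp)) else None
    valid = measured_cut is not None or comp_len is not None
    return CutPlan(end, jitter, measured_cut, comp_len, valid)


def is_refractory(d: Duplex, params: DicingParams) -> bool:
    """True if no internal cut exists at either end (at jitter 0) and the
    duplex is at least as long as a canonical product on one strand.

    This is the geometry of a dicing product — e.g. a 24/23-mer with 1-
    and 2-nt 3' overhangs — which the enzyme binds without cutting.
    """
    if max(len(d.top), len(d.bottom)) < params.measure_len:
        return False
    return not (
        compute_cut_plan(d, End.LEFT, params).valid
        or compute_cut_plan(d, End.RIGHT, params).valid
    )


def _admissible_jitters(o: int, params: DicingParams) -> tuple[int, ...]:
    return tuple(params.blunt_jitter) if o == 0 else (0,)


def score_end(d: Duplex, end: End, params: DicingParams) -> float:
    """Relative affinity of the enzyme for engaging one duplex end.

    Product of the overhang-class weight, the weight of the measured
    strand's 5' nucleotide and the weight of its 5' chemistry; zero when
    no admissible measurement register yields a cut. The identity of the
    overhanging nucleotide itself does not enter the score.
    """
    geom = end_geometry(d, end)
    o = geom.overhang
    if not any(
        compute_cut_plan(d, end, params, j).valid for j in _admissible_jitters(o, params)
    ):
        return 0.0
    return (
        params.overhang_weight(o)
        * params.w_nt[geom.m5_nt]
        * params.w_chem[geom.m5_chem]
    )


def dice_at_end(
    d: Duplex,
    end: End,
    params: DicingParams,
    jitter: int = 0,
    substrate_id: str | None = None,
) -> DicingOutcome:
    """Apply the cut plan at a forced end/register and assemble products.

    The proximal product duplex keeps the engaged end intact; distal
    pieces are released as fragments with provenance propagated.
    """
    plan = compute_cut_plan(d, end, params, jitter)
    if not plan.valid:
        return DicingOutcome(
            substrate_id, DicingMode.NO_CUT, end, plan, d, [], substrate=d,
            notes={"reason": plan.reason or "no_internal_cut"},
        )
    measured, comp = _strands_at(d, end)
    fragments: list[RNAStrand] = []
    if plan.measured_cut_after is not None:
        m_prod = measured.prefix(plan.measured_cut_after)
        fragments.append(measured.suffix(len(measured) - plan.measured_cut_after))
    else:
        m_prod = measured
    if plan.comp_product_len is not None:
        c_prod = comp.suffix(plan.comp_product_len)
        fragments.append(comp.prefix(len(comp) - plan.comp_product_len))
    else:
        c_prod = comp
    if end is End.LEFT:
        product = Duplex(m_prod, c_prod, d.left_ext, allow_gu=d.allow_gu)
    else:
        new_left = len(m_prod) - len(c_prod) + d.right_ext
        product = Duplex(c_prod, m_prod, new_left, allow_gu=d.allow_gu)
    return DicingOutcome(
        substrate_id, DicingMode.DICED, end, plan, product, fragments, substrate=d
    )


def enumerate_dicing_outcomes(
    d: Duplex, params: DicingParams, substrate_id: str | None = None
) -> list[DicingOutcome]:
    """All valid dicing outcomes over both ends and admissible registers.

    For an end with a 3' overhang the register is fixed; blunt ends are
    enumerated across the full jitter set. Refractory duplexes yield an
    empty list.
    """
    outcomes = []
    for end in (End.LEFT, End.RIGHT):
        o = end_geometry(d, end).overhang
        for j in _admissible_jitters(o, params):
            if compute_cut_plan(d, end, params, j).valid:
                outcomes.append(dice_at_end(d, end, params, j, substrate_id))
    return outcomes


def degrade(
    d: Duplex,
    params: DicingParams,
    rng: np.random.Generator,
    substrate_id: str | None = None,
) -> DicingOutcome:
    """Variable-position digestion of sub-product-size duplexes.

    Duplexes whose strands are both shorter than the measuring rule do
    not anchor in the enzyme; each strand independently receives one cut
    such that the retained 5' piece is uniform on
    ``[degradation_min_len, len - 1]``. Strands too short to cut are left
    whole; when neither strand can be cut the substrate is returned
    unchanged and flagged degenerate.
    """
    if max(len(d.top), len(d.bottom)) >= params.measure_len:
        raise PreconditionError("degradation applies only below the measured size")
    pieces: list[RNAStrand] = []
    retained_lengths: list[int | None] = []
    any_cut = False
    for strand in (d.top, d.bottom):
        n = len(strand)
        if n >= params.degradation_min_len + 1:
            k = int(rng.integers(params.degradation_min_len, n))
            pieces.append(strand.prefix(k))
            pieces.append(strand.suffix(n - k))
            retained_lengths.append(k)
            any_cut = True
        else:
            pieces.append(strand)
            retained_lengths.append(None)
    notes = {"retained_lengths": tuple(retained_lengths), "degenerate": not any_cut}
    if not any_cut:
        return DicingOutcome(
            substrate_id, DicingMode.DEGRADED, None, None, d, [], substrate=d,
            notes=notes,
        )
    return DicingOutcome(
        substrate_id, DicingMode.DEGRADED, None, None, None, pieces, substrate=d,
        notes=notes,
    )


def dice(
    d: Duplex,
    params: DicingParams,
    rng: np.random.Generator | None = None,
    substrate_id: str | None = None,
    enumerate_blunt: bool = False,
) -> DicingOutcome:
    """Full decision cascade: refractory check, degradation, end choice,
    register choice, cleavage.

    A random stream is required for stochastic end choice, blunt-end
    register draws and degradation; the deterministic path picks the
    argmax-scoring end (ties to LEFT) and register 0. With
    ``enumerate_blunt`` the outcome of a blunt engagement additionally
    records the full register enumeration under
    ``notes['jitter_enumeration']``.
    """
    # refractoriness is a property of product-like substrate geometry;
    # a catalytically dead enzyme reports NO_CUT instead
    if (params.domain_a_active or params.domain_b_active) and is_refractory(d, params):
        return DicingOutcome(
            substrate_id, DicingMode.REFRACTORY, None, None, d, [], substrate=d
        )
    if (
        params.enable_degradation
        and len(d.top) < params.measure_len
        and len(d.bottom) < params.measure_len
    ):
        if rng is None:
            raise PreconditionError("degradation requires a random stream")
        return degrade(d, params, rng, substrate_id)
    s_left = score_end(d, End.LEFT, params)
    s_right = score_end(d, End.RIGHT, params)
    if s_left == 0.0 and s_right == 0.0:
        return DicingOutcome(
            substrate_id, DicingMode.NO_CUT, None, None, d, [], substrate=d,
            notes={"reason": "both_ends_score_zero"},
        )
    if params.end_choice_mode is EndChoiceMode.DETERMINISTIC:
        end = End.LEFT if s_left >= s_right else End.RIGHT
    else:
        if rng is None:
            raise PreconditionError("stochastic end choice requires a random stream")
        total = s_left + s_right
        end = End.LEFT if rng.random() < s_left / total else End.RIGHT
    o = end_geometry(d, end).overhang
    if o == 0:
        if params.end_choice_mode is EndChoiceMode.DETERMINISTIC:
            jitter = 0
        else:
            if rng is None:
                raise PreconditionError("blunt-end register draw requires a random stream")
            jitter = int(rng.choice(np.asarray(params.blunt_jitter)))
    else:
        jitter = 0
    outcome = dice_at_end(d, end, params, jitter, substrate_id)
    if enumerate_blunt and o == 0:
        outcome.notes["jitter_enumeration"] = enumerate_dicing_outcomes(
            d, params, substrate_id
        )
    return outcome


def outcome_conserves_nucleotides(outcome: DicingOutcome) -> bool:
    """Check the multiset of nucleotides is preserved by an outcome."""
    if outcome.substrate is None:
        raise GeometryError("outcome carries no substrate reference")
    before = outcome.substrate.nucleotide_counts()
    after: dict[str, int] = {}
    seqs: Iterable[str] = [f.seq for f in outcome.fragments]
    if outcome.product is not None:
        seqs = list(seqs) + [outcome.product.top.seq, outcome.product.bottom.seq]
    for seq in seqs:
        for nt in seq:
            after[nt] = after.get(nt, 0) + 1
    return before == after
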