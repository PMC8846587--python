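"""Pool-level analysis: dice ensembles, tabulate siRNA products, classify
precursor-end scenarios and enumerate the dicing routes.

Three precursor-end configurations (scenarios) determine which end is
diced and the 24/23-nt output pattern:

* S1 — dicing at the Pol IV-strand 5' end, guided by the 1-nt 3'
  overhang left by RDR2's untemplated nucleotide: 24-nt Pol IV-strand
  siRNA paired with a 23-nt RDR2-strand siRNA.
* S2 — dicing at the RDR2-strand 5' end when RDR2 initiated 1 nt
  internal (delta = 1): 24-nt RDR2 / 23-nt Pol IV products.
* S3 — same end with delta = 2: 24-nt siRNAs from both strands.

Counting the deduplicated routes through this grid gives two ways to a
24-mer from each strand and a single way to a 23-mer from each strand,
matching the excess of 24-mers over 23-mers.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .duplex import Duplex, End, WhichStrand, end_geometry
from .engine import (
    DicingMode,
    DicingOutcome,
    DicingParams,
    Scenario,
    compute_cut_plan,
    dice,
)
from .errors import ClassificationError, PreconditionError, ProvenanceError
from .strands import RNAStrand, StrandSource, reverse_complement


class OriginEnd(str, enum.Enum):
    FIVE_PRIME = "FIVE_PRIME"
    THREE_PRIME = "THREE_PRIME"
    INTERNAL = "INTERNAL"


@dataclass
class PoolSummary:
    """Aggregated description of a diced pool.

    ``counts`` maps (product length, source strand, origin end) to a
    product-strand count; ``ratio_24_23`` is None (flagged) when the pool
    holds no 23-mers.
    """

    counts: dict[tuple[int, StrandSource, OriginEnd], int]
    ratio_24_23: float | None
    five_prime_comp: dict[str, float]
    scenario_counts: dict[Scenario, int]
    mode_counts: dict[DicingMode, int] = field(default_factory=dict)

    @property
    def ratio_defined(self) -> bool:
        return self.ratio_24_23 is not None

    def size_count(self, length: int) -> int:
        return sum(c for (sz, _, _), c in self.counts.items() if sz == length)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "length": sz,
                "source": src.value,
                "origin_end": oe.value,
                "count": c,
            }
            for (sz, src, oe), c in sorted(
                self.counts.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
            )
        ]
        return pd.DataFrame(rows, columns=["length", "source", "origin_end", "count"])


def dice_ensemble(
    duplexes: list[Duplex], params: DicingParams, seed: int
) -> list[DicingOutcome]:
    """One outcome per duplex, deterministic for a fixed seed."""
    if not duplexes:
        raise PreconditionError("empty ensemble")
    rng = np.random.default_rng(seed)
    return [
        dice(d, params, rng=rng, substrate_id=str(i)) for i, d in enumerate(duplexes)
    ]


def origin_end(product_strand: RNAStrand) -> OriginEnd:
    """Locate a product strand within its source transcript.

    FIVE_PRIME when the provenance interval starts at transcript position
    1 (taking precedence when the strand spans the whole transcript),
    THREE_PRIME when it ends at the transcript's 3' terminus, INTERNAL
    otherwise.
    """
    if product_strand.source_interval is None:
        raise ProvenanceError("strand carries no provenance interval")
    s, e = product_strand.source_interval
    if s == 1:
        return OriginEnd.FIVE_PRIME
    if product_strand.source_len is None:
        raise ProvenanceError("strand carries no source transcript length")
    if e == product_strand.source_len:
        return OriginEnd.THREE_PRIME
    return OriginEnd.INTERNAL


def classify_scenario(outcome: DicingOutcome) -> Scenario:
    """Assign the precursor-end scenario behind a DICED outcome."""
    if outcome.mode is not DicingMode.DICED:
        raise ClassificationError("only DICED outcomes carry a scenario")
    d = outcome.substrate
    if d is None:
        raise ClassificationError("outcome carries no substrate reference")
    sources = {d.top.source, d.bottom.source}
    if sources != {StrandSource.POL_IV, StrandSource.RDR2}:
        raise ClassificationError(
            "scenario labels apply only to Pol IV/RDR2 precursors"
        )
    geom = end_geometry(d, outcome.chosen_end)
    measured = d.strand(geom.measured_strand)
    comp = d.strand(
        WhichStrand.BOTTOM if geom.measured_strand is WhichStrand.TOP else WhichStrand.TOP
    )
    if measured.source is StrandSource.POL_IV:
        if geom.overhang >= 1 and comp.untemplated_tail_len >= 1:
            return Scenario.S1
        return Scenario.OTHER
    # measured strand is the RDR2 transcript; the overhang is the Pol IV
    # strand's 3' protrusion, i.e. the RDR2 internal-initiation offset
    if geom.overhang == 1:
        return Scenario.S2
    if geom.overhang == 2:
        return Scenario.S3
    return Scenario.OTHER


def _scenario_or_other(outcome: DicingOutcome) -> Scenario:
    try:
        return classify_scenario(outcome)
    except ClassificationError:
        return Scenario.OTHER


def _generic_precursor(delta: int, length: int = 30) -> Duplex:
    """A representative tail-bearing Pol IV-RDR2 duplex for route analysis."""
    base = "AGCU" * (length // 4 + 1)
    pol = RNAStrand(base[:length], source=StrandSource.POL_IV)
    rdr2 = RNAStrand(
        reverse_complement(pol.seq[: length - delta]) + "A",
        source=StrandSource.RDR2,
        untemplated_tail_len=1,
    )
    return Duplex(pol, rdr2, left_ext=1)


def enumerate_routes(params: DicingParams, precursor_len: int = 30) -> pd.DataFrame:
    """Analytic outcome table over the end x delta grid (tail present).

    Each row is one cell of {LEFT, RIGHT} x {delta 1, 2} on a generic
    precursor, with the product length contributed by each strand and the
    scenario label. The two LEFT cells give identical outcomes because
    the left end does not see delta.
    """
    if precursor_len < 27:
        raise PreconditionError("route analysis needs a precursor of >= 27 nt")
    rows = []
    for delta in (1, 2):
        d = _generic_precursor(delta, precursor_len)
        for end in (End.LEFT, End.RIGHT):
            plan = compute_cut_plan(d, end, params)
            measured, comp = (
                (d.top, d.bottom) if end is End.LEFT else (d.bottom, d.top)
            )
            m_len = plan.measured_cut_after or len(measured)
            c_len = plan.comp_product_len or len(comp)
            by_source = {measured.source: m_len, comp.source: c_len}
            scenario = (
                Scenario.S1
                if end is End.LEFT
                else (Scenario.S2 if delta == 1 else Scenario.S3)
            )
            rows.append(
                {
                    "end": end.value,
                    "delta": delta,
                    "tail": True,
                    "pol_iv_product_len": by_source[StrandSource.POL_IV],
                    "rdr2_product_len": by_source[StrandSource.RDR2],
                    "scenario": scenario.value,
                }
            )
    return pd.DataFrame(rows)


def route_counts(routes: pd.DataFrame) -> dict[tuple[StrandSource, int], int]:
    """Distinct routes to each (strand, product size).

    Grid cells with identical dicing outcomes (same end, same product
    sizes) are one route; each route contributes one product per strand.
    """
    unique = routes.drop_duplicates(
        subset=["end", "pol_iv_product_len", "rdr2_product_len"]
    )
    counts: Counter[tuple[StrandSource, int]] = Counter()
    for _, row in unique.iterrows():
        counts[(StrandSource.POL_IV, int(row["pol_iv_product_len"]))] += 1
        counts[(StrandSource.RDR2, int(row["rdr2_product_len"]))] += 1
    return dict(counts)


def tally_products(outcomes: list[DicingOutcome]) -> PoolSummary:
    """Aggregate counts, 24:23 ratio, 5' composition and scenario counts."""
    if not outcomes:
        raise PreconditionError("empty outcome list")
    counts: Counter[tuple[int, StrandSource, OriginEnd]] = Counter()
    five_prime: Counter[str] = Counter()
    scenarios: Counter[Scenario] = Counter()
    modes: Counter[DicingMode] = Counter()
    for oc in outcomes:
        modes[oc.mode] += 1
        if oc.mode is not DicingMode.DICED:
            continue
        scenarios[_scenario_or_other(oc)] += 1
        for strand in (oc.product.top, oc.product.bottom):
            counts[(len(strand), strand.source, origin_end(strand))] += 1
            five_prime[strand.five_prime_nt] += 1
    n24 = sum(c for (sz, _, _), c in counts.items() if sz == 24)
    n23 = sum(c for (sz, _, _), c in counts.items() if sz == 23)
    ratio = (n24 / n23) if n23 else None
    total5 = sum(five_prime.values())
    comp = {nt: five_prime.get(nt, 0) / total5 for nt in "ACGU"} if total5 else {}
    return PoolSummary(
        counts=dict(counts),
        ratio_24_23=ratio,
        five_prime_comp=comp,
        scenario_counts={s: scenarios.get(s, 0) for s in Scenario},
        mode_counts=dict(modes),
    )
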