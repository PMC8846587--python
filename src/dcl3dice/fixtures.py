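"""Reproducible synthetic oligo substrate panel.

Emits the full set of bench substrate geometries used to characterise
the dicer: 37-nt top strands against 37/38/39-nt bottoms (overhang
preference), the 22-25-nt permutations (measurement rule, refractory
products, degradation), the 26/27-nt domain-mutant substrate and its
2-nt-overhang variant, and the 5'-nucleotide / 5'-chemistry variants.
Sequences are arbitrary but seeded — only lengths and end geometry carry
information — and every fixture is validated through the duplex model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .duplex import Duplex
from .io import write_fasta, write_substrates_tsv
from .strands import FivePrimeChem, RNAStrand, StrandSource, complement

_NTS = ("A", "C", "G", "U")

DEFAULT_FIXTURE_SEED = 7


def random_rna(
    rng: np.random.Generator,
    length: int,
    first_nt: str | None = None,
    fixed: dict[int, str] | None = None,
) -> str:
    """Random RNA sequence with optional pinned positions (1-based)."""
    chars = [_NTS[i] for i in rng.integers(0, 4, size=length)]
    if first_nt is not None:
        chars[0] = first_nt
    for pos, nt in (fixed or {}).items():
        chars[pos - 1] = nt
    return "".join(chars)


def design_bottom_strand(
    top_seq: str,
    left_ext: int,
    bottom_len: int,
    rng: np.random.Generator,
    overhang_nt: str | None = None,
) -> str:
    """Bottom strand complementary to *top_seq* under a given registration.

    Positions pairing the top strand are Watson-Crick complements;
    overhanging positions are random unless ``overhang_nt`` pins the
    bottom strand's 3'-terminal (left-overhang) nucleotide.
    """
    lt = len(top_seq)
    right_ext = lt - bottom_len + left_ext
    chars = []
    for j in range(1, bottom_len + 1):
        i = lt - right_ext - j + 1
        if 1 <= i <= lt:
            chars.append(complement(top_seq[i - 1]))
        else:
            chars.append(_NTS[rng.integers(0, 4)])
    if overhang_nt is not None and left_ext > 0:
        chars[-1] = overhang_nt
    return "".join(chars)


def make_duplex(
    rng: np.random.Generator,
    top_len: int,
    bottom_len: int,
    left_ext: int = 0,
    top_first_nt: str | None = None,
    top_fixed: dict[int, str] | None = None,
    overhang_nt: str | None = None,
    top_chem: FivePrimeChem = FivePrimeChem.MONO_P,
    bottom_chem: FivePrimeChem = FivePrimeChem.MONO_P,
    untemplated_tail_len: int = 0,
) -> Duplex:
    """Seeded duplex of the requested lengths and registration."""
    top_seq = random_rna(rng, top_len, first_nt=top_first_nt, fixed=top_fixed)
    bottom_seq = design_bottom_strand(top_seq, left_ext, bottom_len, rng, overhang_nt)
    top = RNAStrand(top_seq, five_prime_chem=top_chem, source=StrandSource.SYNTHETIC)
    bottom = RNAStrand(
        bottom_seq,
        five_prime_chem=bottom_chem,
        source=StrandSource.SYNTHETIC,
        untemplated_tail_len=untemplated_tail_len,
    )
    return Duplex(top, bottom, left_ext)


@dataclass(frozen=True)
class _FixtureSpec:
    name: str
    figure: str
    top_len: int
    bottom_len: int
    left_ext: int = 0
    top_first_nt: str | None = None
    overhang_nt: str | None = None
    top_chem: FivePrimeChem = FivePrimeChem.MONO_P
    bottom_chem: FivePrimeChem = FivePrimeChem.MONO_P


_PANEL: tuple[_FixtureSpec, ...] = (
    # overhang-preference panel: one 37-nt top against 37/38/39-nt bottoms
    _FixtureSpec("fig1C_37_37", "Fig 1C blunt", 37, 37, 0),
    _FixtureSpec("fig1C_37_38", "Fig 1C 1-nt overhang", 37, 38, 1),
    _FixtureSpec("fig1C_37_39", "Fig 1C 2-nt overhang", 37, 39, 2),
    # measurement-rule panel
    _FixtureSpec("fig2A_24_25", "Fig 2A", 24, 25, 1),
    _FixtureSpec("fig2B_24_24", "Fig 2B blunt", 24, 24, 0),
    _FixtureSpec("fig2B_23_24", "Fig 2B recessed", 23, 24, 1),
    # refractory product mimics
    _FixtureSpec("fig2C_24_23", "Fig 2C product mimic", 24, 23, 1),
    _FixtureSpec("fig2C_24_24_2nt", "Fig 2C symmetric", 24, 24, 2),
    # sub-product degradation panel
    _FixtureSpec("fig2D_23_23", "Fig 2D", 23, 23, 0),
    _FixtureSpec("fig2D_22_22", "Fig 2D", 22, 22, 0),
    _FixtureSpec("fig2D_22_23", "Fig 2D", 22, 23, 1),
    # domain-mutant substrate and its 2-nt-overhang variant
    _FixtureSpec("fig3B_26_27", "Fig 3B", 26, 27, 1),
    _FixtureSpec("fig3Bs_26_28", "Fig 3B supplement", 26, 28, 2),
    # 5'-nucleotide preference panel
    _FixtureSpec("fig4A_5pA", "Fig 4A", 37, 38, 1, top_first_nt="A"),
    _FixtureSpec("fig4A_5pU", "Fig 4A", 37, 38, 1, top_first_nt="U"),
    _FixtureSpec("fig4A_5pC", "Fig 4A", 37, 38, 1, top_first_nt="C"),
    _FixtureSpec("fig4A_5pG", "Fig 4A", 37, 38, 1, top_first_nt="G"),
    # overhang-nucleotide neutrality panel
    _FixtureSpec("fig4B_ohA", "Fig 4B", 37, 38, 1, top_first_nt="A", overhang_nt="A"),
    _FixtureSpec("fig4B_ohU", "Fig 4B", 37, 38, 1, top_first_nt="A", overhang_nt="U"),
    _FixtureSpec("fig4B_ohC", "Fig 4B", 37, 38, 1, top_first_nt="A", overhang_nt="C"),
    _FixtureSpec("fig4B_ohG", "Fig 4B", 37, 38, 1, top_first_nt="A", overhang_nt="G"),
    # 5'-chemistry panel: 37/37 with 1-nt overhangs at both ends
    _FixtureSpec(
        "fig4C_btmOH", "Fig 4C", 37, 37, 1, top_first_nt="A",
        overhang_nt="U", bottom_chem=FivePrimeChem.OH,
    ),
    _FixtureSpec(
        "fig4C_btmP", "Fig 4C", 37, 37, 1, top_first_nt="A",
        overhang_nt="U", bottom_chem=FivePrimeChem.MONO_P,
    ),
    _FixtureSpec(
        "fig4C_btmPPP", "Fig 4C", 37, 37, 1, top_first_nt="A",
        overhang_nt="U", bottom_chem=FivePrimeChem.TRI_P,
    ),
)


def fixture_panel(seed: int = DEFAULT_FIXTURE_SEED) -> list[tuple[str, Duplex, str]]:
    """Build the full substrate panel as (id, duplex, figure) triples."""
    rng = np.random.default_rng(seed)
    out = []
    for spec in _PANEL:
        top_fixed = None
        if spec.name.startswith("fig4C"):
            # both ends need 5' A and a U overhang: the bottom 5' nt pairs
            # the top position opposite it, and the top's own 3' terminus
            # is the right-side overhang
            lt = spec.top_len
            re = lt - spec.bottom_len + spec.left_ext
            i_for_bottom5 = lt - re  # pairs bottom position 1
            top_fixed = {i_for_bottom5: "U", lt: "U"}
        d = make_duplex(
            rng,
            spec.top_len,
            spec.bottom_len,
            spec.left_ext,
            top_first_nt=spec.top_first_nt,
            top_fixed=top_fixed,
            overhang_nt=spec.overhang_nt,
            top_chem=spec.top_chem,
            bottom_chem=spec.bottom_chem,
        )
        out.append((spec.name, d, spec.figure))
    return out


def get_fixture(name: str, seed: int = DEFAULT_FIXTURE_SEED) -> Duplex:
    """One named panel substrate."""
    for sid, d, _ in fixture_panel(seed):
        if sid == name:
            return d
    raise KeyError(name)


def make_fixtures(outdir: str | Path, seed: int = DEFAULT_FIXTURE_SEED) -> Path:
    """Write the panel as a substrate TSV plus a strand FASTA.

    Byte-identical output for identical seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = fixture_panel(seed)
    named = [(sid, d) for sid, d, _ in panel]
    write_substrates_tsv(
        named,
        outdir / "substrates.tsv",
        extra={"figure": [fig for _, _, fig in panel]},
    )
    seqs: dict[str, str] = {}
    for sid, d, _ in panel:
        seqs[f"{sid}_top"] = d.top.seq
        seqs[f"{sid}_bottom"] = d.bottom.seq
    write_fasta(seqs, outdir / "strands.fasta")
    return outdir
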