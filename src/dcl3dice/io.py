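"""File formats: substrate/product TSVs, FASTA, YAML configuration.

Strand-local coordinates in TSVs are 1-based inclusive; BED-like outputs
use 0-based half-open template coordinates. Both conventions are stated
in file headers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .duplex import Duplex, build_duplex
from .engine import DicingMode, DicingOutcome, DicingParams, EndChoiceMode
from .errors import ConfigError
from .pool import PoolSummary, _scenario_or_other, origin_end
from .precursor import PrecursorParams
from .strands import FivePrimeChem, StrandSource

SUBSTRATE_COLUMNS = [
    "id",
    "top_seq",
    "bottom_seq",
    "left_ext",
    "top_5p_chem",
    "bottom_5p_chem",
    "top_source",
    "bottom_source",
    "untemplated_tail_len",
]

PRODUCT_COLUMNS = [
    "substrate_id",
    "mode",
    "end",
    "strand",
    "role",
    "length",
    "seq",
    "source",
    "origin_end",
    "scenario",
]


def read_substrates_tsv(path: str | Path) -> list[tuple[str, Duplex]]:
    """Read a substrate table into validated duplexes."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    missing = set(SUBSTRATE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"substrate TSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        d = build_duplex(
            row["top_seq"],
            row["bottom_seq"],
            left_ext=int(row["left_ext"]),
            top_chem=FivePrimeChem(row["top_5p_chem"]),
            bottom_chem=FivePrimeChem(row["bottom_5p_chem"]),
            top_source=StrandSource(row["top_source"]),
            bottom_source=StrandSource(row["bottom_source"]),
            untemplated_tail_len=int(row["untemplated_tail_len"]),
        )
        out.append((str(row["id"]), d))
    return out


def substrates_to_frame(
    named: list[tuple[str, Duplex]], extra: dict[str, list] | None = None
) -> pd.DataFrame:
    rows = []
    for sid, d in named:
        rows.append(
            {
                "id": sid,
                "top_seq": d.top.seq,
                "bottom_seq": d.bottom.seq,
                "left_ext": d.left_ext,
                "top_5p_chem": d.top.five_prime_chem.value,
                "bottom_5p_chem": d.bottom.five_prime_chem.value,
                "top_source": d.top.source.value,
                "bottom_source": d.bottom.source.value,
                "untemplated_tail_len": d.bottom.untemplated_tail_len,
            }
        )
    df = pd.DataFrame(rows, columns=SUBSTRATE_COLUMNS)
    for name, values in (extra or {}).items():
        df[name] = values
    return df


def write_substrates_tsv(
    named: list[tuple[str, Duplex]],
    path: str | Path,
    extra: dict[str, list] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("# dcl3dice substrate table; strand coordinates 1-based inclusive\n")
        substrates_to_frame(named, extra).to_csv(fh, sep="\t", index=False)


def outcomes_to_frame(outcomes: list[DicingOutcome]) -> pd.DataFrame:
    """Flatten outcomes into the per-strand products table."""
    rows = []
    for oc in outcomes:
        scenario = ""
        if oc.mode is DicingMode.DICED:
            scenario = _scenario_or_other(oc).value
        end = oc.chosen_end.value if oc.chosen_end else ""
        if oc.product is not None:
            for which, strand in (("top", oc.product.top), ("bottom", oc.product.bottom)):
                rows.append(
                    {
                        "substrate_id": oc.substrate_id,
                        "mode": oc.mode.value,
                        "end": end,
                        "strand": which,
                        "role": "product",
                        "length": len(strand),
                        "seq": strand.seq,
                        "source": strand.source.value,
                        "origin_end": origin_end(strand).value,
                        "scenario": scenario,
                    }
                )
        for frag in oc.fragments:
            rows.append(
                {
                    "substrate_id": oc.substrate_id,
                    "mode": oc.mode.value,
                    "end": end,
                    "strand": "",
                    "role": "fragment",
                    "length": len(frag),
                    "seq": frag.seq,
                    "source": frag.source.value,
                    "origin_end": origin_end(frag).value,
                    "scenario": scenario,
                }
            )
    return pd.DataFrame(rows, columns=PRODUCT_COLUMNS)


def write_products_tsv(outcomes: list[DicingOutcome], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# dcl3dice products table; lengths in nt\n")
        outcomes_to_frame(outcomes).to_csv(fh, sep="\t", index=False)


def read_products_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", dtype={"substrate_id": str}, keep_default_na=False
    )


def summary_from_products(df: pd.DataFrame) -> pd.DataFrame:
    """Length x source x origin-end counts from a products table."""
    prod = df[df["role"] == "product"]
    grouped = (
        prod.groupby(["length", "source", "origin_end"]).size().reset_index(name="count")
    )
    return grouped


def write_summary_tsv(summary: PoolSummary | pd.DataFrame, path: str | Path) -> None:
    frame = summary.to_frame() if isinstance(summary, PoolSummary) else summary
    with open(path, "w") as fh:
        fh.write("# dcl3dice pool summary\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_coverage_bed(
    outcomes: list[DicingOutcome], template_name: str, path: str | Path
) -> None:
    """BED intervals of product strands on the DNA template.

    0-based half-open coordinates; strand column gives the genomic sense
    of the RNA product ('-' for Pol IV-strand products, '+' for RDR2).
    Products without a template mapping are skipped.
    """
    lines = []
    for oc in outcomes:
        if oc.product is None:
            continue
        for strand in (oc.product.top, oc.product.bottom):
            if strand.template_span is None:
                continue
            a, b = strand.template_span
            lines.append(
                f"{template_name}\t{a}\t{b}\t{oc.substrate_id}_{strand.source.value}"
                f"\t{len(strand)}\t{strand.template_strand}"
            )
    with open(path, "w") as fh:
        fh.write("# dcl3dice product coverage; BED 0-based half-open\n")
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _params_from_dict(cls, data: dict, name: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown keys in {name} block: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key == "w_chem":
            value = {FivePrimeChem(k): float(v) for k, v in value.items()}
        elif key == "end_choice_mode":
            value = EndChoiceMode(value)
        elif key in ("pol_5p_chem", "rdr2_5p_chem"):
            value = FivePrimeChem(value)
        elif key in ("blunt_jitter", "pol_len_range"):
            value = tuple(int(v) for v in value)
        elif key == "delta_probs":
            value = {int(k): float(v) for k, v in value.items()}
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None) -> tuple[DicingParams, PrecursorParams]:
    """Load engine/generator parameter blocks from YAML.

    Recognised top-level keys: ``engine`` and ``generator``; unknown keys
    anywhere are rejected. A missing path yields the defaults.
    """
    if path is None:
        return DicingParams(), PrecursorParams()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - {"engine", "generator"}
    if unknown:
        raise ConfigError(f"unknown top-level configuration keys: {sorted(unknown)}")
    engine = _params_from_dict(DicingParams, data.get("engine", {}) or {}, "engine")
    generator = _params_from_dict(
        PrecursorParams, data.get("generator", {}) or {}, "generator"
    )
    return engine, generator
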