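"""Readers and writers: FASTA, aligned FASTA, and validated delimited tables.

All tabular output defaults to tab-separated text.  Supplementary-style
spreadsheets are expected to be pre-exported to TSV/CSV; the loader
auto-detects the delimiter, validates the schema, and quarantines malformed
rows instead of failing wholesale.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .sequences import CodingSequence, MissenseMutation

logger = logging.getLogger("gldcscore")

__all__ = [
    "read_fasta",
    "read_coding_sequence",
    "read_pairwise_alignment",
    "TableSchema",
    "load_supplementary_table",
    "mutations_to_frame",
    "write_table",
]

LABEL_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]\d+[ACDEFGHIKLMNPQRSTVWY]$")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All records of a FASTA file as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_coding_sequence(
    path: str | Path, leader_length: int = 0, record: str | None = None
) -> CodingSequence:
    """Load one coding sequence from FASTA (by record id, or the single record)."""
    records = read_fasta(path)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record is None:
        if len(records) > 1:
            raise ValueError(
                f"{path} holds {len(records)} records; pass record= to pick one"
            )
        rid, seq = records[0]
    else:
        match = [r for r in records if r[0] == record]
        if not match:
            raise ValueError(f"record {record!r} not found in {path}")
        rid, seq = match[0]
    return CodingSequence(id=rid, nucleotides=seq, leader_length=leader_length)


def read_pairwise_alignment(path: str | Path) -> tuple[str, str]:
    """Two aligned (gapped) sequences from an aligned-FASTA file."""
    records = read_fasta(path)
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 aligned records in {path}, got {len(records)}")
    (a_id, a), (b_id, b) = records
    if len(a) != len(b):
        raise ValueError(
            f"aligned lengths differ in {path}: {a_id}={len(a)}, {b_id}={len(b)}"
        )
    return a, b


@dataclass
class TableSchema:
    """Validation schema for a supplementary-style mutation table."""

    required_columns: tuple[str, ...]
    numeric_columns: tuple[str, ...] = ()
    label_column: str | None = "label"
    name: str = "table"


def _detect_sep(path: Path) -> str:
    head = path.read_text().splitlines()[:5]
    n_tab = sum(line.count("\t") for line in head)
    n_comma = sum(line.count(",") for line in head)
    return "\t" if n_tab >= n_comma else ","


def load_supplementary_table(
    path: str | Path, schema: TableSchema
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate a delimited mutation table.

    Returns ``(valid, rejected)`` frames.  Missing required columns raise a
    ``ValueError`` naming them; rows with unparseable numeric fields or
    malformed mutation labels are quarantined into ``rejected`` and logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in schema.required_columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{schema.name} {path.name}: missing required column(s) {missing}"
        )
    bad = pd.Series(False, index=df.index)
    for col in schema.numeric_columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad |= parsed.isna() & df[col].notna() | df[col].isna()
        df[col] = parsed
    if schema.label_column and schema.label_column in df.columns:
        labels = df[schema.label_column].astype(str).str.strip()
        df[schema.label_column] = labels
        bad |= ~labels.str.match(LABEL_RE)
    valid = df[~bad].reset_index(drop=True)
    rejected = df[bad].reset_index(drop=True)
    logger.info(
        "%s %s: %d rows validated, %d quarantined",
        schema.name,
        path.name,
        len(valid),
        len(rejected),
    )
    return valid, rejected


def mutations_to_frame(mutations) -> pd.DataFrame:
    """Mutation list as a table: label, positions, residues, nucleotide change."""
    rows = [
        {
            "label": m.label,
            "protein_position": m.protein_position,
            "ref_aa": m.ref_aa,
            "alt_aa": m.alt_aa,
            "cdna_position": m.cdna_position,
            "ref_base": m.ref_base,
            "alt_base": m.alt_base,
        }
        for m in mutations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "protein_position",
            "ref_aa",
            "alt_aa",
            "cdna_position",
            "ref_base",
            "alt_base",
        ],
    )


def write_table(df: pd.DataFrame, path: str | Path, *, sep: str = "\t") -> None:
    """Write a table as delimited text (tab by default), no index column."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
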