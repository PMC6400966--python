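"""Readers and writers for the plain-text formats the pipeline exchanges.

Sequences travel as FASTA; per-record metadata (nucleic acid type, host
lineage) as TSV with columns ``id``, ``nucleic_acid`` and optionally
``host_lineage``; feature matrices as TSV with the schema names as header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .features import FEATURE_NAMES, NucleicAcid, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "load_records",
    "write_feature_matrix",
    "read_feature_matrix",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Return (id, sequence) pairs for every record in a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-record metadata table; ``id`` and ``nucleic_acid`` required."""
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"id", "nucleic_acid"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return meta.set_index("id", drop=False)


def write_metadata(path: str | Path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t", index=False)


def load_records(fasta_path: str | Path, metadata_path: str | Path) -> list[SequenceRecord]:
    """Join a FASTA file with its metadata table into sequence records."""
    meta = read_metadata(metadata_path)
    records = []
    for name, seq in read_fasta(fasta_path):
        if name not in meta.index:
            raise KeyError(f"record {name!r} absent from metadata table")
        row = meta.loc[name]
        lineage = row.get("host_lineage", "") or None
        records.append(
            SequenceRecord(
                id=name,
                residues=seq,
                nucleic_acid=NucleicAcid.coerce(row["nucleic_acid"]),
                host_lineage=lineage,
            )
        )
    return records


def write_feature_matrix(path: str | Path, X: pd.DataFrame) -> None:
    if tuple(X.columns) != FEATURE_NAMES:
        raise ValueError("feature matrix columns do not match the feature schema")
    X.to_csv(path, sep="\t", index_label="id")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    X = pd.read_csv(path, sep="\t", index_col="id")
    if tuple(X.columns) != FEATURE_NAMES:
        raise ValueError("feature matrix columns do not match the feature schema")
    return X
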