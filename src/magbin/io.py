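"""FASTA and TSV I/O helpers shared by the CLI and the simulator."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records) -> None:
    """Write (id, sequence) pairs (or a dict) as FASTA."""
    if isinstance(records, dict):
        records = records.items()
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix with row ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.rename_axis(index_label).to_csv(path, sep="\t")


def read_two_column_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (e.g. KO -> function) into a multimap."""
    df = pd.read_csv(path, sep="\t", header=None, names=["key", "value"], dtype=str)
    out: dict[str, set[str]] = {}
    for k, v in zip(df["key"], df["value"]):
        out.setdefault(k, set()).add(v)
    return out
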