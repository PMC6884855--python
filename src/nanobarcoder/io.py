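"""FASTA/FASTQ and tabular IO (thin wrappers over Biopython/pandas)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .demux import Read


def read_sequences(path) -> list[Read]:
    """Read FASTA or FASTQ (by extension) into Read objects."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [Read(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), fmt)]


def write_fasta(records: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="")
            for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(reads: list[tuple[str, str]], path, quality: int = 12) -> None:
    """Write reads with a uniform placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{chr(33 + quality) * len(seq)}\n")


def read_layout(path) -> pd.DataFrame:
    """Plate-layout CSV: plate, well, specimen_id, fwd_tag, rev_tag,
    is_negative."""
    df = pd.read_csv(path)
    required = {"plate", "well", "specimen_id", "fwd_tag", "rev_tag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"layout missing columns: {sorted(missing)}")
    if "is_negative" not in df.columns:
        df["is_negative"] = False
    df["is_negative"] = df["is_negative"].astype(bool)
    return df


def write_layout(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
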