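"""Readers and writers: FASTA input, BED/TSV hit output, summary tables."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .core import NucleotideSequence, PQSHit

__all__ = [
    "read_fasta",
    "write_bed",
    "write_hits_tsv",
    "read_hits_tsv",
    "write_summary_tsv",
    "read_grouping",
]


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (possibly gzipped) multi-record FASTA file."""
    path = Path(path)
    if path.suffix == ".gz":
        handle = gzip.open(path, "rt")
    else:
        handle = open(path)
    with handle:
        records = [
            NucleotideSequence(rec.id, str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, residues) pairs as FASTA, 70 columns per line."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_bed(hits: Sequence[PQSHit], path: str | Path) -> None:
    """BED6: name = region sequence, score = region score x 100 (rounded),
    strand + for G-rich / - for C-rich."""
    with open(path, "w") as fh:
        for h in hits:
            name = h.sequence if h.sequence is not None else "."
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{name}\t"
                f"{round(h.region_score * 100)}\t{'+' if h.sign > 0 else '-'}\n"
            )


_HIT_COLUMNS = [
    "seq_id",
    "start",
    "end",
    "length",
    "strand",
    "region_score",
    "max_window_score",
    "sequence",
]


def hits_frame(hits: Sequence[PQSHit]) -> pd.DataFrame:
    """Hits as a DataFrame with 1-based inclusive user-facing coordinates."""
    return pd.DataFrame(
        [
            {
                "seq_id": h.seq_id,
                "start": h.start + 1,  # 1-based inclusive for text output
                "end": h.end,
                "length": h.length,
                "strand": "+" if h.sign > 0 else "-",
                "region_score": h.region_score,
                "max_window_score": h.max_window_score,
                "sequence": h.sequence,
            }
            for h in hits
        ],
        columns=_HIT_COLUMNS,
    )


def write_hits_tsv(hits: Sequence[PQSHit], path: str | Path) -> None:
    hits_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[PQSHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        PQSHit(
            seq_id=str(r.seq_id),
            start=int(r.start) - 1,
            end=int(r.end),
            sign=1 if r.strand == "+" else -1,
            region_score=float(r.region_score),
            max_window_score=float(r.max_window_score),
            sequence=None if pd.isna(r.sequence) else str(r.sequence),
        )
        for r in df.itertuples()
    ]


def write_summary_tsv(summaries, path: str | Path) -> None:
    """Per-assembly metrics table (one row per assembly)."""
    from .genome import summary_frame

    summary_frame(summaries).to_csv(path, sep="\t", index=False)


def read_grouping(path: str | Path) -> pd.DataFrame:
    """Cohort sheet: columns assembly_id, group[, subgroup]; CSV or TSV."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"assembly_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"grouping sheet misses columns: {sorted(missing)}")
    return df
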