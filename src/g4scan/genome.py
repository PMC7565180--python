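"""Whole-assembly scanning and per-genome PQS metrics.

For each assembly (one or more FASTA records: chromosomes, plasmids,
contigs) this module computes the quantities used throughout the cohort
analysis: GC%, total merged PQS count, PQS frequency per kbp, %PQS (the
fraction of nucleotides lying inside any detected G4-prone region — the
probability that a random nucleotide is part of a PQS), and counts of hits
per score-magnitude bin.

Records are scanned independently: contigs are unlinked, so no window spans
a record boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import G4Params, NucleotideSequence, PQSHit, detect_hits

__all__ = [
    "GenomeSummary",
    "BIN_EDGES",
    "BIN_LABELS",
    "gc_content",
    "scan_assembly",
    "window_size_study",
    "summary_frame",
]

# Hit score-magnitude bins.  Upper edges of the first four bins; the last
# bin is unbounded.  The lowest bin is open below: a merged region's mean
# can be diluted under the window threshold by zero-score bases inside the
# merged window union, and every detected hit must land in exactly one bin.
BIN_EDGES = (1.4, 1.6, 1.8, 2.0)
BIN_LABELS = ("1.2-1.4", "1.4-1.6", "1.6-1.8", "1.8-2.0", ">2.0")


@dataclass(frozen=True)
class GenomeSummary:
    """Per-assembly metrics: one summary row per scanned assembly."""

    assembly_id: str
    total_length: int
    gc_percent: float
    pqs_count: int
    freq_per_kbp: float
    pqs_coverage_percent: float
    bin_counts: tuple[int, int, int, int, int]


def gc_content(assembly: list[NucleotideSequence] | NucleotideSequence) -> float:
    """GC percentage over all records.

    Ambiguity codes (N, R, Y, ...) are excluded from both numerator and
    denominator; U counts as T.  An assembly with zero unambiguous bases is
    an error.
    """
    if isinstance(assembly, NucleotideSequence):
        assembly = [assembly]
    if not assembly:
        raise ValueError("empty assembly")
    gc = at = 0
    for rec in assembly:
        s = rec.residues.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T") + s.count("U")
    if gc + at == 0:
        raise ValueError("assembly contains no unambiguous bases")
    return 100.0 * gc / (gc + at)


def bin_hits(hits: list[PQSHit]) -> tuple[int, int, int, int, int]:
    """Count hits per |region_score| bin; the five bins partition the hits."""
    mags = np.array([abs(h.region_score) for h in hits])
    counts = [0] * 5
    if mags.size:
        idx = np.searchsorted(BIN_EDGES, mags, side="right")
        for i in idx:
            counts[i] += 1
    return tuple(counts)


def _covered_positions(hits: list[PQSHit]) -> int:
    """Number of distinct positions covered by any hit on one record,
    counting a nucleotide once even under overlapping +/- hits."""
    if not hits:
        return 0
    ivals = sorted((h.start, h.end) for h in hits)
    total = 0
    cur_s, cur_e = ivals[0]
    for s, e in ivals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def scan_assembly(
    assembly: list[NucleotideSequence],
    params: G4Params = G4Params(),
    assembly_id: str | None = None,
    trim: bool = False,
) -> tuple[GenomeSummary, list[PQSHit]]:
    """Scan every record of an assembly and pool the metrics."""
    if not assembly:
        raise ValueError("empty assembly")
    if assembly_id is None:
        assembly_id = assembly[0].id
    all_hits: list[PQSHit] = []
    covered = 0
    for rec in assembly:
        hits = detect_hits(rec, params, trim=trim)
        covered += _covered_positions(hits)
        all_hits.extend(hits)
    total_length = sum(len(r) for r in assembly)
    count = len(all_hits)
    summary = GenomeSummary(
        assembly_id=assembly_id,
        total_length=total_length,
        gc_percent=gc_content(assembly),
        pqs_count=count,
        freq_per_kbp=count / total_length * 1000.0,
        pqs_coverage_percent=covered / total_length * 100.0,
        bin_counts=bin_hits(all_hits),
    )
    return summary, all_hits


def window_size_study(
    assembly: list[NucleotideSequence],
    windows: list[int],
    threshold: float = 1.2,
    check: bool = True,
) -> list[int]:
    """Hit counts for a series of window sizes at a fixed threshold.

    Windows must be sorted ascending; counts are expected to be
    non-increasing with window size (longer windows demand sustained G
    density and merge neighbouring motifs) and this is asserted when
    ``check`` is true.
    """
    if sorted(windows) != list(windows):
        raise ValueError("windows must be sorted ascending")
    counts = []
    for w in windows:
        params = G4Params(window=w, threshold=threshold)
        counts.append(sum(len(detect_hits(rec, params)) for rec in assembly))
    if check and any(b > a for a, b in zip(counts, counts[1:])):
        raise AssertionError(
            f"hit counts not non-increasing over windows {windows}: {counts}"
        )
    return counts


def summary_frame(summaries: list[GenomeSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "assembly_id": s.assembly_id,
            "total_length": s.total_length,
            "gc_percent": s.gc_percent,
            "pqs_count": s.pqs_count,
            "freq_per_kbp": s.freq_per_kbp,
            "pqs_coverage_percent": s.pqs_coverage_percent,
        }
        row.update(dict(zip(BIN_LABELS, s.bin_counts)))
        rows.append(row)
    return pd.DataFrame(rows)
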