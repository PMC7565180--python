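"""PQS density inside annotated feature classes.

Annotations come either from NCBI tab-delimited feature tables
(``*_feature_table.txt``) or from GFF3.  Features are grouped into the
classes gene, rRNA, tRNA, ncRNA and repeat_region (anything else is kept as
``other:<label>``), coordinates are normalized to 0-based half-open, and
the PQS density of a class is the number of hits overlapping the class's
interval union, per kbp of union length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import pyranges as pr

from .core import PQSHit

__all__ = [
    "FeatureRecord",
    "FeatureDensity",
    "CANONICAL_CLASSES",
    "read_features",
    "feature_densities",
]

CANONICAL_CLASSES = ("gene", "rRNA", "tRNA", "ncRNA", "repeat_region")
_CANON = {c.lower(): c for c in CANONICAL_CLASSES}
_CANON["repeat region"] = "repeat_region"


@dataclass(frozen=True)
class FeatureRecord:
    seq_id: str
    feature_class: str
    start: int  # 0-based half-open
    end: int
    strand: str = "unknown"  # '+', '-' or 'unknown'

    def __post_init__(self) -> None:
        if not self.feature_class:
            raise ValueError("feature_class must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"feature on {self.seq_id} has start {self.start} >= end {self.end}"
            )


@dataclass(frozen=True)
class FeatureDensity:
    feature_class: str
    total_feature_length: int  # union of same-class intervals, in bases
    pqs_inside: int
    density_per_kbp: float


def _classify(label: str) -> str:
    label = label.strip()
    return _CANON.get(label.lower(), f"other:{label}")


def _read_ncbi_feature_table(path: Path) -> list[FeatureRecord]:
    records: list[FeatureRecord] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("# ").split("\t")
                continue
            fields = line.split("\t")
            if header is None:
                raise ValueError(f"{path}:{lineno}: data before '# feature' header")
            row = dict(zip(header, fields))
            try:
                start = int(row["start"])  # 1-based inclusive in the file
                end = int(row["end"])
                seq_id = row["genomic_accession"]
                label = row["feature"]
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if start > end:  # minus-strand rows may be printed reversed
                start, end = end, start
            strand = row.get("strand", "")
            records.append(
                FeatureRecord(
                    seq_id=seq_id,
                    feature_class=_classify(label),
                    start=start - 1,
                    end=end,
                    strand=strand if strand in "+-" and strand else "unknown",
                )
            )
    return records


def _read_gff3(path: Path) -> list[FeatureRecord]:
    records: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 ({exc})") from exc
            records.append(
                FeatureRecord(
                    seq_id=feat.seqid,
                    feature_class=_classify(feat.featuretype),
                    start=feat.start - 1,  # GFF3 is 1-based inclusive
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "unknown",
                )
            )
    return records


def read_features(path: str | Path, dialect: str) -> list[FeatureRecord]:
    """Read annotations in the given dialect ('ncbi_feature_table' or 'gff3')."""
    path = Path(path)
    if dialect == "ncbi_feature_table":
        return _read_ncbi_feature_table(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _class_ranges(
    features: Sequence[FeatureRecord], flank: int
) -> dict[str, pr.PyRanges]:
    by_class: dict[str, dict[str, list]] = {}
    for f in features:
        d = by_class.setdefault(f.feature_class, {"c": [], "s": [], "e": []})
        d["c"].append(f.seq_id)
        d["s"].append(max(0, f.start - flank))
        d["e"].append(f.end + flank)
    return {
        cls: pr.PyRanges(
            chromosomes=d["c"], starts=d["s"], ends=d["e"]
        ).merge()
        for cls, d in by_class.items()
    }


def feature_densities(
    hits: Sequence[PQSHit],
    features: Sequence[FeatureRecord],
    assign: str = "overlap",
    flank: int = 0,
) -> list[FeatureDensity]:
    """PQS density per feature class.

    A hit counts toward a class if it overlaps the class's interval union by
    at least one nucleotide (``assign='overlap'``), lies entirely inside it
    (``'containment'``), or has its midpoint inside it (``'midpoint'``).
    One hit may count toward several classes, but at most once per class.
    Strand is ignored: the hit's sign already encodes which strand carries
    the G-rich motif.  ``flank`` widens every feature by that many bases on
    both sides before building the union ("around features").
    """
    if assign not in ("overlap", "containment", "midpoint"):
        raise ValueError(f"unknown assignment rule {assign!r}")
    class_pr = _class_ranges(features, flank)
    if not class_pr:
        return []
    if hits:
        if assign == "midpoint":
            mids = [(h.start + h.end) // 2 for h in hits]
            hits_pr = pr.PyRanges(
                chromosomes=[h.seq_id for h in hits],
                starts=mids,
                ends=[m + 1 for m in mids],
            )
        else:
            hits_pr = pr.PyRanges(
                chromosomes=[h.seq_id for h in hits],
                starts=[h.start for h in hits],
                ends=[h.end for h in hits],
            )
        hits_pr.hit_id = list(range(len(hits)))
    else:
        hits_pr = None

    out = []
    for cls in sorted(class_pr):
        cpr = class_pr[cls]
        union_len = int((cpr.End - cpr.Start).sum())
        n = 0
        if hits_pr is not None:
            how = "containment" if assign == "containment" else None
            ov = hits_pr.overlap(cpr, how=how)
            n = 0 if ov.empty else int(ov.df["hit_id"].nunique())
        out.append(
            FeatureDensity(
                feature_class=cls,
                total_feature_length=union_len,
                pqs_inside=n,
                density_per_kbp=n / union_len * 1000.0,
            )
        )
    return out


def densities_frame(
    densities: Iterable[FeatureDensity],
    genome_freq_per_kbp: float | None = None,
) -> pd.DataFrame:
    """Densities as a table, optionally with a genome-average comparison row."""
    rows = [
        {
            "feature_class": d.feature_class,
            "total_feature_length": d.total_feature_length,
            "pqs_inside": d.pqs_inside,
            "density_per_kbp": d.density_per_kbp,
        }
        for d in densities
    ]
    if genome_freq_per_kbp is not None:
        rows.append(
            {
                "feature_class": "genome_average",
                "total_feature_length": pd.NA,
                "pqs_inside": pd.NA,
                "density_per_kbp": genome_freq_per_kbp,
            }
        )
    return pd.DataFrame(rows)
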