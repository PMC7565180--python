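"""Synthetic genomes, cohorts and annotations with exact ground truth.

Every pipeline stage is testable without downloads: this module builds
genomes of chosen length and GC content, plants G-rich motif templates of
known score class at non-overlapping positions, and writes matching
annotation tables with a chosen PQS enrichment per feature class.

Planting guarantees exactness, not approximation: each planted motif is
flanked by zero-score A/T buffers of at least one detection window on each
side, so at default parameters it yields exactly one merged hit whose
extent and region score are fixed properties of the template (verified
against an independent brute-force scorer and frozen below).  On an
A/T-only background the detected hit count therefore equals the planted
count, with zero false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import NucleotideSequence
from .features import FeatureRecord

__all__ = [
    "PlantedTemplate",
    "TEMPLATES",
    "SynthSpec",
    "GroundTruth",
    "make_genome",
    "make_cohort",
    "make_features",
    "write_feature_table",
    "write_gff3",
]


@dataclass(frozen=True)
class PlantedTemplate:
    """A motif template with its frozen detection outcome.

    ``left_ext``/``right_ext`` give how far the merged hit extends into
    zero-score flanks at the default window (25) and threshold (1.2);
    ``region_score`` is the merged region's mean score, whose magnitude bin
    is the template's declared score class.
    """

    sequence: str
    whole_score: float
    left_ext: int
    right_ext: int
    region_score: float

    @property
    def region_length(self) -> int:
        return self.left_ext + len(self.sequence) + self.right_ext

    def expected_hit(self, plant_start: int) -> tuple[int, int]:
        """Expected merged-hit interval for a motif planted at plant_start."""
        return (
            plant_start - self.left_ext,
            plant_start + len(self.sequence) + self.right_ext,
        )


# Score-class templates, keyed by the |region_score| bin of the single hit
# each yields when planted between zero-score flanks (defaults: window 25,
# threshold 1.2).  Extents/scores were computed with an independent
# brute-force run-length scorer and are re-checked against detect_hits in
# the test suite.
TEMPLATES: dict[str, PlantedTemplate] = {
    "1.2-1.4": PlantedTemplate("GGAGGGGAGGGTGGGGAGGGGTGG", 2.7083, 12, 14, 1.3),
    "1.4-1.6": PlantedTemplate("GGGGATGGGTTGTAGAAGTAGTGGGG", 1.7308, 2, 2, 1.5),
    "1.6-1.8": PlantedTemplate(
        "GGAGGGGTAGGGGTAGGGGTGGGGTGGGGTGGGGAGGGG", 2.9744, 13, 16, 1.7058824
    ),
    "1.8-2.0": PlantedTemplate(
        "GGGGGGGGGGGGGGGGGGGGGGGAGGGGGGG", 3.8710, 17, 16, 1.875
    ),
    ">2.0": PlantedTemplate("G" * 36, 4.0, 17, 17, 2.0571429),
}


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic genome.

    ``planted_motifs`` is a list of (template key or raw sequence, count,
    min_spacing) triples.  ``gc_percent`` sets the iid background
    composition; 0 gives a pure A/T (zero-score) background on which planted
    hit counts are exact.  ``block_gc`` optionally switches the background
    to first-order blocks alternating between two GC levels, to mimic
    GC-skewed genomes.
    """

    genome_length: int
    gc_percent: float = 0.0
    planted_motifs: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0
    block_gc: tuple[float, float] | None = None
    block_length: int = 5000


@dataclass(frozen=True)
class PlantedMotif:
    name: str
    start: int  # motif coordinates, 0-based half-open
    end: int
    expected_hit_start: int
    expected_hit_end: int
    region_score: float


@dataclass(frozen=True)
class GroundTruth:
    genome_length: int
    motifs: tuple[PlantedMotif, ...]
    features: tuple[FeatureRecord, ...] = ()

    @property
    def expected_hit_intervals(self) -> list[tuple[int, int]]:
        return [(m.expected_hit_start, m.expected_hit_end) for m in self.motifs]


_BUFFER = 30  # zero-score flank per side; > default window so hits never merge


def _resolve_template(key: str) -> PlantedTemplate:
    if key in TEMPLATES:
        return TEMPLATES[key]
    # raw sequence: extents unknown -> conservatively assume no extension
    return PlantedTemplate(key, 0.0, 0, 0, float("nan"))


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p_gc = gc / 100.0
    return rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8),
        size=n,
        p=[(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2],
    )


def make_genome(
    spec: SynthSpec, seq_id: str = "synth"
) -> tuple[NucleotideSequence, GroundTruth]:
    """Build one genome according to ``spec``; deterministic for fixed seed."""
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length

    if spec.block_gc is not None:
        lo, hi = spec.block_gc
        chunks = []
        pos = 0
        k = 0
        while pos < L:
            n = min(spec.block_length, L - pos)
            chunks.append(_background(rng, n, lo if k % 2 == 0 else hi))
            pos += n
            k += 1
        genome = np.concatenate(chunks)
    else:
        genome = _background(rng, L, spec.gc_percent)

    # slot = buffer + motif + buffer (+ extra spacing), placed left to right
    # with the leftover length shared out as random gaps
    slots = []
    for key, count, min_spacing in spec.planted_motifs:
        tmpl = _resolve_template(key)
        pad = max(_BUFFER, min_spacing)
        for _ in range(count):
            slots.append((key, tmpl, pad))
    rng.shuffle(slots)
    total_slot = sum(len(t.sequence) + 2 * pad for _, t, pad in slots)
    if total_slot > L:
        raise ValueError(
            f"infeasible packing: {total_slot} bases of motifs+buffers "
            f"exceed genome length {L}"
        )
    free = L - total_slot
    gaps = rng.multinomial(free, np.ones(len(slots) + 1) / (len(slots) + 1))

    motifs = []
    pos = 0
    at = np.frombuffer(b"AT", dtype=np.uint8)
    for i, (key, tmpl, pad) in enumerate(slots):
        pos += int(gaps[i])
        mstart = pos + pad
        mend = mstart + len(tmpl.sequence)
        # zero-score flanks so the planted hit is exact and cannot merge
        genome[pos : pos + pad] = rng.choice(at, size=pad)
        genome[mend : mend + pad] = rng.choice(at, size=pad)
        genome[mstart:mend] = np.frombuffer(
            tmpl.sequence.encode("ascii"), dtype=np.uint8
        )
        hs, he = tmpl.expected_hit(mstart)
        motifs.append(
            PlantedMotif(key, mstart, mend, hs, he, tmpl.region_score)
        )
        pos = mend + pad
    seq = NucleotideSequence(seq_id, genome.tobytes().decode("ascii"))
    return seq, GroundTruth(L, tuple(sorted(motifs, key=lambda m: m.start)))


def make_cohort(
    density_plan: dict[str, float],
    genomes_per_group: int = 3,
    genome_length: int = 100_000,
    seed: int = 0,
    template: str = "1.4-1.6",
    outdir: str | Path | None = None,
) -> tuple[dict[str, list[tuple[NucleotideSequence, GroundTruth]]], dict[str, str]]:
    """Build a cohort of genomes with planted per-group PQS densities.

    ``density_plan`` maps group label to planted hits per kbp (an outlier
    group can be given >= 4x the others' density).  Backgrounds are A/T so
    recovered frequencies equal planted densities up to rounding.  Returns
    (genomes by group, grouping map assembly_id -> group); with ``outdir``
    also writes per-genome FASTA, a grouping sheet and a ground-truth TSV.
    """
    rng = np.random.default_rng(seed)
    cohort: dict[str, list[tuple[NucleotideSequence, GroundTruth]]] = {}
    grouping: dict[str, str] = {}
    for group, density in density_plan.items():
        cohort[group] = []
        for i in range(genomes_per_group):
            count = round(density * genome_length / 1000.0)
            spec = SynthSpec(
                genome_length=genome_length,
                gc_percent=0.0,
                planted_motifs=((template, count, _BUFFER),),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            aid = f"{group}_g{i}"
            cohort[group].append(make_genome(spec, seq_id=aid))
            grouping[aid] = group
    if outdir is not None:
        _write_cohort(cohort, grouping, Path(outdir))
    return cohort, grouping


def _write_cohort(cohort, grouping, outdir: Path) -> None:
    from .io import write_fasta

    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "grouping.tsv", "w") as fh:
        fh.write("assembly_id\tgroup\tsubgroup\n")
        for aid, group in grouping.items():
            fh.write(f"{aid}\t{group}\t{group}\n")
    with open(outdir / "ground_truth.tsv", "w") as fh:
        fh.write("assembly_id\tmotif\tstart\tend\texpected_hit_start\t"
                 "expected_hit_end\tregion_score\n")
        for group, genomes in cohort.items():
            for seq, truth in genomes:
                write_fasta([(seq.id, seq.residues)], outdir / f"{seq.id}.fasta")
                for m in truth.motifs:
                    fh.write(
                        f"{seq.id}\t{m.name}\t{m.start}\t{m.end}\t"
                        f"{m.expected_hit_start}\t{m.expected_hit_end}\t"
                        f"{m.region_score}\n"
                    )


@dataclass(frozen=True)
class FeaturePlan:
    """Per-class annotation plan: number of intervals, interval length, and
    PQS enrichment factor relative to the genome-average density."""

    feature_class: str
    n_intervals: int
    interval_length: int
    enrichment: float = 1.0


def make_features(
    genome: NucleotideSequence,
    truth: GroundTruth,
    plans: list[FeaturePlan],
    seed: int = 0,
) -> list[FeatureRecord]:
    """Place annotation intervals realizing each plan's PQS enrichment.

    For a class with union length U on a genome of length L carrying H
    expected hits, enrichment E requires k = round(E * H * U / L) hits
    inside the class union; k intervals are centred on distinct expected
    hits and the remaining intervals go to hit-free gaps.  Intervals of one
    class never overlap, so U is exactly n_intervals * interval_length.
    """
    rng = np.random.default_rng(seed)
    L = truth.genome_length
    hit_ivals = sorted(truth.expected_hit_intervals)
    H = len(hit_ivals)
    out: list[FeatureRecord] = []

    def overlaps(s: int, e: int, ivals) -> bool:
        return any(s < ie and is_ < e for is_, ie in ivals)

    for plan in plans:
        U = plan.n_intervals * plan.interval_length
        k = round(plan.enrichment * H * U / L) if H else 0
        if k > min(plan.n_intervals, H):
            raise ValueError(
                f"infeasible plan for {plan.feature_class}: needs {k} "
                f"hit-containing intervals, have {plan.n_intervals} intervals "
                f"and {H} hits"
            )
        chosen = rng.choice(H, size=k, replace=False) if k else np.array([], int)
        placed: list[tuple[int, int]] = []
        for idx in chosen:
            hs, he = hit_ivals[int(idx)]
            if he - hs > plan.interval_length:
                raise ValueError(
                    f"interval_length {plan.interval_length} shorter than "
                    f"hit of length {he - hs}"
                )
            pad = (plan.interval_length - (he - hs)) // 2
            s = max(0, min(hs - pad, L - plan.interval_length))
            e = s + plan.interval_length
            if overlaps(s, e, placed):
                raise ValueError(
                    f"infeasible plan for {plan.feature_class}: "
                    "hit-centred intervals collide"
                )
            placed.append((s, e))
        # remaining intervals in gaps free of hits and of this class's intervals
        need = plan.n_intervals - k
        attempts = 0
        while need > 0:
            attempts += 1
            if attempts > 10_000:
                raise ValueError(
                    f"infeasible plan for {plan.feature_class}: cannot place "
                    f"{need} hit-free intervals"
                )
            s = int(rng.integers(0, L - plan.interval_length + 1))
            e = s + plan.interval_length
            if overlaps(s, e, hit_ivals) or overlaps(s, e, placed):
                continue
            placed.append((s, e))
            need -= 1
        for s, e in sorted(placed):
            out.append(
                FeatureRecord(
                    seq_id=genome.id,
                    feature_class=plan.feature_class,
                    start=s,
                    end=e,
                    strand="+",
                )
            )
    return out


def write_feature_table(
    features: list[FeatureRecord], path: str | Path, assembly: str = "synth_asm"
) -> None:
    """NCBI feature-table dialect (tab-delimited, 1-based inclusive)."""
    cols = [
        "feature", "class", "assembly", "assembly_unit", "seq_type",
        "chromosome", "genomic_accession", "start", "end", "strand",
    ]
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(cols) + "\n")
        for f in features:
            label = f.feature_class.removeprefix("other:")
            strand = f.strand if f.strand in "+-" else "?"
            fh.write(
                f"{label}\tprotein_coding\t{assembly}\tPrimary Assembly\t"
                f"chromosome\t\t{f.seq_id}\t{f.start + 1}\t{f.end}\t{strand}\n"
            )


def write_gff3(features: list[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            label = f.feature_class.removeprefix("other:")
            strand = f.strand if f.strand in "+-" else "."
            fh.write(
                f"{f.seq_id}\tg4scan_synth\t{label}\t{f.start + 1}\t{f.end}\t"
                f".\t{strand}\t.\tID=feat{i}\n"
            )
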