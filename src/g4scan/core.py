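"""G4Hunter per-base scoring, windowed scoring and merged PQS detection.

The G4Hunter score of a nucleotide sequence is the arithmetic mean of
per-base contributions: each base inside a maximal run of ``k`` consecutive
guanines scores ``+min(k, 4)``, each base in a run of ``k`` cytosines scores
``-min(k, 4)``, and every other base scores 0.  A positive score therefore
marks G-richness (quadruplex on the given strand), a negative score
C-richness (quadruplex on the complementary strand), and the magnitude —
capped at 4 — tracks quadruplex-forming propensity.

Putative quadruplex sequences (PQS) are found by sliding a fixed window
(default 25 nt) along the sequence and keeping windows whose mean score
reaches the threshold (default 1.2) in absolute value; overlapping or
abutting qualifying windows of the same sign are merged into one hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NucleotideSequence",
    "ScoredSequence",
    "G4Params",
    "PQSHit",
    "base_scores",
    "score_sequence",
    "window_scores",
    "detect_hits",
    "reverse_complement",
]

# IUPAC nucleotide alphabet; U is treated as T so RNA can be scanned unchanged.
_IUPAC = set("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def reverse_complement(residues: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (U -> A)."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence over the IUPAC alphabet.

    ``residues`` is validated at construction: it must be non-empty and may
    only contain IUPAC nucleotide codes (case-insensitive; T and U are
    equivalent).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - _IUPAC
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, reverse_complement(self.residues))


@dataclass(frozen=True)
class G4Params:
    """Detection parameters: sliding-window size and score threshold."""

    window: int = 25
    threshold: float = 1.2

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass(frozen=True)
class ScoredSequence:
    sequence: NucleotideSequence
    base_scores: np.ndarray  # int8, one entry per residue, each in [-4, 4]


@dataclass(frozen=True)
class PQSHit:
    """One merged G4-prone region (0-based half-open coordinates).

    sign is +1 for a G-rich hit (quadruplex on the scanned strand) and -1
    for a C-rich hit (quadruplex on the complement).  ``region_score`` is the
    mean per-base score over [start, end); ``max_window_score`` the most
    extreme qualifying window mean inside the region.
    """

    seq_id: str
    start: int
    end: int
    sign: int
    region_score: float
    max_window_score: float
    sequence: str | None = field(default=None, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start


def _coerce(seq: NucleotideSequence | str) -> NucleotideSequence:
    if isinstance(seq, NucleotideSequence):
        return seq
    return NucleotideSequence("seq", seq)


def base_scores(seq: NucleotideSequence | str) -> ScoredSequence:
    """Per-base G4Hunter scores.

    Each maximal run of k consecutive G scores +min(k, 4) per base, each
    maximal run of k consecutive C scores -min(k, 4) per base; A/T/U and all
    ambiguity codes (including N) score 0 and break G/C runs.
    """
    seq = _coerce(seq)
    arr = np.frombuffer(seq.residues.upper().encode("ascii"), dtype=np.uint8)
    out = np.zeros(arr.size, dtype=np.int8)
    for code, sign in ((ord("G"), 1), (ord("C"), -1)):
        mask = arr == code
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.r_[False, mask, False]))
        starts, ends = edges[::2], edges[1::2]
        lengths = ends - starts
        out[mask] = np.repeat(sign * np.minimum(lengths, 4), lengths).astype(np.int8)
    return ScoredSequence(seq, out)


def score_sequence(seq: NucleotideSequence | str) -> float:
    """Whole-sequence G4Hunter score: mean of the per-base scores."""
    return float(base_scores(seq).base_scores.mean())


def window_scores(
    scored: ScoredSequence, params: G4Params = G4Params()
) -> np.ndarray:
    """Sliding-window mean scores.

    For a sequence of length L >= window this returns L - window + 1 values,
    value j being the mean of base scores over [j, j + window).  Sequences
    shorter than the window yield a single whole-sequence mean, so short
    contigs are still scored.
    """
    s = scored.base_scores
    w = params.window
    if s.size < w:
        return np.array([s.mean()])
    c = np.concatenate(([0], np.cumsum(s, dtype=np.int64)))
    return (c[w:] - c[:-w]) / w


def detect_hits(
    seq: NucleotideSequence | str,
    params: G4Params = G4Params(),
    trim: bool = False,
) -> list[PQSHit]:
    """Detect merged PQS hits on both strands in a single pass.

    Windows whose mean score reaches ``params.threshold`` in absolute value
    are selected; runs of selected same-sign windows whose spans overlap or
    abut are merged into one hit spanning from the first window's start to
    the last window's end.  Opposite-sign hits are never merged (a G-rich
    and a C-rich region may overlap).  With ``trim=True``, terminal
    zero-score bases are removed from each merged region and the region
    score recomputed.
    """
    seq = _coerce(seq)
    scored = base_scores(seq)
    s = scored.base_scores
    w_eff = min(params.window, s.size)
    ws = window_scores(scored, params)
    cum = np.concatenate(([0], np.cumsum(s, dtype=np.int64)))

    hits: list[PQSHit] = []
    for sign in (1, -1):
        js = np.flatnonzero(sign * ws >= params.threshold)
        if js.size == 0:
            continue
        # same-length windows at starts j, j' overlap/abut iff j' - j <= window
        breaks = np.flatnonzero(np.diff(js) > w_eff)
        group_starts = np.r_[0, breaks + 1]
        group_ends = np.r_[breaks, js.size - 1]
        for gs, ge in zip(group_starts, group_ends):
            a = int(js[gs])
            b = int(js[ge]) + w_eff
            if trim:
                while a < b and s[a] == 0:
                    a += 1
                while b > a and s[b - 1] == 0:
                    b -= 1
            region_score = float((cum[b] - cum[a]) / (b - a))
            block = ws[js[gs] : js[ge] + 1]
            max_ws = float(block[np.argmax(sign * block)])
            hits.append(
                PQSHit(
                    seq_id=seq.id,
                    start=a,
                    end=b,
                    sign=sign,
                    region_score=region_score,
                    max_window_score=max_ws,
                    sequence=seq.residues[a:b],
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.end, -h.sign))


def qualifying_window_starts(
    seq: NucleotideSequence | str, params: G4Params = G4Params()
) -> dict[int, np.ndarray]:
    """Start positions of threshold-passing windows, keyed by sign.

    Exposed for coverage/merging diagnostics and property checks: the union
    of merged hits per sign equals the union of these windows' spans.
    """
    seq = _coerce(seq)
    ws = window_scores(base_scores(seq), params)
    return {
        sign: np.flatnonzero(sign * ws >= params.threshold) for sign in (1, -1)
    }
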