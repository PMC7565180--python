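"""Unit and property tests for G4Hunter scoring and PQS detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4scan.core import (
    G4Params,
    NucleotideSequence,
    base_scores,
    detect_hits,
    qualifying_window_starts,
    reverse_complement,
    score_sequence,
    window_scores,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("GGGG", [4, 4, 4, 4]),
        ("CCT", [-2, -2, 0]),
        ("GGGGG", [4, 4, 4, 4, 4]),  # run cap at 4
        ("GCGC", [1, -1, 1, -1]),
        ("GGNGG", [2, 2, 0, 2, 2]),  # N scores 0 and breaks the run
        ("GGRGG", [2, 2, 0, 2, 2]),  # ambiguity codes likewise
        ("ggcc", [2, 2, -2, -2]),  # case-insensitive
        ("GUG", [1, 0, 1]),  # U behaves like T
    ],
)
def test_base_scores_run_length_rule(seq, expected):
    assert base_scores(seq).base_scores.tolist() == expected


def test_base_scores_catalogue_motif_642k():
    """28-nt dense motif: per-base sum 82, mean 2.93."""
    scored = base_scores("TGGTGGGGGCGGGGGGAGGGGCGGGGGT")
    assert scored.base_scores.sum() == 82
    assert round(score_sequence("TGGTGGGGGCGGGGGGAGGGGCGGGGGT"), 2) == 2.93


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError, match="empty"):
        NucleotideSequence("x", "")
    with pytest.raises(ValueError, match="non-IUPAC"):
        NucleotideSequence("x", "ACGT!")
    with pytest.raises(ValueError):
        base_scores("AXG")


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("TGGGGAGGAGGGGAGGGGAGGTGGGCTGGGGGGGGCT", 2.57),
        ("AT" * 12 + "A", 0.0),  # 25-mer with no G/C runs
    ],
)
def test_score_sequence_examples(seq, expected):
    assert round(score_sequence(seq), 2) == expected


def test_score_antisymmetric_under_reverse_complement():
    s = "TGGTGGGGGCGGGGGGAGGGGCGGGGGT"
    assert round(score_sequence(reverse_complement(s)), 2) == -2.93


def test_window_scores_shapes_and_values(oracle):
    p = G4Params(window=25)
    assert window_scores(base_scores("G" * 25), p).tolist() == [4.0]
    assert window_scores(base_scores("G" * 26), p).tolist() == [4.0, 4.0]
    # shorter than the window: one whole-sequence value
    short = window_scores(base_scores("GGGT"), p)
    assert short.tolist() == [pytest.approx(sum([3, 3, 3, 0]) / 4)]
    rng = np.random.default_rng(0)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=40))
        got = window_scores(base_scores(seq), p)
        assert got == pytest.approx(oracle.window_means(seq, 25))
        assert got.size == 16


def test_detect_no_hits_on_alternating_at():
    assert detect_hits("AT" * 500) == []


def test_detect_planted_block_matches_window_union(oracle):
    """One planted G-rich block in A/T flanks gives exactly one hit covering
    the union of qualifying windows."""
    seq = "AT" * 50 + "GGGTTGGGTTGGGGTTGGGGATGGGG" + "AT" * 37
    hits = detect_hits(seq)
    assert len(hits) == 1
    (h,) = hits
    expect = oracle.hits(seq)
    assert (h.start, h.end, h.sign) == expect[0][:3]
    assert h.region_score == pytest.approx(expect[0][3])
    assert abs(h.max_window_score) >= 1.2
    assert h.length >= 25


def test_detect_opposite_signs_never_merge():
    # G-rich block immediately followed by a C-rich block
    seq = "AT" * 20 + "GGGGG" * 5 + "CCCCC" * 5 + "AT" * 20
    hits = detect_hits(seq)
    signs = {h.sign for h in hits}
    assert signs == {1, -1}
    for a in hits:
        for b in hits:
            if a is not b and a.sign == b.sign:
                assert a.end <= b.start or b.end <= a.start


def test_detect_short_sequence_whole_window():
    hits = detect_hits("GGGGGGGGGG")  # 10 nt, shorter than the window
    assert len(hits) == 1
    assert (hits[0].start, hits[0].end) == (0, 10)
    assert hits[0].region_score == 4.0


def test_trim_removes_terminal_zero_bases():
    seq = "AT" * 30 + "GGGGGAGGGGGAGGGGGAGGGGG" + "AT" * 30
    raw = detect_hits(seq)[0]
    trimmed = detect_hits(seq, trim=True)[0]
    assert trimmed.start >= raw.start and trimmed.end <= raw.end
    assert trimmed.sequence[0] in "GC" and trimmed.sequence[-1] in "GC"
    assert abs(trimmed.region_score) >= abs(raw.region_score)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(dna)
def test_property_oracle_equivalence_short_sequences(seq):
    from conftest import naive_base_scores

    assert base_scores(seq).base_scores.tolist() == naive_base_scores(seq)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=120))
def test_property_antisymmetry_and_cap(seq):
    fwd = base_scores(seq).base_scores
    rev = base_scores(reverse_complement(seq)).base_scores
    assert np.array_equal(rev, -fwd[::-1])
    assert fwd.min() >= -4 and fwd.max() <= 4


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=60, max_size=200))
def test_property_threshold_monotonicity(seq):
    counts = [
        len(detect_hits(seq, G4Params(25, t))) for t in (1.2, 1.4, 1.6, 1.8, 2.0)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_property_hits_cover_exactly_qualifying_windows():
    """Per sign, merged hits are pairwise disjoint and their union equals the
    union of threshold-passing window spans."""
    rng = np.random.default_rng(7)
    p = G4Params()
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=3000))
        starts_by_sign = qualifying_window_starts(seq, p)
        hits = detect_hits(seq, p)
        for sign in (1, -1):
            hs = sorted((h.start, h.end) for h in hits if h.sign == sign)
            for (s1, e1), (s2, e2) in zip(hs, hs[1:]):
                assert e1 < s2  # disjoint with a real gap
            covered = set()
            for s, e in hs:
                covered.update(range(s, e))
            union = set()
            for j in starts_by_sign[sign]:
                union.update(range(j, j + p.window))
            assert covered == union
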