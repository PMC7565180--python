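"""Shared fixtures and the independent brute-force oracle.

The oracle reimplements per-base run-length scoring, exhaustive window
enumeration and window merging character by character, with none of the
vectorized machinery of the package, so the two routes are independent.
"""

from __future__ import annotations

import pytest


def naive_base_scores(seq: str) -> list[int]:
    s = seq.upper().replace("U", "T")
    out = [0] * len(s)
    i = 0
    while i < len(s):
        c = s[i]
        if c in "GC":
            j = i
            while j < len(s) and s[j] == c:
                j += 1
            v = min(j - i, 4) * (1 if c == "G" else -1)
            for k in range(i, j):
                out[k] = v
            i = j
        else:
            i += 1
    return out


def naive_window_means(seq: str, window: int) -> list[float]:
    sc = naive_base_scores(seq)
    if len(sc) < window:
        return [sum(sc) / len(sc)]
    return [sum(sc[j : j + window]) / window for j in range(len(sc) - window + 1)]


def naive_hits(seq: str, window: int = 25, threshold: float = 1.2):
    """Merged hits as (start, end, sign, region_score), sorted by start."""
    sc = naive_base_scores(seq)
    means = naive_window_means(seq, window)
    w = min(window, len(sc))
    spans = [(j, j + w) for j in range(len(means))]
    hits = []
    for sign in (1, -1):
        cur = None
        for (s, e), m in zip(spans, means):
            if sign * m >= threshold:
                if cur is not None and s <= cur[1]:
                    cur = (cur[0], e)
                else:
                    if cur is not None:
                        hits.append((cur, sign))
                    cur = (s, e)
        if cur is not None:
            hits.append((cur, sign))
    out = []
    for (s, e), sign in hits:
        out.append((s, e, sign, sum(sc[s:e]) / (e - s)))
    return sorted(out)


@pytest.fixture
def oracle():
    class Oracle:
        base_scores = staticmethod(naive_base_scores)
        window_means = staticmethod(naive_window_means)
        hits = staticmethod(naive_hits)

    return Oracle


# Characterized long G4-prone motifs from the Hadesarchaea archaeon reference
# catalogue, with their whole-sequence G4Hunter scores (2 d.p.).  Rows 196_K
# and 245_K carry scores recomputed with the run-length definition; the
# catalogue's printed values (2.22, 2.33) are inconsistent with it.
HADESARCHAEA_MOTIFS = {
    "038_K": ("AGGCTGGGGGTGAGGGCGGTGGTGGGGAAGGGAGGGGTGGGGGAGAAAACGAAGGGGGT", 2.07),
    "086_K": ("TGGGGAGGAGGGGAGGGGAGGTGGGCTGGGGGGGGCT", 2.57),
    "174_K": (
        "AGGGTGAGGGAGGAGGTGCTGGGGGGAAGGGAGGTGGGGGAGGGGGAGGTGGAGGGGCTGGTGAGGGA",
        2.07,
    ),
    "175_K": (
        "AGGGGAGGAGGGTGGCCGTGGTGGGGGCGGGGGGAGGGGCGGGGGTGGGGGGGCCTGGGGGGA",
        2.54,
    ),
    "176_K": (
        "AGGAGGAGGGTGAGGGACCAGGGGAGGAGGGAGGGGAGGGGGGGAAGGAGGAGGGAGAGGAGGAGGGA",
        1.93,
    ),
    "178_K": ("TGGTGGGGGCGGGGGGAGGGGCGGGGGTGGGGGGGCCTGGGGGGA", 2.89),
    "195_K": ("AGGGGAGGAGGGTGGCCGTGGTGGGGGCGGGGGGAGGGGCGGGGGTGGCCTCCACGGA", 1.91),
    "196_K": ("AGGGGAGGAGGGAGGGGAGGGGGGGAAGGAGGAGGGAGAGGAGGAGGGA", 2.20),
    "245_K": (
        "GGGGTCGTCGGGGGGGAGAGCTGGGGAGGAGGGGAGGGGAGGTGGGCTGGGGGGGGCTGGGGAGGGAGGAGGTGAGGGG",
        2.39,
    ),
    "640_K": ("AGGGAGGTGGGGGAGGGGGAGGTGGAGGGGCT", 2.38),
    "642_K": ("TGGTGGGGGCGGGGGGAGGGGCGGGGGT", 2.93),
    "643_K": ("AGGCTGGGGGTGAGGGCGGTGGTGGGGAAGGGAGGGGTGGGGGAGAAAACGAAGGGGGT", 2.07),
    "644_K": ("AGGGCGGTGGTGGGGAAGGGAGGGGTGGGGGA", 2.41),
    "645_K": ("GGCGGGGGGGGAGTCCTTCATCCTGGGGTAGGGG", 1.74),
}
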