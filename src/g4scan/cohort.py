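"""Cohort-level statistics over per-genome PQS summaries.

Genomes are grouped by taxon label; per group the module tabulates genome
counts, length statistics, mean GC%, total PQS, mean/min/max PQS frequency
per kbp and %PQS.  Group similarity is depicted by Ward.D2 hierarchical
clustering on Euclidean distances over the (mean_f, min_f, max_f, pct_pqs)
feature matrix, with branch support estimated by an ordinary bootstrap over
feature columns (the fraction of resamplings in which a branch's leaf set
reappears).  Note this is a plain bootstrap proportion (BP), not the
multiscale approximately-unbiased (AU) p-value some R packages report; BP
is typically more conservative.  Group differences in PQS frequency are
tested pairwise with Kruskal-Wallis and a Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import kruskal

from .genome import GenomeSummary

__all__ = [
    "CLUSTER_FEATURES",
    "DendrogramResult",
    "aggregate",
    "cluster_groups",
    "compare_groups",
]

CLUSTER_FEATURES = ("mean_f", "min_f", "max_f", "pct_pqs")


def aggregate(
    summaries: Sequence[GenomeSummary],
    grouping: Mapping[str, str],
    pooled_pct: bool = True,
) -> pd.DataFrame:
    """Per-group aggregate table.

    ``grouping`` maps assembly_id to a group label; every summary must be
    labeled.  %PQS is pooled over the group by default (total covered
    nucleotides / total group length), the length-unweighted mean of
    per-genome values with ``pooled_pct=False``.
    """
    missing = [s.assembly_id for s in summaries if s.assembly_id not in grouping]
    if missing:
        raise KeyError(f"assemblies without a group label: {missing}")
    df = pd.DataFrame(
        {
            "group": [grouping[s.assembly_id] for s in summaries],
            "length": [s.total_length for s in summaries],
            "gc": [s.gc_percent for s in summaries],
            "pqs": [s.pqs_count for s in summaries],
            "f": [s.freq_per_kbp for s in summaries],
            "pct": [s.pqs_coverage_percent for s in summaries],
            "covered": [
                s.pqs_coverage_percent * s.total_length / 100.0 for s in summaries
            ],
        }
    )
    g = df.groupby("group", sort=True)
    out = pd.DataFrame(
        {
            "n_genomes": g.size(),
            "median_length": g["length"].median(),
            "shortest": g["length"].min(),
            "longest": g["length"].max(),
            "gc_percent": g["gc"].mean(),
            "total_pqs": g["pqs"].sum(),
            "mean_f": g["f"].mean(),
            "min_f": g["f"].min(),
            "max_f": g["f"].max(),
        }
    )
    if pooled_pct:
        out["pct_pqs"] = g["covered"].sum() / g["length"].sum() * 100.0
    else:
        out["pct_pqs"] = g["pct"].mean()
    return out


@dataclass(frozen=True)
class DendrogramResult:
    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix, Ward.D2 on Euclidean
    bootstrap_proportions: tuple[float, ...]  # one BP per internal node
    n_boot: int

    def newick(self) -> str:
        """Newick string with BP as internal node labels and heights as
        branch lengths."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b, h, _ = self.linkage[i - n]
            a, b = int(a), int(b)
            bp = self.bootstrap_proportions[i - n]
            la = node(a) + f":{(heights[i] - heights[a]):.6g}"
            lb = node(b) + f":{(heights[i] - heights[b]):.6g}"
            return f"({la},{lb}){bp:.4g}"

        for k, (_, _, h, _) in enumerate(self.linkage):
            heights[n + k] = float(h)
        return node(2 * n - 2) + ";"


def _leaf_sets(Z: np.ndarray, n: int) -> list[frozenset[int]]:
    """Leaf-index set of each internal node of a linkage matrix."""
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, _, _) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + k] = s
        out.append(s)
    return out


def cluster_groups(
    table: pd.DataFrame,
    features: Sequence[str] = CLUSTER_FEATURES,
    n_boot: int = 10_000,
    seed: int = 0,
    scale: bool = False,
) -> DendrogramResult:
    """Ward.D2 dendrogram over groups with bootstrap branch support.

    Distances are Euclidean on the (by default unstandardized) feature
    matrix; ``scale=True`` standardizes each feature column first.  Branch
    support is the proportion of ``n_boot`` resamplings of the feature
    columns (with replacement) in which the branch's leaf set reappears in
    the resampled dendrogram; deterministic for a fixed seed.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 groups to cluster")
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    if scale:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    labels = tuple(str(i) for i in table.index)
    n, p = X.shape
    Z = linkage(X, method="ward")
    ref_sets = _leaf_sets(Z, n)
    counts = np.zeros(len(ref_sets))
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, p, size=p)
        Zb = linkage(X[:, cols], method="ward")
        boot_sets = set(_leaf_sets(Zb, n))
        for i, s in enumerate(ref_sets):
            if s in boot_sets:
                counts[i] += 1
    return DendrogramResult(
        labels=labels,
        linkage=Z,
        bootstrap_proportions=tuple(counts / n_boot),
        n_boot=n_boot,
    )


def _kruskal_h_p(groups: list[np.ndarray]) -> tuple[float, float]:
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # degenerate: no variation anywhere
    h, p = kruskal(*groups)
    return float(h), float(p)


def compare_groups(
    freqs_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    pairwise: bool = True,
) -> pd.DataFrame:
    """Kruskal-Wallis comparisons of per-genome PQS frequencies.

    With ``pairwise=True`` (default) every pair of groups is tested and raw
    p-values are Bonferroni-adjusted over the number of pairs; otherwise a
    single omnibus test over all groups is run.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in freqs_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 genomes")
    if not pairwise:
        h, p = _kruskal_h_p(list(groups.values()))
        return pd.DataFrame(
            [
                {
                    "group1": "all",
                    "group2": "all",
                    "H": h,
                    "p_raw": p,
                    "p_adjusted": p,
                    "significant": p < alpha,
                }
            ]
        )
    pairs = list(combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        h, p = _kruskal_h_p([groups[a], groups[b]])
        rows.append({"group1": a, "group2": b, "H": h, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = (df["p_raw"] * len(pairs)).clip(upper=1.0)
    df["significant"] = df["p_adjusted"] < alpha
    return df
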