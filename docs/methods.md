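# Methods

## Scoring model

`g4scan` predicts G-quadruplex-prone regions (putative quadruplex
sequences, PQS) with the G4Hunter scheme. Each base receives an integer
score from its maximal mononucleotide run: a base inside a run of *k*
guanines scores `+min(k, 4)`, inside a run of *k* cytosines `-min(k, 4)`,
and A/T/U score 0. The cap at 4 reflects that runs longer than four
guanines do not add quadruplex-forming potential per base; the negative
mirror means a C-rich stretch marks a quadruplex on the complementary
strand. The G4Hunter score of a sequence is the arithmetic mean of its
per-base scores, so it lies in [-4, 4] and is exactly antisymmetric under
reverse complement.

IUPAC ambiguity codes (N, R, Y, ...) score 0 **and break G/C runs**. This
is a deliberate conservative choice: an unknown base is given no
quadruplex-forming propensity rather than an imputed one. T and U are
treated identically so RNA features can be scanned unchanged.

## Detection

A window of `window` residues (default 25, roughly the span of one
intramolecular quadruplex) slides one base at a time; windows whose mean
score reaches `threshold` (default 1.2) in absolute value qualify. Runs of
qualifying same-sign windows whose spans overlap or abut are merged into
one hit; the hit count is therefore a count of discrete, non-overlapping
G4-prone regions per sign. Sequences shorter than the window are scored as
a single whole-sequence window so short contigs are not silently dropped.
Opposite-sign hits are never merged, and both strands are covered by the
single forward pass (antisymmetry makes a reverse-complement scan
redundant).

Each hit carries two scores: `region_score`, the mean per-base score over
the merged region, and `max_window_score`, the most extreme qualifying
window mean inside it. Merged regions are **not** trimmed to G/C
boundaries by default — characterized high-scoring motifs begin and end on
A/T, so trimming would misrepresent them — but `trim=True` (CLI `--trim`)
removes terminal zero-score bases and rescores.

Numerical notes:

- Window means are computed from an integer cumulative sum, so they are
  exact (no floating accumulation error); the threshold comparison uses
  `>=`.
- Coordinates are 0-based half-open internally; text outputs (TSV) print
  1-based inclusive starts, and BED output keeps BED's native half-open
  convention.

## Per-genome metrics

For an assembly (all records pooled): GC% excludes ambiguity codes from
numerator and denominator; PQS frequency per kbp divides the merged hit
count by the **total** assembly length (including ambiguous bases), since
genome size is the natural normalizer; %PQS is the fraction of distinct
nucleotide positions covered by any hit of either sign — the probability
that a random nucleotide lies in a G4-prone region — counting a position
once even where + and - hits overlap. Records are scanned independently:
no window spans a contig boundary, so concatenating an assembly with an
equal-length zero-score record exactly halves frequency and coverage (a
property the tests assert).

Hits are binned by |region_score| into 1.2–1.4, 1.4–1.6, 1.6–1.8, 1.8–2.0
and >2.0, half-open on the left edge ([1.4, 1.6) etc.). One deliberate
deviation from a literal reading of those labels: the lowest bin is open
below. A merged region's mean can fall under the 1.2 window threshold
because the window union includes zero-score flanking bases (a single
dense 25-mer in an A/T context yields a ~59-nt merged region with mean
~1.7 even when every base of the motif scores 4; weaker motifs dilute
below 1.2). Every detected hit must land in exactly one bin
(`sum(bin_counts) == pqs_count`), so such hits stay in the lowest class
rather than vanish.

## Feature-class densities

Annotations come from NCBI tab-delimited feature tables or GFF3 and are
grouped into gene, rRNA, tRNA, ncRNA and repeat_region (anything else kept
as `other:<label>`). Per class, intervals are unioned (overlapping
same-class annotations are not double counted) and a hit counts toward the
class if it overlaps the union by at least one nucleotide — at most once
per class, though one hit may count toward several classes. Density is
hits per kbp of union length, directly comparable to the genome-average
frequency. The overlap rule is configurable (`containment`, `midpoint`)
because no single convention is canonical; overlap-by-1-nt is the default
as the least surprising. Strand is ignored for assignment — the hit's sign
already says which strand carries the G-rich motif. A `--flank N` option
widens features before the union for "around the feature" analyses; there
is no principled default flank, so it is 0.

## Cohort statistics

Per-group aggregation reports genome counts, median/shortest/longest
length, mean GC%, total PQS, mean/min/max frequency and %PQS. Group %PQS
is pooled (total covered nucleotides over total group length) by default;
a length-unweighted mean of per-genome values is available
(`pooled_pct=False`) since both conventions are defensible.

Group similarity uses Ward.D2 agglomerative clustering on Euclidean
distances over the unstandardized (mean_f, min_f, max_f, pct_pqs) matrix
(`scale=True` standardizes first, for sensitivity checks).
`scipy.cluster.hierarchy.linkage(method="ward")` on the observation matrix
implements exactly the Ward.D2 criterion. Branch support is an ordinary
bootstrap proportion: feature columns are resampled with replacement
`n_boot` times (default 10,000) and each internal node's support is the
fraction of resamplings in which its leaf set reappears. This is **not**
the multiscale-bootstrap "approximately unbiased" (AU) p-value reported by
some R packages; BP is simpler and typically conservative, and with only
four feature columns the column bootstrap is coarse — supports should be
read qualitatively. The bootstrap seed is mandatory in the API (default 0)
and results are deterministic given it.

Group differences in per-genome PQS frequency use the Kruskal–Wallis test
(tie-corrected, via scipy) run pairwise over all group pairs with a
Bonferroni adjustment (`p_adj = min(1, p * n_pairs)`) and a 0.05 cutoff; a
single omnibus test is available with `pairwise=False`. Degenerate input
(every value identical across both groups) is defined as H = 0, p = 1
rather than an error.

## Synthetic data generator

The generator builds the stated world the pipeline is tested in: genomes
of chosen length and GC content (defaults emulate archaeal assemblies —
e.g. 46.51% GC, the archaeal average, reproduces within +-0.5% at 1 Mb),
with G-rich motif templates planted at non-overlapping positions and
annotation tables written in both dialects.

Planting is designed for exact, not approximate, ground truth. Each
planted motif is flanked by A/T (zero-score) buffers of at least 30 nt >
one default window on each side, so planted hits can never merge with each
other, and each template's merged-hit extent and region score at default
parameters are fixed, frozen constants (computed once with an independent
brute-force scorer; re-verified against `detect_hits` in the tests). Five
templates cover the five score bins. Consequences:

- On an A/T background, detected count = planted count (sensitivity 1.0,
  zero false positives) and every hit lands in its declared bin.
- On a GC-rich iid background, background hits appear (as they do in real
  genomes) and counts are approximate; ground-truth assertions in tests
  use the A/T background. A first-order block background
  (`block_gc=(lo, hi)`) mimics GC-skewed genomes for GC-vs-PQS trend
  checks.

Cohorts assign each group a planted density in hits/kbp (an "outlier"
group can carry >=4x the rest, emulating the extreme subgroup observed in
hot-spring archaea); with A/T backgrounds recovered frequencies equal the
plan up to integer rounding of motif counts. Feature plans request, per
class, `n` non-overlapping intervals of fixed length and an enrichment
factor E; the generator places `round(E * H * U / L)` intervals centred on
distinct expected hits and the rest in hit-free gaps, so the realized
enrichment is E up to that integer rounding — plans in the tests are sized
so the target is attainable exactly. Everything is deterministic
(bit-identical FASTA and tables) for a fixed seed.

What a green synthetic test does **not** establish: recovery under
sequencing error, assembly gaps, repeat-induced mis-assembly, or realistic
codon/GC structure — the backgrounds are iid or blockwise-iid, and planted
motifs are idealized. Whole-domain summary numbers (thousands of genomes)
require the real assemblies and are out of scope of the test suite.

## Known limitations

- Hit merging can chain qualifying windows through moderately G-rich
  background into long regions whose mean drops below the threshold; this
  is inherent to the window-union definition and the reason for the open
  lowest bin.
- Count monotonicity in window size is an empirical regularity asserted by
  `window_size_study` (and verified on the test worlds), not a theorem;
  pathological sequences can violate it, in which case the check raises.
- BP values are bootstrap proportions over only four feature columns;
  they are not calibrated p-values.
- No structural topology prediction (parallel/antiparallel), no i-motif
  scoring beyond the sign convention, and no accession
  download/management.
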