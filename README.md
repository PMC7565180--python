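# g4scan

Genome-scale prediction and statistics of putative G-quadruplex sequences
(PQS), built around the G4Hunter score. It is aimed at microbial
comparative genomics — scanning whole assemblies (chromosomes, plasmids,
contigs), relating PQS density to GC content and annotated feature
classes, and comparing taxon groups — and ships a synthetic-genome
generator so the entire pipeline is testable without downloading anything.

## The score

Guanine quartets stack into four-stranded G-quadruplexes (G4) wherever the
sequence supplies enough closely spaced G-runs. G4Hunter quantifies that
propensity: each base in a run of *k* guanines scores `+min(k, 4)`, in a
run of *k* cytosines `-min(k, 4)` (a C-rich stretch is G-rich on the other
strand), all else 0; the score of a sequence is the mean per-base score.
Detection slides a 25-nt window and keeps windows with |mean| ≥ 1.2,
merging overlapping/abutting same-sign windows into discrete hits. Per
genome, `g4scan` reports hit counts, frequency per kbp, %PQS (fraction of
nucleotides inside any hit), score-bin counts, and per-feature-class
densities; per cohort, group aggregates, a Ward.D2/Euclidean dendrogram
with bootstrap branch support, and pairwise Kruskal–Wallis tests with
Bonferroni correction.

## Worked example

```python
>>> from g4scan import score_sequence, detect_hits
>>> score_sequence("TGGTGGGGGCGGGGGGAGGGGCGGGGGT")   # a 28-nt archaeal motif
2.9285714285714284
>>> hit, = detect_hits("AT"*40 + "GGGGATGGGTTGTAGAAGTAGTGGGG" + "AT"*40)
>>> hit.start, hit.end, hit.sign, hit.region_score
(78, 108, 1, 1.5)
```

The motif scores 2.93: its G-runs put almost every base at the +4 cap, far
above the 1.2 detection threshold (scores above ~1.5 almost always form
stable quadruplexes in vitro). The planted 26-mer in the second call
yields exactly one merged hit; the 30-nt region extends one qualifying
window's reach beyond the motif and its mean score 1.5 places it in the
1.4–1.6 stability bin.

End-to-end on synthetic data:

```
$ g4scan simulate --seed 5 --length 50000 --motifs "1.4-1.6:10,1.6-1.8:3" --outdir synth
$ g4scan scan synth/genome.fasta --out-prefix demo
$ cat demo.summary.tsv
assembly_id  total_length  gc_percent  pqs_count  freq_per_kbp  pqs_coverage_percent  1.2-1.4  1.4-1.6  1.6-1.8  1.8-2.0  >2.0
genome       50000         0.48        13         0.26          1.008                 0        10       3        0        0
```

All 13 planted motifs (10 of the 1.4–1.6 class, 3 of 1.6–1.8) are
recovered in their declared bins with zero false positives — the A/T
background scores 0 everywhere, so 0.26 hits/kbp is exactly the planted
density. `g4scan detect` writes hits as BED6/TSV, `g4scan features`
computes per-feature-class densities from an NCBI feature table or GFF3,
and `g4scan cohort` aggregates per-genome summaries by group, writes the
dendrogram as Newick and the group tests as TSV.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time, the whole-sequence G4Hunter scores
of six characterized long G4-prone motifs from the *Hadesarchaea archaeon*
genome (the headline worked examples for the scorer) and writes them as
JSON, one entry per target with the sequence length used.

See `docs/methods.md` for the model's assumptions, parameter meanings,
what the synthetic generator does and does not emulate, and known
limitations.
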