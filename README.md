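# pirnakit

Small-RNA sequencing analysis of piRNA biology, built for genomes with a
heavy transposable-element load such as the mosquito *Aedes aegypti*.
Starting from raw small-RNA libraries (FASTA/FASTQ), a genome assembly and
gene/TE annotations, the package runs the complete analysis chain:

* **Preprocessing** — 3′-adapter stripping (suffix–prefix overlap scan),
  removal of rRNA/miRNA-like contaminants by full-length matching, and
  partitioning into size classes (21-nt endo-siRNAs; 24–31-nt piRNAs;
  the open-ended ≥24-nt class used for diversity estimation).
* **Mapping** — a built-in full-length ungapped mapper: every placement of
  a read on either strand with Hamming distance ≤ 2 is reported, and a read
  is *uniquely mapping* when exactly one hit attains the minimum mismatch
  count.  Externally produced SAM alignments can be ingested instead.
* **piRNA-cluster discovery** — uniquely mapping piRNAs are counted in
  non-overlapping 5-kb windows by their 5′ coordinate; windows holding ≥ 10
  distinct sequences seed clusters, adjacent qualifying windows merge, and
  boundaries are refined to the furthest member-read extents.  A
  random-interval null model scores each cluster's TE content (coverage and
  element count) as z-scores against equally long intervals drawn uniformly
  from the assembly.
* **Ping-pong signature** — all opposite-strand hit pairs sharing ≥ 1
  genomic position are enumerated; the overlap between 5′ ends
  (`minus 5′ − plus 5′ + 1`) is exactly 10 nt for ping-pong partners, with
  a 5′-U on one mate and an A at position 10 of the other (U1/A10).  The
  module reports the overlap histogram, the fraction of participating
  sequences in a 10-nt pair, per-overlap 5′-base composition, and
  per-element density maps.
* **Targeting** — gene/TE/both/neither classification by annotation
  overlap, genome occupancy fractions, TE-family tallies by consensus
  matching, sense/antisense orientation fractions, and a gene ranking by
  uniquely-mapping piRNA density (count / gene length).
* **Transgene-derived piRNAs** — piRNAs from transformation plasmids are
  those with *zero* genome hits and an exact full-length match to a plasmid
  (treated as circular); reads matching more than one plasmid are flagged
  ambiguous and reported parenthesised.
* **Pool-size estimation** — Lincoln–Petersen capture–recapture over every
  non-replicate library pair: `N̂ = n_a·n_b / k` where `n_a`, `n_b` are the
  eligible (≥ 24 nt, genome-mapped, within-library multiplicity 1) distinct
  sequences and `k` the shared ones.  Excluding within-library duplicates
  counters the bias that highly amplified sequences introduce; a seeded
  in-silico harness validates the estimator against known pool sizes.
* **Synthetic data** — a seeded generator producing genomes with planted
  TE copies (including MITEs with terminal inverted repeats), genes,
  strand-biased piRNA clusters, a latent sequence pool with configurable
  5′-U bias and ping-pong partner rates, and libraries sampled with skewed
  abundance — plus machine-readable truth for every downstream stage.

## Worked example

```python
from pirnakit import (
    SimConfig, simulate_dataset, merge_libraries, partition_by_size,
    map_library, unique_hits, window_counts, call_clusters,
    summarize_clusters, coverage_summary, enumerate_overlap_pairs,
    overlap_profile, estimate_pool,
)

config = SimConfig(
    seed=11,
    n_contigs=4, contig_length=250_000,
    n_clusters=6, cluster_length_range=(30_000, 50_000),
    pool_size=5_000, depth=20_000,
    strand_bias=0.9, p_u1=0.8,
)
dataset = simulate_dataset(config, n_libraries=2)
combined = merge_libraries(dataset.libraries)
pirna = partition_by_size(combined)["pool_pirna"]
hits = unique_hits(map_library(pirna, dataset.genome.assembly))

clusters = call_clusters(window_counts(hits, dataset.genome.assembly), hits)
summarize_clusters(clusters, combined)
cov = coverage_summary(clusters, dataset.genome.assembly, hits)
profile = overlap_profile(enumerate_overlap_pairs(hits))
pool = estimate_pool(dataset.libraries)
```

This prints (via the obvious `print` statements):

```
distinct piRNA-class sequences: 4473
uniquely mapping: 4457
clusters called: 6 (planted: 6)
top cluster: contig1:85522-124703 (39 kb, 732 unique piRNAs, plus fraction 0.66)
genome fraction in clusters: 25.2%
piRNAs attributable to clusters: 91.6%
ping-pong signature fraction: 15.9%
pool-size estimate: 3,736 (true pool: 5,000)
```

All six planted clusters are recovered at window resolution.  The top
cluster's plus fraction (0.66) is the configured 0.9 strand bias diluted by
opposite-strand ping-pong partners.  The pool estimate undershoots the
truth because the default abundance model is log-normal: shared abundance
skew correlates the two capture occasions, which is exactly the bias the
duplicate-exclusion rule mitigates (see `docs/methods.md`); with
`abundance_model="uniform"` the estimator is accurate to a few percent.

A command-line interface mirrors the stages
(`pirnakit simulate | preprocess | map | clusters | pingpong | poolsize |
transgene | report`); run `pirnakit --help`.

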