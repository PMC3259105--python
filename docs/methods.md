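# Methods

This note documents the models, conventions and numerical choices behind
`pirnakit`, and what its synthetic-data experiments do and do not show.

## Coordinates, alphabets and read identity

All intervals are 0-based half-open internally; TSV reports emit 1-based
inclusive coordinates (the convention of printed genomics tables), JSON
reports keep the internal convention.  U is normalized to T at ingest so
reads, references and annotations share the DNA alphabet.  Reads are
collapsed: a library stores each distinct sequence once with per-library
multiplicities, and a sequence string is its own identifier throughout.
The 5′ coordinate of a minus-strand hit is `interval.end − 1`; this single
rule makes the ping-pong overlap arithmetic exact.

## Preprocessing

The 3′ adapter is located as the smallest cut position whose read suffix
matches a prefix of the adapter, with a mismatch budget of 1 per 10 nt of
overlap and a minimum overlap of 6 nt (all configurable).  The scan is
repeated to a fixed point, so stripping is idempotent; the cost is a small
chance of over-trimming inserts that happen to end in adapter-like bases.
Inserts shorter than 16 nt after trimming are rejected — 16–35 nt is the
gel-excision window of small-RNA library construction and bounds every read
the pipeline accepts.

Contaminant (rRNA-like, miRNA-like) removal uses the same matching rule as
every other database comparison in the package: a sequence is removed iff
it aligns full-length to any reference, either strand, with at most 2
mismatches.  Using one explicit rule everywhere makes the filters
deterministic and directly testable against a brute-force Hamming scan.

Size classes: 21 nt (endo-siRNA), 24–31 nt (piRNA), and the open-ended
≥ 24 nt class.  The last exists because diversity estimation is defined on
"24 nt or larger" while the length profile's piRNA peak is bounded; both
classes are first-class rather than a guessed single intent.

## Mapping policy

The mapper reports *every* placement of a read with full-length Hamming
distance ≤ 2 (budget configurable), on either strand; reference N never
matches.  Seed-and-extend mappers configured with a seed at least as long
as the read implement exactly this contract, so the package states it as
the specification and tests it: a pigeonhole k-mer index (k = ⌊L/(m+1)⌋,
one exact seed guaranteed among m+1 disjoint seeds) accelerates the scan
but must be observationally identical to the exhaustive window scan, which
the oracle suite enforces on hundreds of seeded fixtures.

"Uniquely mapping" is defined as: exactly one hit in the minimum-mismatch
stratum.  This follows best-stratum reporting semantics of short-read
mappers; it is an assumption, recorded here, since uniqueness is used by
the cluster scan, the gene ranking and the density maps.

## Cluster discovery

Uniquely mapping piRNA-class sequences are bucketed by the 5′ coordinate of
their single hit into non-overlapping 5-kb tiles (a "sliding" window with
step = size is the only reading compatible with merging *adjacent*
windows).  Tiles with ≥ 10 distinct sequences qualify; maximal runs of
adjacent qualifying tiles become clusters; boundaries are refined to the
furthest member-read extents.  Qualifying tiles separated by an empty tile
are deliberately not merged (`merge_gap_windows = 0`), producing smaller,
better-defined loci; a gap-tolerant mode exists for comparison.  Window
membership by 5′ coordinate makes reads straddling tile edges unambiguous.
Because the window exceeds the maximum read length, called clusters are
provably disjoint, and this is asserted on every run.

Reported cluster size is `round(length / 1000)` kb, reproducing printed
cluster tables.  Cluster summaries: plus-strand fraction over distinct
member sequences; per-library proportions over member read occurrences;
exclusive fraction = distinct member sequences seen in exactly one library.

The TE-content null model draws `n_samples` (default 1000) intervals of
exactly the cluster's length — "similar size" read strictly, which removes
a free parameter — with starts uniform over all valid (contig, offset)
pairs.  Coverage is the fraction of bases under the union of TE features;
the element count is the number of features overlapping by ≥ 1 bp.
z-scores use the sample standard deviation (n−1); a zero-variance null
leaves z undefined and flags the result rather than dividing by zero.  An
empirical two-sided p (distance from the null mean, +1 continuity
correction) is reported without claiming any named test.  The null is
seeded and bit-reproducible.

## Ping-pong statistics

Pairs are all (plus, minus) hit combinations on one contig whose intervals
share at least one position with the minus 5′ end at or right of the plus
5′ end.  The overlap metric is `minus 5′ − plus 5′ + 1`, under which the
ping-pong signature is exactly 10.  The shared-position condition bounds
the overlap by `len_plus + len_minus − 1`, not by either read alone — a
48-nt 5′ distance between two 28-mers sharing 8 positions is a valid
(non-signature) pair.  The signature fraction is computed over distinct
sequences participating in ≥ 1 pair (numerator: those in ≥ 1 pair of
overlap exactly 10); a multiplicity-weighted variant is exposed via the
`weights` argument.  Pairing defaults to uniquely mapping hits, consistent
with the cluster analyses.  U1/A10: one mate starts with U and the other
carries A at position 10, each read in its own 5′→3′ orientation; mates
shorter than 10 nt cannot satisfy the A10 side.

## Targeting and transgene detection

Two deliberately distinct pathways: target *classification* intersects
genomic hits with annotation intervals (gene/TE/both/neither per sequence),
while TE-family *tallies* match reads full-length against family consensus
sequences.  The two disagree by construction (a consensus match needs no
annotated genomic copy under the hit) and both are reported.  Tally tables
carry read-weighted and distinct-sequence counts; every percentage is
re-derived from its counts by an internal consistency checker on every run
(half-up rounding at 2 decimals; 1 decimal for gene densities).

Gene density = distinct uniquely mapping piRNAs with 5′ inside the full
annotated gene span, divided by span length.  Strand percents are
sense/antisense relative to the gene and sum to 100.

Transgene-derived piRNAs must have zero genome hits at the configured
budget and an exact full-length match to a transformation plasmid, treated
as circular (origin-spanning reads are found by appending the first L−1
bases; a flag disables this).  Reads matching more than one plasmid —
vectors share backbone blocks — are flagged ambiguous and reported
parenthesised rather than double-counted.

## Pool-size estimation

Plain Lincoln–Petersen, `N̂ = n_a·n_b/k`, over every unordered pair of
libraries from different replicate groups; pairs with `k = 0` are dropped
with a warning, and mean/min/max summarise the rest.  The Chapman
correction is available behind a flag but is not the default.  Eligibility:
length ≥ 24 nt, genome-mapped input, and within-library multiplicity
exactly 1 — the duplicate-exclusion rule.  Its rationale is visible in the
validation harness: with log-normally skewed shared abundance the two
capture occasions are positively correlated (abundant sequences are caught
in both libraries), inflating `k` and biasing `N̂` downward; excluding
within-library duplicates removes the most abundance-inflated sequences
and demonstrably shrinks |bias| (a per-pair exclusion by a literal reading;
a global-exclusion mode exists).  The harness simulates labelled pools —
capture–recapture depends only on identity and multiplicity, so labels
stand in for sequences — and recovers a uniform-abundance pool of 10⁵ to
within 5% from two draws of 2×10⁴ (50 replicates).

## Synthetic-data generator

The generator emulates the statistical structure of whole-adult mosquito
small-RNA libraries: a sharp 21-nt peak beside a broad 24–31-nt peak with
mode 28 (discrete weights 2:4:7:12:20:12:7:4); 5′-U probability 0.8
(Bernoulli — the window is resampled until the first base is, or is not,
T, so the realized rate equals the configured one exactly); clusters
emitting 85% of the pool with per-cluster strand bias 0.9; log-normal
(σ = 1) abundance by default.  Every pool member is a genomic substring,
so mapping is consistent by construction.

Ping-pong partners: with probability `p_partner` (default 0.4) a cluster
sequence gains an opposite-strand partner; the partner's 5′ overlap is
exactly 10 with probability `p_pingpong` (default 0.195, the signature
fraction observed among overlapping piRNA pairs in the mosquito survey)
and a non-signature length (4–18, excluding 10) otherwise.  With a 10-nt
overlap the partner's base 10 is the genomic complement of the primary's
base 1, so A10 arises from U1 primaries by complementarity; the generator
records realized A10 status rather than mutating sequences (which would
break mappability).

TE copies overwrite background sequence at recorded positions; MITE
consensus sequences carry 30-nt terminal inverted repeats; copies inside a
cluster adopt its majority orientation with probability 0.9.  Planted
clusters keep a minimum mutual distance (default 11 kb, more than two scan
windows): loci closer than one window are indistinguishable to the scan
and would merge.  All outputs are bit-reproducible from (config, seed).

### Recovery experiments and their problem sizes

The validation experiments are sized to run on a desktop in minutes:

* *Cluster recovery*: 1 Mb genome (4 × 250 kb), 10 clusters of 35–60 kb
  (matching the size range of real top clusters), ~600 distinct reads per
  cluster against ~30 background reads genome-wide, uniform abundance, no
  TE copies (repeats would eject reads from the unique-mapping scan),
  20 seeds.  The windowed scan's boundary error is ± 1 window, so clusters
  of ≥ 10 windows are required for Jaccard ≥ 0.9 recovery; every planted
  cluster is recovered with zero false calls under these conditions.
* *Generator-truth recovery*: 5′-U and strand-bias rates are checked on a
  10⁴-sequence pool without partners (partner 5′ bases are determined by
  complementarity, not by the Bernoulli rate); the signature fraction is
  checked on a sparse configuration (8 Mb genome, ~3.5 Mb of cluster
  territory, every primary partnered) where chance opposite-strand
  overlaps contaminate the statistic by well under the 99% binomial band
  width.
* *Estimator recovery*: pools of 10⁵ (uniform) and 5×10⁴ (log-normal)
  labelled sequences, libraries of 2×10⁴ draws, 50/25 replicates.

What passing these experiments does **not** show: the generator has no
sequencing-error or quality model, no true transcriptional background, and
its clusters emit reads uniformly rather than with the positional
heterogeneity of real loci; real libraries will stress adapter trimming
and contaminant filtering harder than the spiked fixtures do.  Genome-scale
published quantities that depend on the original sequencing libraries
(overall TE-targeting percentages, the 1.7×10⁷ pool estimate, 20.6%/84%
cluster coverage) are not reproducible at this scale; the package instead
verifies their printed arithmetic exactly and its own methods by recovery
from synthetic truth.

## Degenerate inputs and tie-breaks

Empty read files yield empty libraries with a warning; annotation records
with empty intervals are rejected with a warning; SAM records with
indel/clip CIGARs are skipped and counted; k = 0 library pairs are dropped
and counted; a zero-variance null flags its z-scores as undefined.
Clusters are ranked by unique-read count descending with ties broken by
(contig name, start); report row order is always stated by sort keys, and
rewriting any report is byte-identical.
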