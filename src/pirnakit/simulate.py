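"""Seeded synthetic-data generator for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:

* a multi-contig genome with transposable-element insertions (including
  MITEs with terminal inverted repeats) and gene annotations;
* genomically clustered piRNA production with per-cluster strand bias;
* a latent pool of distinct piRNA sequences (genomic substrings, so every
  pool member is mappable) with a Bernoulli 5'-U bias;
* ping-pong partners: opposite-strand sequences whose 5' ends overlap the
  primary's by exactly 10 nt with probability ``p_pingpong`` (otherwise by a
  non-signature length) -- with a 10-nt overlap the partner's base 10 is the
  complement of the primary's base 1, so A10 arises from U1 primaries;
* libraries sampled from the pool with a skewed abundance distribution, an
  optional 21-nt endo-siRNA background, and optional adapter/contaminant/
  transgene spiking.

Everything is driven by one ``numpy`` generator, so outputs are
bit-reproducible from (config, seed).  A machine-readable truth set records
what was planted for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import TEConsensus
from .model import Assembly, Feature, GENE, Interval, Library, TE, reverse_complement

BASES = np.array(list("ACGT"))

#: discrete piRNA length distribution: 24-31 nt with the mode at 28 nt
PIRNA_LENGTHS = np.arange(24, 32)
PIRNA_LENGTH_WEIGHTS = np.array([2.0, 4, 7, 12, 20, 12, 7, 4])
PIRNA_LENGTH_WEIGHTS /= PIRNA_LENGTH_WEIGHTS.sum()

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults encode the structure observed in whole-adult mosquito
    small-RNA libraries: a sharp 21-nt endo-siRNA peak next to a broad
    24-31-nt piRNA peak centered at 28 nt, a strong 5'-U bias, most piRNAs
    arising from a minority of the genome organised in strand-biased
    clusters, and a ~0.2 signature fraction among overlapping pairs.
    """

    seed: int = 0
    # genome
    n_contigs: int = 4
    contig_length: int = 250_000
    # transposable elements
    n_te_families: int = 6
    te_length_range: Tuple[int, int] = (600, 1500)
    mite_length_range: Tuple[int, int] = (150, 400)
    tir_length: int = 30
    class_mix: Tuple[float, float, float] = (0.4, 0.3, 0.3)  # retro, DNA, MITE
    copies_per_family: int = 5
    te_divergence: float = 0.05
    cluster_te_orientation_bias: float = 0.9
    # genes
    n_genes: int = 30
    gene_length_range: Tuple[int, int] = (800, 5000)
    # piRNA clusters
    n_clusters: int = 8
    cluster_length_range: Tuple[int, int] = (10_000, 30_000)
    cluster_margin: int = 11_000  # min gap between planted clusters (> 2 windows)
    cluster_weight: float = 0.85  # share of the pool emitted by clusters
    strand_bias: float = 0.9  # per-cluster P(plus strand)
    # latent pool
    pool_size: int = 20_000
    p_u1: float = 0.8
    p_partner: float = 0.4  # P(a cluster sequence gets an overlapping partner)
    p_pingpong: float = 0.195  # P(that partner's 5' overlap is exactly 10)
    abundance_model: str = "lognormal"
    abundance_sigma: float = 1.0
    # library sampling
    depth: int = 50_000
    sirna_weight: float = 0.25  # fraction of reads drawn as 21-nt background
    adapter: str = DEFAULT_ADAPTER
    contaminant_rate: float = 0.0
    raw_reads: bool = False  # emit untrimmed insert+adapter reads

    def __post_init__(self) -> None:
        for p in (
            self.cluster_weight,
            self.strand_bias,
            self.p_u1,
            self.p_partner,
            self.p_pingpong,
            self.sirna_weight,
            self.contaminant_rate,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not (0.5 <= self.strand_bias <= 1.0):
            raise ValueError("strand_bias is P(majority strand), in [0.5, 1]")


@dataclass
class ClusterTruth:
    interval: Interval
    strand_bias: float
    major_strand: str


@dataclass
class PoolMember:
    sequence: str
    origin: str  # cluster | background | partner
    contig: str
    five_prime: int
    strand: str
    cluster_id: Optional[int] = None
    partner_of: Optional[str] = None
    overlap: Optional[int] = None  # planted 5' overlap with the primary
    u1_forced: Optional[bool] = None


@dataclass
class SimGenome:
    assembly: Assembly
    te_features: List[Feature]
    gene_features: List[Feature]
    consensus: List[TEConsensus]
    clusters: List[ClusterTruth]
    contaminants: Dict[str, str]


@dataclass
class Pool:
    members: List[PoolMember]
    weights: np.ndarray  # shared abundance weights, sum 1

    @property
    def size(self) -> int:
        return len(self.members)

    def truth_u1_fraction(self) -> float:
        primary = [m for m in self.members if m.origin != "partner"]
        return sum(m.sequence[0] == "T" for m in primary) / len(primary)

    def truth_signature_fraction(self) -> float:
        partners = [m for m in self.members if m.origin == "partner"]
        if not partners:
            return float("nan")
        return sum(m.overlap == 10 for m in partners) / len(partners)


@dataclass
class LibraryTruth:
    library_id: str
    depth: int
    n_pirna_reads: int
    n_sirna_reads: int
    n_contaminant_reads: int
    n_transgene_reads: int
    pool_indices: List[int] = field(default_factory=list)


@dataclass
class SimDataset:
    config: SimConfig
    genome: SimGenome
    pool: Pool
    libraries: List[Library]
    truth: List[LibraryTruth]


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        arr[hit] = BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(arr)


def _place_nonoverlapping(
    rng: np.random.Generator,
    contig_lengths: Dict[str, int],
    lengths: Sequence[int],
    occupied: Dict[str, List[Tuple[int, int]]],
    max_tries: int = 200,
    margin: int = 0,
) -> List[Tuple[str, int, int]]:
    """Place intervals of the given lengths without overlapping ``occupied``
    spans (which are updated in place).  ``margin`` enforces a minimum gap
    between placed intervals (planted clusters must be separated by more
    than a scan window to be identifiable as distinct loci)."""
    names = list(contig_lengths)
    placed = []
    for length in lengths:
        for _ in range(max_tries):
            name = names[int(rng.integers(0, len(names)))]
            limit = contig_lengths[name] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            spans = occupied.setdefault(name, [])
            if all(end + margin <= s or start >= e + margin for s, e in spans):
                spans.append((start, end))
                placed.append((name, start, end))
                break
        else:
            raise ValueError(
                f"could not place an interval of {length} bp; genome too full"
            )
    return placed


def build_genome(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimGenome:
    """Random genome with planted clusters, TE copies and genes.

    TE copies overwrite background sequence (contig lengths stay fixed);
    MITE consensus sequences carry terminal inverted repeats.  Copies that
    land inside a planted cluster take the cluster's majority orientation
    with probability ``cluster_te_orientation_bias``.  Fully determined by
    the generator state passed in.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    contigs = {
        f"contig{i + 1}": _random_seq(rng, config.contig_length)
        for i in range(config.n_contigs)
    }
    contig_lengths = {n: len(s) for n, s in contigs.items()}

    # consensus library
    n_retro, n_dna = (
        max(1, round(config.n_te_families * config.class_mix[0])),
        max(1, round(config.n_te_families * config.class_mix[1])),
    )
    n_mite = max(0, config.n_te_families - n_retro - n_dna)
    consensus: List[TEConsensus] = []
    for i in range(n_retro):
        length = int(rng.integers(*config.te_length_range))
        consensus.append(
            TEConsensus(f"RTE{i + 1}", _random_seq(rng, length), "retrotransposon")
        )
    for i in range(n_dna):
        length = int(rng.integers(*config.te_length_range))
        consensus.append(TEConsensus(f"DTE{i + 1}", _random_seq(rng, length), "DNA"))
    for i in range(n_mite):
        length = int(rng.integers(*config.mite_length_range))
        tir = _random_seq(rng, config.tir_length)
        internal = _random_seq(rng, max(length - 2 * config.tir_length, 10))
        consensus.append(
            TEConsensus(f"MITE{i + 1}", tir + internal + reverse_complement(tir), "MITE")
        )

    occupied: Dict[str, List[Tuple[int, int]]] = {}

    # clusters first (they are the scarcest resource)
    cluster_lengths = [
        int(rng.integers(*config.cluster_length_range))
        for _ in range(config.n_clusters)
    ]
    cluster_truth: List[ClusterTruth] = []
    for name, start, end in _place_nonoverlapping(
        rng, contig_lengths, cluster_lengths, occupied, margin=config.cluster_margin
    ):
        major = "+" if rng.random() < 0.5 else "-"
        cluster_truth.append(
            ClusterTruth(Interval(name, start, end, "."), config.strand_bias, major)
        )

    # TE copies (allowed inside clusters: separate occupancy bookkeeping,
    # but TE copies never overlap each other)
    te_occupied: Dict[str, List[Tuple[int, int]]] = {}
    te_features: List[Feature] = []
    cluster_by_contig: Dict[str, List[ClusterTruth]] = {}
    for ct in cluster_truth:
        cluster_by_contig.setdefault(ct.interval.contig, []).append(ct)
    for cons in consensus:
        lengths = [len(cons.sequence)] * config.copies_per_family
        for name, start, end in _place_nonoverlapping(
            rng, contig_lengths, lengths, te_occupied
        ):
            host = next(
                (
                    ct
                    for ct in cluster_by_contig.get(name, ())
                    if start >= ct.interval.start and end <= ct.interval.end
                ),
                None,
            )
            if host is not None and rng.random() < config.cluster_te_orientation_bias:
                strand = host.major_strand
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            copy = _mutate(rng, cons.sequence, config.te_divergence)
            if strand == "-":
                copy = reverse_complement(copy)
            contigs[name] = contigs[name][:start] + copy + contigs[name][end:]
            te_features.append(
                Feature(Interval(name, start, end, strand), TE, cons.name, cons.te_class)
            )

    # genes: non-overlapping with each other
    gene_occupied: Dict[str, List[Tuple[int, int]]] = {}
    gene_lengths = [
        int(rng.integers(*config.gene_length_range)) for _ in range(config.n_genes)
    ]
    gene_features = [
        Feature(
            Interval(name, start, end, "+" if rng.random() < 0.5 else "-"),
            GENE,
            f"GENE{i + 1:04d}",
        )
        for i, (name, start, end) in enumerate(
            _place_nonoverlapping(rng, contig_lengths, gene_lengths, gene_occupied)
        )
    ]

    contaminants = {"rRNA_like_1": _random_seq(rng, 2000)}
    return SimGenome(
        Assembly(contigs),
        te_features,
        gene_features,
        consensus,
        cluster_truth,
        contaminants,
    )


def _draw_pirna_length(rng: np.random.Generator) -> int:
    return int(rng.choice(PIRNA_LENGTHS, p=PIRNA_LENGTH_WEIGHTS))


def _window_sequence(
    assembly: Assembly, contig: str, start: int, length: int, strand: str
) -> str:
    s = assembly.contigs[contig][start : start + length]
    return s if strand == "+" else reverse_complement(s)


def _draw_cluster_seq(
    rng: np.random.Generator,
    assembly: Assembly,
    cluster: ClusterTruth,
    want_u1: bool,
    max_tries: int = 60,
) -> Tuple[str, str, int, int]:
    """One sequence from a cluster: (sequence, strand, start, length).

    The first base is Bernoulli-controlled: resample the window until the 5'
    base is (or is not) T, so the realized 5'-U rate equals the configured
    probability exactly.
    """
    iv = cluster.interval
    if rng.random() < cluster.strand_bias:
        strand = cluster.major_strand
    else:
        strand = "-" if cluster.major_strand == "+" else "+"
    for _ in range(max_tries):
        length = _draw_pirna_length(rng)
        start = int(rng.integers(iv.start, max(iv.end - length, iv.start + 1)))
        seq = _window_sequence(assembly, iv.contig, start, length, strand)
        if "N" in seq or len(seq) < length:
            continue
        if (seq[0] == "T") == want_u1:
            return seq, strand, start, length
    return seq, strand, start, length  # accept the last draw rather than fail


def _partner_overlap(rng: np.random.Generator, config: SimConfig) -> int:
    if rng.random() < config.p_pingpong:
        return 10
    choices = [d for d in range(4, 19) if d != 10]
    return int(choices[int(rng.integers(0, len(choices)))])


def build_pool(
    config: SimConfig,
    genome: SimGenome,
    rng: Optional[np.random.Generator] = None,
) -> Pool:
    """Latent pool of ``pool_size`` distinct genomic substrings with origins.

    ``cluster_weight`` of the pool comes from planted clusters (strand
    Bernoulli of the cluster bias, 5'-U Bernoulli ``p_u1``); the rest is
    genomic background.  With probability ``p_partner`` a cluster sequence
    gains an opposite-strand partner whose 5' overlap is 10 nt with
    probability ``p_pingpong`` (A10 then follows from a U1 primary by
    complementarity) and a non-signature length otherwise.  Partners count
    toward the pool size; all members are distinct.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    assembly = genome.assembly
    members: List[PoolMember] = []
    seen = set()
    n_target = config.pool_size
    cluster_lengths = np.array([c.interval.length for c in genome.clusters], dtype=float)
    cluster_p = (
        cluster_lengths / cluster_lengths.sum() if len(genome.clusters) else None
    )
    contig_names = list(assembly.contigs)
    contig_lengths = np.array([assembly.lengths[n] for n in contig_names], dtype=float)
    contig_p = contig_lengths / contig_lengths.sum()

    max_total_tries = 200 * n_target
    tries = 0
    while len(members) < n_target and tries < max_total_tries:
        tries += 1
        from_cluster = bool(genome.clusters) and rng.random() < config.cluster_weight
        want_u1 = rng.random() < config.p_u1
        if from_cluster:
            ci = int(rng.choice(len(genome.clusters), p=cluster_p))
            cluster = genome.clusters[ci]
            seq, strand, start, length = _draw_cluster_seq(
                rng, assembly, cluster, want_u1
            )
            contig = cluster.interval.contig
            origin = "cluster"
            cluster_id = ci
        else:
            contig = contig_names[int(rng.choice(len(contig_names), p=contig_p))]
            length = _draw_pirna_length(rng)
            limit = assembly.lengths[contig] - length
            strand = "+" if rng.random() < 0.5 else "-"
            seq = ""
            for _ in range(60):
                start = int(rng.integers(0, limit))
                seq = _window_sequence(assembly, contig, start, length, strand)
                if "N" not in seq and (seq[0] == "T") == want_u1:
                    break
            origin = "background"
            cluster_id = None
        if not seq or seq in seen:
            continue
        five_prime = start if strand == "+" else start + length - 1
        member = PoolMember(
            seq, origin, contig, five_prime, strand, cluster_id, u1_forced=want_u1
        )
        members.append(member)
        seen.add(seq)

        if (
            origin == "cluster"
            and len(members) < n_target
            and rng.random() < config.p_partner
        ):
            partner = _make_partner(rng, config, assembly, member)
            if partner is not None and partner.sequence not in seen:
                members.append(partner)
                seen.add(partner.sequence)
    if len(members) < n_target:
        raise ValueError(
            "could not draw enough distinct pool sequences; enlarge the genome"
        )

    if config.abundance_model == "uniform":
        weights = np.full(len(members), 1.0 / len(members))
    elif config.abundance_model == "lognormal":
        w = rng.lognormal(0.0, config.abundance_sigma, size=len(members))
        weights = w / w.sum()
    else:
        raise ValueError(f"unknown abundance model {config.abundance_model!r}")
    return Pool(members, weights)


def _make_partner(
    rng: np.random.Generator,
    config: SimConfig,
    assembly: Assembly,
    primary: PoolMember,
) -> Optional[PoolMember]:
    d = _partner_overlap(rng, config)
    length = max(_draw_pirna_length(rng), d)
    contig_len = assembly.lengths[primary.contig]
    if primary.strand == "+":
        m = primary.five_prime + d - 1  # partner minus-strand 5' coordinate
        start = m - length + 1
        if start < 0 or m + 1 > contig_len:
            return None
        seq = _window_sequence(assembly, primary.contig, start, length, "-")
        strand, five_prime = "-", m
    else:
        pf = primary.five_prime - d + 1  # partner plus-strand 5' coordinate
        start = pf
        if start < 0 or start + length > contig_len:
            return None
        seq = _window_sequence(assembly, primary.contig, start, length, "+")
        strand, five_prime = "+", pf
    if "N" in seq:
        return None
    return PoolMember(
        seq,
        "partner",
        primary.contig,
        five_prime,
        strand,
        primary.cluster_id,
        partner_of=primary.sequence,
        overlap=d,
    )


def sample_library(
    pool: Pool,
    genome: SimGenome,
    config: SimConfig,
    library_id: str,
    rng: Optional[np.random.Generator] = None,
    replicate_group: str = "",
    transgene_reads: Sequence[str] = (),
) -> Tuple[Library, LibraryTruth]:
    """Multinomial draw of one library from the pool.

    ``depth`` reads split into a piRNA fraction (multinomial over the pool's
    shared abundance weights), a 21-nt endo-siRNA background, and optional
    contaminant and transgene spikes.  With ``raw_reads`` the 3' adapter is
    appended (preprocessing input); otherwise reads are emitted trimmed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.depth < 1:
        raise ValueError("library depth must be >= 1")
    depth = config.depth
    n_transgene = len(transgene_reads)
    n_contam = int(round(depth * config.contaminant_rate))
    n_sirna = int(round(depth * config.sirna_weight))
    n_pirna = depth - n_sirna - n_contam - n_transgene
    if n_pirna < 1:
        raise ValueError("depth too small for the configured spike rates")

    lib = Library(id=library_id, replicate_group=replicate_group)

    def _add(seq: str, count: int = 1) -> None:
        if config.raw_reads:
            seq = seq + config.adapter
        lib.add(seq, count)

    counts = rng.multinomial(n_pirna, pool.weights)
    drawn = np.nonzero(counts)[0]
    for i in drawn:
        _add(pool.members[i].sequence, int(counts[i]))

    assembly = genome.assembly
    contig_names = list(assembly.contigs)
    for _ in range(n_sirna):
        contig = contig_names[int(rng.integers(0, len(contig_names)))]
        limit = assembly.lengths[contig] - 21
        start = int(rng.integers(0, limit))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _window_sequence(assembly, contig, start, 21, strand)
        if "N" not in seq:
            _add(seq)

    contam_names = sorted(genome.contaminants)
    for _ in range(n_contam):
        name = contam_names[int(rng.integers(0, len(contam_names)))]
        ref = genome.contaminants[name]
        length = int(rng.integers(18, 32))
        start = int(rng.integers(0, len(ref) - length))
        _add(ref[start : start + length])

    for seq in transgene_reads:
        _add(seq)

    truth = LibraryTruth(
        library_id=library_id,
        depth=depth,
        n_pirna_reads=int(counts.sum()),
        n_sirna_reads=n_sirna,
        n_contaminant_reads=n_contam,
        n_transgene_reads=n_transgene,
        pool_indices=[int(i) for i in drawn],
    )
    return lib, truth


def simulate_dataset(
    config: SimConfig, n_libraries: int = 2, replicate_groups: Optional[Sequence[str]] = None
) -> SimDataset:
    """Genome + pool + ``n_libraries`` sampled libraries from one seed."""
    rng = np.random.default_rng(config.seed)
    genome = build_genome(config, rng)
    pool = build_pool(config, genome, rng)
    libraries: List[Library] = []
    truths: List[LibraryTruth] = []
    for i in range(n_libraries):
        group = (
            replicate_groups[i]
            if replicate_groups is not None
            else f"group{i + 1}"
        )
        lib, truth = sample_library(
            pool, genome, config, f"lib{i + 1}", rng, replicate_group=group
        )
        libraries.append(lib)
        truths.append(truth)
    return SimDataset(config, genome, pool, libraries, truths)


def truth_as_dict(dataset: SimDataset) -> dict:
    """JSON-serialisable truth set for the dataset."""
    return {
        "config": asdict(dataset.config),
        "clusters": [
            {
                "contig": c.interval.contig,
                "start": c.interval.start,
                "end": c.interval.end,
                "strand_bias": c.strand_bias,
                "major_strand": c.major_strand,
            }
            for c in dataset.genome.clusters
        ],
        "pool_size": dataset.pool.size,
        "u1_fraction": dataset.pool.truth_u1_fraction(),
        "partner_signature_fraction": dataset.pool.truth_signature_fraction(),
        "libraries": [asdict(t) for t in dataset.truth],
    }
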