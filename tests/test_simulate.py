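import numpy as np
import pytest
from scipy import stats

from pirnakit.mapping import align_full_length
from pirnakit.model import reverse_complement
from pirnakit.preprocess import filter_matching, strip_library
from pirnakit.simulate import (
    SimConfig,
    build_genome,
    build_pool,
    sample_library,
    simulate_dataset,
    truth_as_dict,
)

SMALL = dict(
    n_contigs=2,
    contig_length=60_000,
    n_clusters=3,
    cluster_length_range=(8_000, 12_000),
    cluster_margin=6_000,
    pool_size=1_500,
    depth=5_000,
    n_te_families=4,
    copies_per_family=2,
    n_genes=8,
)


def test_same_seed_is_bit_reproducible():
    a = simulate_dataset(SimConfig(seed=5, **SMALL), n_libraries=2)
    b = simulate_dataset(SimConfig(seed=5, **SMALL), n_libraries=2)
    assert a.genome.assembly.contigs == b.genome.assembly.contigs
    assert truth_as_dict(a) == truth_as_dict(b)
    for la, lb in zip(a.libraries, b.libraries):
        assert {s: r.total for s, r in la.reads.items()} == {
            s: r.total for s, r in lb.reads.items()
        }
    c = simulate_dataset(SimConfig(seed=6, **SMALL), n_libraries=2)
    assert c.genome.assembly.contigs != a.genome.assembly.contigs


def test_mite_consensus_has_terminal_inverted_repeats():
    genome = build_genome(SimConfig(seed=2, **SMALL))
    mites = [c for c in genome.consensus if c.te_class == "MITE"]
    assert mites
    for m in mites:
        tir = m.sequence[:30]
        assert m.sequence[-30:] == reverse_complement(tir)


def test_cluster_truth_consistent_with_genome():
    genome = build_genome(SimConfig(seed=3, **SMALL))
    assert len(genome.clusters) == 3
    ivs = [c.interval for c in genome.clusters]
    for iv in ivs:
        assert iv.end <= genome.assembly.lengths[iv.contig]
    for a in ivs:
        for b in ivs:
            if a is not b and a.contig == b.contig:
                assert not a.overlaps(b)


def test_pool_members_are_genomic_substrings():
    cfg = SimConfig(seed=4, **SMALL)
    genome = build_genome(cfg)
    rng = np.random.default_rng(4)
    pool = build_pool(cfg, genome, rng)
    assert pool.size == cfg.pool_size
    assert len({m.sequence for m in pool.members}) == pool.size
    for m in pool.members[:200]:
        hits = align_full_length(m.sequence, genome.assembly, 0)
        assert any(
            h.interval.contig == m.contig
            and h.five_prime == m.five_prime
            and h.interval.strand == m.strand
            for h in hits
        )


def test_extreme_strand_bias_and_partner_probability():
    cfg = SimConfig(
        seed=7, strand_bias=1.0, p_partner=1.0, p_pingpong=1.0, **SMALL
    )
    genome = build_genome(cfg)
    pool = build_pool(cfg, genome, np.random.default_rng(7))
    clustered = [m for m in pool.members if m.origin == "cluster"]
    majors = {i: c.major_strand for i, c in enumerate(genome.clusters)}
    assert all(m.strand == majors[m.cluster_id] for m in clustered)
    partners = [m for m in pool.members if m.origin == "partner"]
    assert partners and all(m.overlap == 10 for m in partners)


def test_u1_fraction_matches_configuration():
    cfg = SimConfig(
        seed=8,
        p_u1=0.8,
        p_partner=0.0,
        n_contigs=4,
        contig_length=120_000,
        n_clusters=6,
        cluster_length_range=(10_000, 20_000),
        pool_size=10_000,
    )
    genome = build_genome(cfg)
    rng = np.random.default_rng(8)
    pool = build_pool(cfg, genome, rng)
    observed = round(pool.truth_u1_fraction() * pool.size)
    lo, hi = stats.binom.interval(0.99, pool.size, 0.8)
    assert lo <= observed <= hi


def test_sample_library_distinct_count_matches_closed_form():
    cfg = SimConfig(seed=9, abundance_model="uniform", sirna_weight=0.0, **SMALL)
    genome = build_genome(cfg)
    rng = np.random.default_rng(9)
    pool = build_pool(cfg, genome, rng)
    lib, truth = sample_library(pool, genome, cfg, "L", rng)
    n, d = pool.size, truth.n_pirna_reads
    expected = n * (1 - (1 - 1 / n) ** d)
    sd = np.sqrt(n * (1 - 1 / n) ** d * (1 - (1 - 1 / n) ** d))
    assert abs(len(truth.pool_indices) - expected) < 5 * sd


def test_spiked_adapter_and_contaminants_are_recoverable():
    cfg = SimConfig(
        seed=10, raw_reads=True, contaminant_rate=0.05, sirna_weight=0.1, **SMALL
    )
    genome = build_genome(cfg)
    rng = np.random.default_rng(10)
    pool = build_pool(cfg, genome, rng)
    lib, truth = sample_library(pool, genome, cfg, "L", rng)
    stripped, tally = strip_library(lib, cfg.adapter)
    # every raw read carries the adapter
    assert tally["unchanged"] == 0
    kept, removed = filter_matching(stripped, genome.contaminants, 0)
    n_removed = removed.total_reads
    lo, hi = stats.binom.interval(0.99, truth.depth, cfg.contaminant_rate)
    # planted contaminant reads are recovered at the configured rate
    assert lo * 0.9 <= n_removed <= hi * 1.1


def test_depth_and_probability_validation():
    with pytest.raises(ValueError):
        SimConfig(p_u1=1.5)
    with pytest.raises(ValueError):
        SimConfig(strand_bias=0.2)
    cfg = SimConfig(seed=1, sirna_weight=0.9, **{**SMALL, "depth": 1})
    genome = build_genome(cfg)
    rng = np.random.default_rng(1)
    pool = build_pool(cfg, genome, rng)
    with pytest.raises(ValueError, match="depth"):
        sample_library(pool, genome, cfg, "L", rng)
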