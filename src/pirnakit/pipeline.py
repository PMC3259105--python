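"""End-to-end orchestration into the headline report bundle.

``run_end_to_end`` drives every stage on a synthetic dataset (or
pre-loaded inputs) and writes one output directory with fixed file names:
a size x target-category table, cluster summaries, cluster TE-content null
statistics, TE-family tallies, a transgene count matrix, a gene density
ranking, the opposite-strand overlap profile, and the pool-size estimate,
plus a manifest that makes every report traceable to its configuration and
seed.  ``check_percentages`` re-derives every printed percentage from the
counts in a report and flags mismatches; it runs on every bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import __version__
from .annotate import (
    classify_targets,
    detect_transgene_pirnas,
    genome_occupancy,
    rank_gene_density,
    sense_antisense,
    tally_te_families,
)
from .clusters import (
    WindowConfig,
    call_clusters,
    coverage_summary,
    summarize_clusters,
    te_null_zscores,
    window_counts,
)
from .io import write_report
from .mapping import map_library, unique_hits
from .model import Library, merge_libraries
from .pingpong import enumerate_overlap_pairs, overlap_profile
from .poolsize import estimate_pool
from .preprocess import SizeClassRule, partition_by_size
from .published import percent
from .simulate import SimConfig, simulate_dataset

BUNDLE_FILES = (
    "size_target_table.tsv",
    "clusters.tsv",
    "cluster_null.tsv",
    "te_tally.tsv",
    "transgene_matrix.tsv",
    "gene_density.tsv",
    "overlap_profile.tsv",
    "pool_estimate.json",
    "manifest.json",
)


def run_end_to_end(
    config: SimConfig,
    outdir,
    n_libraries: int = 3,
    null_samples: int = 200,
    window_config: Optional[WindowConfig] = None,
    size_rule: Optional[SizeClassRule] = None,
) -> Dict[str, object]:
    """Run the whole pipeline on a synthetic dataset and write the bundle.

    Deterministic given (config, seed): rerunning with the same arguments
    produces a byte-identical bundle.  Returns the in-memory results keyed
    like the report files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    window_config = window_config or WindowConfig()
    size_rule = size_rule or SizeClassRule()

    dataset = simulate_dataset(config, n_libraries=n_libraries)
    genome = dataset.genome
    combined = merge_libraries(dataset.libraries)
    classes = partition_by_size(combined, size_rule)

    mapped_pool = map_library(classes["pool_pirna"], genome.assembly)
    uh = unique_hits(mapped_pool)

    counts = window_counts(uh, genome.assembly, window_config)
    clusters = call_clusters(counts, uh, window_config)
    summarize_clusters(clusters, combined)
    coverage = coverage_summary(clusters, genome.assembly, uh)

    cluster_rows = [
        {
            "rank": c.rank,
            "contig": c.interval.contig,
            "start": c.interval.start,
            "stop": c.interval.end,
            "size_kb": c.size_kb,
            "unique_pirnas": c.unique_pirna_count,
            "plus_fraction": round(c.plus_fraction, 4),
            "exclusive_fraction": round(c.exclusive_fraction, 4),
            "nearest_cluster_bp": (
                c.nearest_cluster_bp if c.nearest_cluster_bp is not None else "NA"
            ),
        }
        for c in clusters
    ]
    write_report(cluster_rows, outdir / "clusters.tsv", "TSV")

    null_rows = []
    for c in clusters[:10]:
        stats = te_null_zscores(
            c, genome.te_features, genome.assembly, null_samples, seed=config.seed
        )
        null_rows.append(
            {
                "rank": c.rank,
                "contig": c.interval.contig,
                "start": c.interval.start,
                "stop": c.interval.end,
                "te_coverage": round(stats.te_coverage, 6),
                "null_mean_coverage": round(stats.null_mean_coverage, 6),
                "z_coverage": (
                    round(stats.z_coverage, 4) if stats.z_coverage is not None else "NA"
                ),
                "te_element_count": stats.te_element_count,
                "null_mean_count": round(stats.null_mean_count, 4),
                "z_count": (
                    round(stats.z_count, 4) if stats.z_count is not None else "NA"
                ),
            }
        )
    write_report(null_rows, outdir / "cluster_null.tsv", "TSV")

    categories, size_table = classify_targets(
        map_library(combined, genome.assembly),
        genome.gene_features,
        genome.te_features,
    )
    write_report(size_table, outdir / "size_target_table.tsv", "TSV")

    class_table, family_table = tally_te_families(
        classes["pirna"], genome.consensus
    )
    ok, discrepancies = check_percentages(class_table)
    if not ok:
        raise AssertionError(f"tally percentages inconsistent: {discrepancies}")
    write_report(class_table + family_table_as_class_rows(family_table),
                 outdir / "te_tally.tsv", "TSV")

    orientation = sense_antisense(mapped_pool, genome.te_features)
    occupancy = genome_occupancy(
        genome.gene_features, genome.te_features, genome.assembly
    )

    gene_rows = rank_gene_density(genome.gene_features, uh, clusters)
    write_report(
        [
            {
                "gene": r.gene_id,
                "length_bp": r.gene_length,
                "unique_pirnas": r.unique_pirna_count,
                "density": r.density_1dp,
                "strand_percent": f"{r.sense_percent}/{r.antisense_percent}",
                "in_cluster": "yes" if r.in_cluster else "no",
            }
            for r in gene_rows
        ],
        outdir / "gene_density.tsv",
        "TSV",
    )

    pairs = enumerate_overlap_pairs(uh, min_len=size_rule.pool_min)
    profile = overlap_profile(pairs)
    write_report(
        [
            {
                "overlap": length,
                "pairs": profile.histogram[length],
                **{
                    f"freq_{b}": round(profile.base_freq[length][b], 4)
                    for b in ("A", "C", "G", "U")
                },
            }
            for length in sorted(profile.histogram)
        ],
        outdir / "overlap_profile.tsv",
        "TSV",
    )

    # transgene detection on plasmid-free libraries yields an all-zero matrix;
    # planted transgene reads are exercised by the dedicated fixtures
    plasmids = _synthetic_plasmids(config)
    _, matrix = detect_transgene_pirnas(
        classes["pirna"], genome.assembly, plasmids
    )
    matrix_rows = [
        {
            "library": lid,
            **{
                p: _matrix_cell(matrix[lid][p]) for p in sorted(plasmids)
            },
        }
        for lid in sorted(matrix)
    ]
    write_report(matrix_rows, outdir / "transgene_matrix.tsv", "TSV")

    pool_min_classes = [
        partition_by_size(lib, size_rule)["pool_pirna"] for lib in dataset.libraries
    ]
    estimate = estimate_pool(pool_min_classes, pool_min=size_rule.pool_min)
    pool_payload = {
        "mean": estimate.mean,
        "minimum": estimate.minimum,
        "maximum": estimate.maximum,
        "n_pairs": estimate.n_pairs,
        "true_pool_size": dataset.pool.size,
    }
    with open(outdir / "pool_estimate.json", "w") as fh:
        json.dump(pool_payload, fh, indent=1)
        fh.write("\n")

    manifest = {
        "tool": "pirnakit",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_digest": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_libraries": n_libraries,
        "outputs": list(BUNDLE_FILES),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return {
        "clusters": clusters,
        "coverage": coverage,
        "size_table": size_table,
        "te_tally": class_table,
        "orientation": orientation,
        "occupancy": occupancy,
        "gene_density": gene_rows,
        "overlap_profile": profile,
        "pool_estimate": estimate,
        "transgene_matrix": matrix,
        "manifest": manifest,
    }


def family_table_as_class_rows(family_table: List[dict]) -> List[dict]:
    return [
        {
            "category": f"family:{r['family']}",
            "reads": r["reads"],
            "distinct": r["distinct"],
            "pct_reads": r["pct_reads"],
            "pct_distinct": r["pct_distinct"],
        }
        for r in family_table
    ]


def _matrix_cell(cell) -> str:
    unambiguous, ambiguous = cell
    return f"{unambiguous}({ambiguous})" if ambiguous else str(unambiguous)


def _synthetic_plasmids(config: SimConfig) -> Dict[str, str]:
    """Small deterministic plasmid set (synthetic stand-ins for
    transformation vectors), derived from the run seed."""
    import numpy as np

    from .simulate import _random_seq

    rng = np.random.default_rng((config.seed * 2_654_435_761 + 17) % (2**31))
    shared = _random_seq(rng, 300)
    return {
        "vectorA": _random_seq(rng, 1500) + shared,
        "vectorB": _random_seq(rng, 1200) + shared,
    }


def check_percentages(table: Sequence[dict], decimals: int = 2):
    """Re-derive every percentage in a tally table from its counts.

    Expects rows with ``reads``/``pct_reads`` and ``distinct``/
    ``pct_distinct`` plus a ``Total`` row.  Returns ``(ok, discrepancies)``.
    """
    totals = [r for r in table if r.get("category") == "Total"]
    if not totals:
        return False, ["no Total row"]
    total_reads = totals[0]["reads"]
    total_distinct = totals[0]["distinct"]
    discrepancies: List[str] = []
    for r in table:
        for count_key, pct_key, denom in (
            ("reads", "pct_reads", total_reads),
            ("distinct", "pct_distinct", total_distinct),
        ):
            if pct_key not in r:
                continue
            expected = percent(r[count_key], denom, decimals) if denom else 0.0
            if abs(expected - r[pct_key]) > 10 ** (-decimals) / 2:
                discrepancies.append(
                    f"{r.get('category', '?')}/{pct_key}: "
                    f"printed {r[pct_key]}, recomputed {expected}"
                )
    return not discrepancies, discrepancies
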