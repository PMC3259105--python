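"""piRNA-cluster discovery by windowed genome scan.

Uniquely mapping piRNA-class reads are bucketed into non-overlapping 5-kb
tiles by their 5' coordinate; tiles holding at least ``min_unique_pirnas``
distinct sequences seed clusters, adjacent qualifying tiles are merged, and
cluster boundaries are refined to the furthest read extents.  Non-contiguous
qualifying tiles are deliberately NOT collapsed across gaps (the default
``merge_gap_windows=0``), which yields smaller, better-defined loci.

A random-interval null model compares each cluster's transposable-element
content (base coverage and element count) against equally long intervals
drawn uniformly from the assembly, summarised as z-scores.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import AlignmentHit, Assembly, Feature, Interval, Library


@dataclass
class WindowConfig:
    window_size: int = 5000
    min_unique_pirnas: int = 10
    merge_gap_windows: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 35:
            raise ValueError("window_size must exceed the maximum read length")
        if self.min_unique_pirnas < 1:
            raise ValueError("min_unique_pirnas must be >= 1")


@dataclass
class PiRNACluster:
    """A refined cluster locus with its member unique-mapping reads."""

    interval: Interval
    member_hits: List[AlignmentHit] = field(default_factory=list)
    plus_fraction: Optional[float] = None
    per_library_proportion: Dict[str, float] = field(default_factory=dict)
    exclusive_fraction: Optional[float] = None
    nearest_cluster_bp: Optional[int] = None
    rank: int = 0

    @property
    def unique_pirna_count(self) -> int:
        return len(self.member_hits)

    @property
    def size_kb(self) -> int:
        """Reported size in kb: round(length / 1000), matching how cluster
        tables print sizes."""
        return round(self.interval.length / 1000)


@dataclass
class ClusterNullStats:
    te_coverage: float
    null_mean_coverage: float
    null_sd_coverage: float
    z_coverage: Optional[float]
    p_coverage: float
    te_element_count: int
    null_mean_count: float
    null_sd_count: float
    z_count: Optional[float]
    p_count: float
    n_samples: int
    seed: int
    degenerate: bool = False


def window_counts(
    unique_hits: Sequence[AlignmentHit],
    assembly: Assembly,
    config: WindowConfig = WindowConfig(),
) -> Dict[str, Dict[int, int]]:
    """Distinct-sequence counts per window, keyed by contig then window index.

    Each uniquely mapping sequence is assigned to the window containing the
    5' coordinate of its single hit (floor(five_prime / window_size)); counts
    are of distinct sequences, never read multiplicities.
    """
    counts: Dict[str, Dict[int, int]] = {}
    seen = set()
    for hit in unique_hits:
        if hit.sequence_id in seen:
            raise ValueError(
                f"duplicate sequence in unique-hit input: {hit.sequence_id!r}"
            )
        seen.add(hit.sequence_id)
        w = hit.five_prime // config.window_size
        per = counts.setdefault(hit.interval.contig, {})
        per[w] = per.get(w, 0) + 1
    return counts


def call_clusters(
    counts: Dict[str, Dict[int, int]],
    unique_hits: Sequence[AlignmentHit],
    config: WindowConfig = WindowConfig(),
) -> List[PiRNACluster]:
    """Merge runs of qualifying windows into refined clusters.

    Maximal runs of consecutive windows with count >= ``min_unique_pirnas``
    (allowing up to ``merge_gap_windows`` empty windows inside a run) become
    one cluster each; the refined interval spans the member reads' extents.
    Clusters are ranked by unique-read count descending (ties by contig name
    then start).
    """
    by_window: Dict[Tuple[str, int], List[AlignmentHit]] = {}
    for hit in unique_hits:
        w = hit.five_prime // config.window_size
        by_window.setdefault((hit.interval.contig, w), []).append(hit)

    clusters: List[PiRNACluster] = []
    for contig, per in counts.items():
        qualifying = sorted(
            w for w, c in per.items() if c >= config.min_unique_pirnas
        )
        for run in _runs(qualifying, config.merge_gap_windows):
            members: List[AlignmentHit] = []
            for w in run:
                members.extend(by_window.get((contig, w), []))
            if not members:
                continue
            start = min(h.interval.start for h in members)
            end = max(h.interval.end for h in members)
            members.sort(key=lambda h: h.sort_key)
            clusters.append(
                PiRNACluster(Interval(contig, start, end, "."), members)
            )
    clusters.sort(
        key=lambda c: (-c.unique_pirna_count, c.interval.contig, c.interval.start)
    )
    for i, c in enumerate(clusters, start=1):
        c.rank = i
    _assert_disjoint(clusters)
    return clusters


def _runs(windows: List[int], max_gap: int) -> List[List[int]]:
    """Group sorted window indices into runs (gap between consecutive
    qualifying windows of more than ``max_gap`` empty windows splits)."""
    runs: List[List[int]] = []
    for w in windows:
        if runs and w - runs[-1][-1] <= max_gap + 1:
            runs[-1].append(w)
        else:
            runs.append([w])
    return runs


def _assert_disjoint(clusters: Sequence[PiRNACluster]) -> None:
    by_contig: Dict[str, List[PiRNACluster]] = {}
    for c in clusters:
        by_contig.setdefault(c.interval.contig, []).append(c)
    for group in by_contig.values():
        group = sorted(group, key=lambda c: c.interval.start)
        for a, b in zip(group, group[1:]):
            if a.interval.end > b.interval.start:
                raise AssertionError(
                    "overlapping clusters called; window size must exceed "
                    "the maximum read length"
                )


def summarize_clusters(
    clusters: Sequence[PiRNACluster], combined: Library
) -> List[PiRNACluster]:
    """Annotate clusters with strand bias, library support and exclusivity.

    ``combined`` is the merged library whose reads carry per-library counts.
    ``plus_fraction`` is over distinct member sequences; library proportions
    are over member read occurrences (multiplicities); ``exclusive_fraction``
    is the share of distinct member sequences present in exactly one library.
    """
    for c in clusters:
        n = len(c.member_hits)
        if n:
            plus = sum(1 for h in c.member_hits if h.interval.strand == "+")
            c.plus_fraction = plus / n
        occurrences: Dict[str, int] = {}
        exclusive = 0
        for h in c.member_hits:
            read = combined.reads.get(h.sequence_id)
            if read is None:
                continue
            libs = [lid for lid, cnt in read.counts.items() if cnt > 0]
            if len(libs) == 1:
                exclusive += 1
            for lid in libs:
                occurrences[lid] = occurrences.get(lid, 0) + read.counts[lid]
        total = sum(occurrences.values())
        if total:
            c.per_library_proportion = {
                lid: occurrences[lid] / total for lid in sorted(occurrences)
            }
        if n:
            c.exclusive_fraction = exclusive / n

    by_contig: Dict[str, List[PiRNACluster]] = {}
    for c in clusters:
        by_contig.setdefault(c.interval.contig, []).append(c)
    for group in by_contig.values():
        for c in group:
            gaps = []
            for other in group:
                if other is c:
                    continue
                if other.interval.start >= c.interval.end:
                    gaps.append(other.interval.start - c.interval.end)
                elif other.interval.end <= c.interval.start:
                    gaps.append(c.interval.start - other.interval.end)
            c.nearest_cluster_bp = min(gaps) if gaps else None
    return list(clusters)


class _TECover:
    """Per-contig merged TE intervals with prefix sums for O(log) queries."""

    def __init__(self, te_features: Sequence[Feature]):
        raw: Dict[str, List[Tuple[int, int]]] = {}
        self.feature_spans: Dict[str, Tuple[List[int], List[int]]] = {}
        for f in te_features:
            raw.setdefault(f.interval.contig, []).append(
                (f.interval.start, f.interval.end)
            )
        self.merged: Dict[str, Tuple[List[int], List[int], List[int]]] = {}
        for contig, spans in raw.items():
            spans.sort()
            merged: List[Tuple[int, int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            starts = [s for s, _ in merged]
            ends = [e for _, e in merged]
            prefix = [0]
            for s, e in merged:
                prefix.append(prefix[-1] + (e - s))
            self.merged[contig] = (starts, ends, prefix)
            fs = sorted(s for s, _ in spans)
            fe = sorted(e for _, e in spans)
            self.feature_spans[contig] = (fs, fe)

    def covered_bases(self, contig: str, start: int, end: int) -> int:
        if contig not in self.merged:
            return 0
        starts, ends, prefix = self.merged[contig]
        lo = bisect_right(ends, start)
        hi = bisect_left(starts, end)
        total = 0
        for i in range(lo, hi):
            total += min(ends[i], end) - max(starts[i], start)
        return total

    def covered_many(self, contig: str, starts_arr: np.ndarray, length: int) -> np.ndarray:
        return np.array(
            [self.covered_bases(contig, int(s), int(s) + length) for s in starts_arr],
            dtype=float,
        )

    def element_count(self, contig: str, start: int, end: int) -> int:
        """Number of TE features overlapping [start, end) by >= 1 bp."""
        if contig not in self.feature_spans:
            return 0
        fs, fe = self.feature_spans[contig]
        started_before_end = bisect_left(fs, end)
        ended_by_start = bisect_right(fe, start)
        return started_before_end - ended_by_start


def te_null_zscores(
    cluster: PiRNACluster,
    te_features: Sequence[Feature],
    assembly: Assembly,
    n_samples: int = 1000,
    seed: int = 0,
) -> ClusterNullStats:
    """Compare a cluster's TE content against random equal-length intervals.

    The null draws ``n_samples`` intervals of exactly the cluster's length,
    with the start uniform over all valid (contig, offset) pairs (contigs
    weighted by their number of valid starts).  z-scores use the sample
    standard deviation (n-1); a zero-variance null leaves z undefined and
    flags the result.  Empirical two-sided p-values use the distance from
    the null mean with a +1 continuity correction.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    length = cluster.interval.length
    cover = _TECover(te_features)
    contigs = [(n, l) for n, l in assembly.lengths.items() if l >= length]
    if not contigs:
        raise ValueError("no contig is at least as long as the cluster")
    names = [n for n, _ in contigs]
    weights = np.array([l - length + 1 for _, l in contigs], dtype=float)
    rng = np.random.default_rng(seed)
    which = rng.choice(len(names), size=n_samples, p=weights / weights.sum())
    null_cov = np.empty(n_samples)
    null_cnt = np.empty(n_samples)
    for i, ci in enumerate(which):
        name = names[ci]
        s = int(rng.integers(0, assembly.lengths[name] - length + 1))
        null_cov[i] = cover.covered_bases(name, s, s + length) / length
        null_cnt[i] = cover.element_count(name, s, s + length)

    iv = cluster.interval
    obs_cov = cover.covered_bases(iv.contig, iv.start, iv.end) / length
    obs_cnt = cover.element_count(iv.contig, iv.start, iv.end)

    def _z_p(obs: float, null: np.ndarray):
        mean = float(null.mean())
        sd = float(null.std(ddof=1))
        z = (obs - mean) / sd if sd > 0 else None
        p = (1 + int(np.sum(np.abs(null - mean) >= abs(obs - mean)))) / (
            n_samples + 1
        )
        return mean, sd, z, p

    mean_cov, sd_cov, z_cov, p_cov = _z_p(obs_cov, null_cov)
    mean_cnt, sd_cnt, z_cnt, p_cnt = _z_p(obs_cnt, null_cnt)
    return ClusterNullStats(
        te_coverage=obs_cov,
        null_mean_coverage=mean_cov,
        null_sd_coverage=sd_cov,
        z_coverage=z_cov,
        p_coverage=p_cov,
        te_element_count=obs_cnt,
        null_mean_count=mean_cnt,
        null_sd_count=sd_cnt,
        z_count=z_cnt,
        p_count=p_cnt,
        n_samples=n_samples,
        seed=seed,
        degenerate=(z_cov is None or z_cnt is None),
    )


def coverage_summary(
    clusters: Sequence[PiRNACluster],
    assembly: Assembly,
    unique_hits: Sequence[AlignmentHit],
) -> Dict[str, float]:
    """Genome fraction occupied by clusters and the fraction of distinct
    uniquely mapping piRNAs whose 5' end lies inside any cluster."""
    genome = assembly.total_length
    in_cluster_len = sum(c.interval.length for c in clusters)
    spans: Dict[str, List[Tuple[int, int]]] = {}
    for c in clusters:
        spans.setdefault(c.interval.contig, []).append(
            (c.interval.start, c.interval.end)
        )
    for v in spans.values():
        v.sort()
    inside = 0
    for hit in unique_hits:
        fp = hit.five_prime
        for s, e in spans.get(hit.interval.contig, ()):
            if s <= fp < e:
                inside += 1
                break
    n = len(unique_hits)
    return {
        "genome_fraction_in_clusters": in_cluster_len / genome if genome else 0.0,
        "pirna_fraction_from_clusters": inside / n if n else 0.0,
    }
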