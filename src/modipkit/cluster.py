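"""Gap-tolerant clustering of mapped reads into candidate oxidation regions.

Mapped, denoised reads are sorted by chromosome and start, then scanned left
to right: a read joins the open cluster when the distance from the cluster's
right edge to the read's start is at most ``gap`` (overlapping or abutting
reads always join at the default gap of 0); otherwise the cluster closes with
its member count and a new one opens.  Each chromosome is processed
independently, so memory never holds more than one chromosome's reads at a
time beyond the initial bucketing.

Outputs are BED5: a membership file (comma-joined member read ids in the name
column) and a count file (member count in the score column), plus a
region-by-sample count table for downstream differential statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from modipkit.core_io import (
    Cluster,
    ConfigError,
    DataError,
    GenomicInterval,
    MappedRead,
    UsageError,
    write_bed,
)

MAX_SUPPORTED_GAP = 50  # the exposed option range is 0-50 bp


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering options.

    gap:            largest distance (bp) between non-overlapping consecutive
                    reads still merged into one cluster (default 0; 0-50
                    supported).
    require_overlap: strict mode — merge only genuinely overlapping reads
                    (abutting reads stay separate; ignores ``gap``).
    """

    gap: int = 0
    require_overlap: bool = False
    emit_membership: bool = True
    emit_counts: bool = True

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ConfigError("gap must be non-negative")
        if self.gap > MAX_SUPPORTED_GAP:
            raise ConfigError(f"gap above the supported range 0-{MAX_SUPPORTED_GAP}")


def _check_mapped(reads: Iterable[MappedRead]) -> list[MappedRead]:
    out = []
    for read in reads:
        if getattr(read, "interval", None) is None:
            raise DataError(f"read {read.read_id} has no mapped interval")
        out.append(read)
    return out


def iter_chromosome_groups(reads: Iterable[MappedRead]
                           ) -> Iterator[tuple[str, list[MappedRead]]]:
    """Yield (chrom, reads sorted by start/end) per chromosome, in chromosome
    order.  This is the streaming unit: downstream stages never need more than
    one chromosome's group at a time."""
    buckets: dict[str, list[MappedRead]] = {}
    for read in _check_mapped(reads):
        buckets.setdefault(read.interval.chrom, []).append(read)
    for chrom in sorted(buckets):
        group = sorted(
            buckets[chrom], key=lambda r: (r.interval.start, r.interval.end)
        )
        yield chrom, group


def sort_reads(reads: Iterable[MappedRead]) -> list[MappedRead]:
    """Stable sort by (chrom, start, end); ties keep input order."""
    return [read for _, group in iter_chromosome_groups(reads) for read in group]


def _joins(cluster_end: int, read: MappedRead, config: ClusterConfig) -> bool:
    if config.require_overlap:
        return read.interval.start < cluster_end
    return read.interval.start - cluster_end <= config.gap


def build_clusters(sorted_reads: Sequence[MappedRead],
                   config: ClusterConfig | int = ClusterConfig()) -> list[Cluster]:
    """Merge sorted reads into clusters under the gap rule.

    Input must already be sorted as by :func:`sort_reads`; unsorted input
    raises :class:`UsageError`.
    """
    if isinstance(config, int):
        config = ClusterConfig(gap=config)
    reads = _check_mapped(sorted_reads)
    for prev, cur in zip(reads, reads[1:]):
        if (cur.interval.chrom, cur.interval.start, cur.interval.end) < (
            prev.interval.chrom, prev.interval.start, prev.interval.end
        ):
            raise UsageError(
                f"reads not sorted: {cur.read_id} follows {prev.read_id}"
            )
    clusters: list[Cluster] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    members: list[str] = []

    def close() -> None:
        if members:
            clusters.append(
                Cluster(GenomicInterval(cur_chrom, cur_start, cur_end),
                        list(members))
            )

    for read in reads:
        iv = read.interval
        if cur_chrom == iv.chrom and _joins(cur_end, read, config):
            cur_end = max(cur_end, iv.end)
            members.append(read.read_id)
        else:
            close()
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            members = [read.read_id]
    close()
    return clusters


def write_cluster_outputs(clusters: Sequence[Cluster],
                          membership_path: str | os.PathLike,
                          counts_path: str | os.PathLike) -> None:
    """Write the two BED5 result files.

    Membership file: name column holds the comma-joined member read ids.
    Count file: name column holds ``cluster_<ordinal>``; score is the count.
    """
    write_bed(
        [(c.interval, ",".join(c.members), c.count) for c in clusters],
        membership_path,
    )
    write_bed(
        [(c.interval, f"cluster_{i + 1}", c.count)
         for i, c in enumerate(clusters)],
        counts_path,
    )


def _merge_regions(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping-or-abutting intervals into disjoint regions."""
    regions: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if regions and regions[-1].chrom == iv.chrom and iv.start <= regions[-1].end:
            last = regions[-1]
            regions[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, iv.end)
            )
        else:
            regions.append(iv)
    return regions


def export_count_table(clusters_by_sample: Mapping[str, Sequence[Cluster]]
                       ) -> pd.DataFrame:
    """Region x sample count matrix for downstream differential statistics.

    Rows are the merged union of all samples' cluster intervals; each cell is
    the number of that sample's reads falling in the row region (the summed
    member counts of the sample's clusters overlapping it).  Columns:
    region_id, chrom, start, end, then one column per sample.
    """
    if not clusters_by_sample:
        raise DataError("need at least one sample")
    all_intervals = [
        c.interval for clusters in clusters_by_sample.values() for c in clusters
    ]
    regions = _merge_regions(all_intervals)
    if not regions:
        raise DataError("no clusters in any sample: empty region union")
    rows: list[dict] = []
    for i, region in enumerate(regions):
        row: dict = {
            "region_id": f"region_{i + 1}",
            "chrom": region.chrom,
            "start": region.start,
            "end": region.end,
        }
        for sample, clusters in clusters_by_sample.items():
            row[sample] = sum(
                c.count for c in clusters if region.overlap(c.interval) > 0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_count_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the count table as TSV with a header row."""
    table.to_csv(path, sep="\t", index=False)
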