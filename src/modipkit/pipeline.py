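"""End-to-end pipeline driver: generate, map, screen, denoise, cluster.

Stage order mirrors the intended analysis of real MoDIP-seq data: reads are
first mapped in the strict ungapped regime; reads it leaves unaligned are
escalated to the gapped regime (the indel-tolerant aligner); mapped and
unmapped sets are screened for repeat composition separately; mapped reads
are background-subtracted against the negative-control set; the survivors are
clustered into candidate oxidation regions and exported as BED plus a
region-by-sample count table.  Every stage's record counts go into a flat
key=value run manifest, alongside the seed and package version, so two runs
with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from modipkit import cluster as cluster_mod
from modipkit import mockgen
from modipkit.aligner import (
    AccuracyReport,
    GapScoring,
    MappingPolicy,
    assess_mapping_accuracy,
    build_index,
    map_read_gapped,
    map_read_ungapped,
)
from modipkit.cluster import ClusterConfig
from modipkit.core_io import (
    AlignmentRecord,
    MappedRead,
    MockRead,
    format_interval,
    write_alignment_sam,
    write_alignment_tab,
    write_bed,
    write_fasta,
)
from modipkit.denoise import BackgroundSet, DenoiseResult, remove_background
from modipkit.mockgen import GeneratorConfig, ReferenceGenome
from modipkit.repeat_screen import (
    CompositionSummary,
    dataset_composition,
    write_repeat_library,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Union of all stage configurations plus driver options."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    policy: MappingPolicy = field(default_factory=MappingPolicy)
    scoring: GapScoring = field(default_factory=GapScoring)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    denoise_threshold: float = 0.5
    denoise_enabled: bool = True
    gapped_only: bool = False
    one_based_reports: bool = False
    seed: int = 0
    verbose: bool = False


@dataclass
class PipelineResult:
    """In-memory handles to every stage's output, plus the artifact paths."""

    config: PipelineConfig
    ref: ReferenceGenome
    dataset: list[MockRead]           # unmodified mock reads
    modified: list[MockRead]          # after modification injection
    background: BackgroundSet
    alignments: list[AlignmentRecord]
    accuracy: AccuracyReport
    composition_mapped: CompositionSummary | None
    composition_unmapped: CompositionSummary | None
    denoise_result: DenoiseResult
    clusters: list
    count_table: object
    manifest: dict[str, object]
    out_dir: Path | None


def _log(config: PipelineConfig, stage: str, message: str) -> None:
    if config.verbose:
        print(f"[{stage}] {message}", file=sys.stderr)


def run_pipeline(config: PipelineConfig = PipelineConfig(),
                 out_dir: str | os.PathLike | None = None) -> PipelineResult:
    """Run every stage; write the artifact directory when *out_dir* is given."""
    gen = config.generator
    rng = np.random.default_rng(config.seed)

    _log(config, "mockgen", f"seed={config.seed}")
    ref = mockgen.generate_reference(gen, seed=rng)
    dataset = mockgen.build_mock_dataset(ref, gen, seed=rng)
    background = mockgen.build_background_set(dataset, ref, gen.n_background,
                                              seed=rng)
    modified = mockgen.inject_modifications(dataset, gen.n_modified, seed=rng)
    truth = {read.read_id: read for read in modified}

    _log(config, "align", f"{len(modified)} reads, mode="
         + ("gapped-only" if config.gapped_only else "ungapped+gapped-retry"))
    index = build_index(ref, config.policy.seed_len)
    alignments: list[AlignmentRecord] = []
    n_retried = 0
    for read in modified:
        if config.gapped_only:
            rec = map_read_gapped(index, read, config.policy, config.scoring)
        else:
            rec = map_read_ungapped(index, read, config.policy)
            if rec.status == "unaligned":
                n_retried += 1
                rec = map_read_gapped(index, read, config.policy, config.scoring)
        alignments.append(rec)
    accuracy = assess_mapping_accuracy(alignments, truth)

    _log(config, "screen", "repeat composition of mapped vs unmapped sets")
    library = ref.repeat_library()
    by_id = {rec.read_id: rec for rec in alignments}
    mapped_reads = [r for r in modified if by_id[r.read_id].status == "unique"]
    unmapped_reads = [r for r in modified if by_id[r.read_id].status != "unique"]
    composition_mapped = (
        dataset_composition(mapped_reads, library) if mapped_reads else None
    )
    composition_unmapped = (
        dataset_composition(unmapped_reads, library) if unmapped_reads else None
    )

    _log(config, "denoise", f"{len(mapped_reads)} mapped reads vs "
         f"{len(background)} background entries")
    mapped = [
        MappedRead(r.read_id, r.seq, by_id[r.read_id].interval,
                   by_id[r.read_id].strand)
        for r in mapped_reads
    ]
    if config.denoise_enabled:
        denoised = remove_background(mapped, background,
                                     config.denoise_threshold)
    else:
        denoised = DenoiseResult(kept=list(mapped), removed=[],
                                 threshold=config.denoise_threshold)

    _log(config, "cluster", f"{len(denoised.kept)} reads, gap="
         f"{config.cluster.gap}")
    sorted_kept = cluster_mod.sort_reads(denoised.kept)
    clusters = cluster_mod.build_clusters(sorted_kept, config.cluster)
    count_table = (
        cluster_mod.export_count_table({"modip": clusters}) if clusters else None
    )

    manifest: dict[str, object] = {
        "modipkit_version": _version(),
        "seed": config.seed,
        "n_chroms": gen.n_chroms,
        "chrom_len": gen.chrom_len,
        "n_generated": len(dataset),
        "n_modified": sum(1 for r in modified if r.modification is not None),
        "n_background": len(background),
        "n_gapped_retries": n_retried,
        "n_unique": accuracy.n_unique,
        "n_multi": accuracy.n_multi,
        "n_unaligned": accuracy.n_unaligned,
        "n_correct": accuracy.n_correct,
        "mapping_accuracy": f"{accuracy.accuracy:.4f}",
        "n_kept": len(denoised.kept),
        "n_removed": len(denoised.removed),
        "n_clusters": len(clusters),
        "cluster_member_total": sum(c.count for c in clusters),
        "denoise_threshold": config.denoise_threshold,
        "cluster_gap": config.cluster.gap,
    }

    result = PipelineResult(
        config=config, ref=ref, dataset=dataset, modified=modified,
        background=background, alignments=alignments, accuracy=accuracy,
        composition_mapped=composition_mapped,
        composition_unmapped=composition_unmapped,
        denoise_result=denoised, clusters=clusters, count_table=count_table,
        manifest=manifest, out_dir=None,
    )
    if out_dir is not None:
        result.out_dir = Path(out_dir)
        _write_artifacts(result)
    return result


def _version() -> str:
    from modipkit import __version__
    return __version__


def _write_artifacts(result: PipelineResult) -> None:
    out = result.out_dir
    assert out is not None
    out.mkdir(parents=True, exist_ok=True)
    config = result.config
    ref = result.ref

    write_fasta(ref.chroms, out / "reference.fasta")
    write_bed(
        [(iv, cls, 0) for iv, cls in ref.repeat_annotations],
        out / "repeats.bed",
    )
    write_bed(
        [(iv, f"dup_pair_{i + 1}", 0)
         for i, pair in enumerate(ref.duplicated_loci) for iv in pair],
        out / "duplicated_loci.bed",
    )
    write_repeat_library(ref.repeat_library(), out / "repeat_library.fasta")

    write_fasta([(r.read_id, r.seq) for r in result.modified],
                out / "reads.fasta")
    # truth BED: score 1 flags an indel-modified read (start tolerance +/-5)
    write_bed(
        [(r.origin, r.read_id,
          int(r.modification is not None and r.modification.is_indel))
         for r in result.modified],
        out / "truth.bed",
    )
    write_fasta([(e.read_id, e.seq) for e in result.background],
                out / "background.fasta")
    write_bed([(e.interval, e.read_id, 0) for e in result.background],
              out / "background.bed")

    seqs = {r.read_id: r.seq for r in result.modified}
    write_alignment_tab(result.alignments, seqs, out / "alignments.tab")
    write_alignment_sam(
        result.alignments, seqs,
        {name: len(seq) for name, seq in ref.chroms.items()},
        out / "alignments.sam",
    )

    write_bed([(r.interval, r.read_id, 0) for r in result.denoise_result.kept],
              out / "kept.bed")
    write_bed(
        [(r.interval, f"{r.read_id}|{reason}", 0)
         for r, reason in result.denoise_result.removed],
        out / "removed.bed",
    )
    cluster_mod.write_cluster_outputs(
        result.clusters, out / "clusters_members.bed", out / "clusters_counts.bed"
    )
    if result.count_table is not None:
        cluster_mod.write_count_table(result.count_table, out / "counts.tsv")

    with open(out / "manifest.txt", "w") as fh:
        for key, value in result.manifest.items():
            fh.write(f"{key}={value}\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(_render_report(result))


def _render_report(result: PipelineResult) -> str:
    """Human-readable run summary (optionally 1-based inclusive coordinates)."""
    one_based = result.config.one_based_reports
    acc = result.accuracy
    lines = [
        "modipkit run report",
        f"seed: {result.config.seed}",
        f"coordinates: {'1-based inclusive' if one_based else '0-based half-open'}",
        "",
        f"reads generated: {len(result.dataset)}"
        f" (modified: {result.manifest['n_modified']},"
        f" background entries: {len(result.background)})",
        f"mapping: unique={acc.n_unique} multi={acc.n_multi}"
        f" unaligned={acc.n_unaligned} correct={acc.n_correct}"
        f" accuracy={acc.accuracy:.3f}",
    ]
    for label, comp in (("mapped", result.composition_mapped),
                        ("unmapped", result.composition_unmapped)):
        if comp is not None:
            lines.append(
                f"composition ({label}): unique {comp.unique_fraction:.1%}, "
                f"repetitive {comp.repetitive_fraction:.1%} "
                f"over {comp.total_bases} bases"
            )
    lines.append(
        f"denoise: kept={len(result.denoise_result.kept)} "
        f"removed={len(result.denoise_result.removed)} "
        f"(threshold >{result.denoise_result.threshold:.0%} overlap)"
    )
    lines.append(f"clusters: {len(result.clusters)}")
    for i, c in enumerate(result.clusters):
        lines.append(
            f"  cluster_{i + 1} {format_interval(c.interval, one_based)} "
            f"count={c.count}"
        )
    return "\n".join(lines) + "\n"
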