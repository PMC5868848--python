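"""Synthetic reference genome and mock MoDIP-seq dataset generator.

Generates the canonical validation dataset used to exercise the pipeline before real
sequencing data exist: 25-bp reads tiled across two 200-bp source regions
separated by 100 bp (consecutive reads overlapping by 5 bp), topped up with
reads dispersed across several chromosomes; a modified variant set carrying
single-base substitutions and 5-nt insertions/deletions; and a 25-sequence
negative-control background set that matches or overlaps the unmodified reads.

The reference is i.i.d. uniform sequence with *planted* structure recorded as
truth: repeat elements of three classes (SINE-like, LINE-like,
microsatellite-like, in tandem and dispersed copies), at least one exactly
duplicated locus pair, and the two designated tiled regions.  Base composition
(GC content) of real genomes is deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from modipkit.core_io import (
    ConfigError,
    GenomicInterval,
    MockRead,
    Modification,
)
from modipkit.denoise import BackgroundEntry, BackgroundSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")

REPEAT_CLASSES = ("SINE-like", "LINE-like", "microsatellite-like")

# planted element lengths per class (bp); microsatellites are a short motif
# tandemly repeated to this length, so every copy is internally tandem
_ELEMENT_LEN = {"SINE-like": 150, "LINE-like": 400, "microsatellite-like": 60}
_MICROSAT_MOTIF_LEN = 3


def _rng(seed) -> np.random.Generator:
    """Accepts an int seed or an existing Generator (threaded through stages)."""
    return np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the mock-data generator; defaults are the stated dataset.

    n_total:        total reads in the mock dataset (100)
    read_len:       unmodified read length, bp (25)
    overlap:        overlap between consecutive tiled reads, bp (5)
    region_len:     length of each tiled source region, bp (200)
    region_separation: gap between the two tiled regions, bp (100)
    n_modified:     reads receiving an injected modification (75)
    n_background:   negative-control sequences (25)
    n_chroms:       chromosomes in the synthetic reference (3, mirroring the
                    intended chr1/chr2/chrX sampling at desk scale)
    chrom_len:      length of each chromosome, bp (10 kb — desk scale)
    repeat_copies:  planted copies per repeat class (3)
    n_duplicated_pairs: exactly-duplicated locus pairs (1)
    n_tiled:        override for the number of tiled reads taken (None = all)
    """

    n_total: int = 100
    read_len: int = 25
    overlap: int = 5
    region_len: int = 200
    region_separation: int = 100
    n_modified: int = 75
    n_background: int = 25
    n_chroms: int = 3
    chrom_len: int = 10_000
    repeat_copies: int = 3
    n_duplicated_pairs: int = 1
    n_tiled: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.read_len):
            raise ConfigError("require 0 <= overlap < read_len")
        if self.n_modified > self.n_total:
            raise ConfigError("n_modified cannot exceed n_total")
        for name in ("n_total", "n_modified", "n_background", "n_chroms",
                     "repeat_copies", "n_duplicated_pairs"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_chroms < 1:
            raise ConfigError("need at least one chromosome")
        if self.chrom_len < 2 * (self.region_len + self.region_separation):
            raise ConfigError(
                "chromosome too short for the two tiled regions: need at least "
                f"{2 * (self.region_len + self.region_separation)} bp"
            )


@dataclass
class ReferenceGenome:
    """Synthetic reference with planted-truth annotations."""

    chroms: dict[str, str]
    repeat_annotations: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    duplicated_loci: list[tuple[GenomicInterval, GenomicInterval]] = field(default_factory=list)
    tiled_regions: list[GenomicInterval] = field(default_factory=list)

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval; bounds-checked."""
        seq = self.chroms.get(interval.chrom)
        if seq is None:
            raise ConfigError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > len(seq):
            raise ConfigError(f"interval {interval} exceeds chromosome bounds")
        return seq[interval.start:interval.end]

    def repeat_library(self) -> dict[str, list[str]]:
        """Repeat library (class -> distinct element sequences) derived from
        the planted annotations — the masking stand-in's reference library."""
        lib: dict[str, list[str]] = {}
        for interval, cls in self.repeat_annotations:
            seq = self.fetch(interval)
            lib.setdefault(cls, [])
            if seq not in lib[cls]:
                lib[cls].append(seq)
        return lib

    def annotated_intervals(self) -> list[GenomicInterval]:
        """All truth intervals a 'unique, non-repetitive' read must avoid."""
        out = [iv for iv, _ in self.repeat_annotations]
        for a, b in self.duplicated_loci:
            out.extend((a, b))
        return out


def _chrom_names(n: int) -> list[str]:
    names = [f"chr{i + 1}" for i in range(n)]
    if n >= 3:
        names[-1] = "chrX"
    return names


def _place(rng: np.random.Generator, occupied: dict[str, list[tuple[int, int]]],
           chrom_len: int, length: int, chrom: str,
           max_tries: int = 200) -> int:
    """Uniformly sample a start for a non-overlapping planting on *chrom*."""
    spans = occupied[chrom]
    for _ in range(max_tries):
        start = int(rng.integers(0, chrom_len - length + 1))
        end = start + length
        if all(end <= s or e <= start for s, e in spans):
            spans.append((start, end))
            return start
    raise ConfigError(
        f"chromosome {chrom} too short/crowded to plant a {length}-bp element"
    )


def generate_reference(config: GeneratorConfig, seed=None) -> ReferenceGenome:
    """Build the synthetic reference genome with planted truth.

    The two tiled regions sit on the first chromosome, separated by exactly
    ``region_separation`` bp; repeat elements and the duplicated locus pair are
    planted clear of them (and of each other) so tiled reads map uniquely.
    """
    rng = _rng(config.seed if seed is None else seed)
    names = _chrom_names(config.n_chroms)
    arrays = {
        name: rng.choice(_BASES, size=config.chrom_len) for name in names
    }
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}

    # tiled regions: planted on the first chromosome, gap exactly region_separation
    block = 2 * config.region_len + config.region_separation
    first = names[0]
    lo = config.chrom_len // 10
    hi = config.chrom_len - block - lo
    block_start = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
    region_a = GenomicInterval(first, block_start, block_start + config.region_len)
    b_start = region_a.end + config.region_separation
    region_b = GenomicInterval(first, b_start, b_start + config.region_len)
    occupied[first].append((region_a.start, region_b.end))
    tiled_regions = [region_a, region_b]

    # repeat elements: one element sequence per class, repeat_copies plantings
    repeat_annotations: list[tuple[GenomicInterval, str]] = []
    if config.repeat_copies > 0:
        for cls in REPEAT_CLASSES:
            if cls == "microsatellite-like":
                motif = _random_seq(rng, _MICROSAT_MOTIF_LEN)
                reps = _ELEMENT_LEN[cls] // _MICROSAT_MOTIF_LEN
                element = motif * reps
            else:
                element = _random_seq(rng, _ELEMENT_LEN[cls])
            for _ in range(config.repeat_copies):
                chrom = names[int(rng.integers(0, len(names)))]
                start = _place(rng, occupied, config.chrom_len, len(element), chrom)
                arrays[chrom][start:start + len(element)] = np.frombuffer(
                    element.encode(), dtype="S1"
                )
                repeat_annotations.append(
                    (GenomicInterval(chrom, start, start + len(element)), cls)
                )

    # exactly duplicated locus pairs
    duplicated_loci: list[tuple[GenomicInterval, GenomicInterval]] = []
    dup_len = config.region_len
    for _ in range(config.n_duplicated_pairs):
        chrom_a = names[int(rng.integers(0, len(names)))]
        start_a = _place(rng, occupied, config.chrom_len, dup_len, chrom_a)
        chrom_b = names[int(rng.integers(0, len(names)))]
        start_b = _place(rng, occupied, config.chrom_len, dup_len, chrom_b)
        arrays[chrom_b][start_b:start_b + dup_len] = arrays[chrom_a][
            start_a:start_a + dup_len
        ]
        duplicated_loci.append(
            (
                GenomicInterval(chrom_a, start_a, start_a + dup_len),
                GenomicInterval(chrom_b, start_b, start_b + dup_len),
            )
        )

    chroms = {name: arr.tobytes().decode() for name, arr in arrays.items()}
    return ReferenceGenome(
        chroms=chroms,
        repeat_annotations=repeat_annotations,
        duplicated_loci=duplicated_loci,
        tiled_regions=tiled_regions,
    )


def extract_tiled_reads(ref: ReferenceGenome, region: GenomicInterval,
                        read_len: int, overlap: int,
                        id_prefix: str = "tile") -> list[MockRead]:
    """Tile a region with reads stepping by (read_len - overlap).

    Reads start at ``region.start`` and are emitted while they fit entirely
    inside the region, so consecutive reads share exactly ``overlap`` bases.
    """
    if not (0 <= overlap < read_len):
        raise ConfigError("require 0 <= overlap < read_len")
    if read_len > len(region):
        raise ConfigError("read_len exceeds region length")
    chrom_seq = ref.chroms.get(region.chrom)
    if chrom_seq is None or region.end > len(chrom_seq):
        raise ConfigError(f"region {region} outside chromosome bounds")
    step = read_len - overlap
    reads = []
    for i, start in enumerate(range(region.start, region.end - read_len + 1, step)):
        iv = GenomicInterval(region.chrom, start, start + read_len)
        reads.append(MockRead(f"{id_prefix}_{i:02d}", ref.fetch(iv), iv))
    return reads


def sample_dispersed_reads(ref: ReferenceGenome, n: int, read_len: int,
                           seed=None, id_prefix: str = "disp") -> list[MockRead]:
    """Sample n reads at uniform positions across all chromosomes, excluding
    placements that overlap a tiled region.  Deterministic under a fixed seed.
    """
    rng = _rng(seed)
    names = list(ref.chroms)
    lengths = np.array([len(ref.chroms[c]) for c in names], dtype=float)
    weights = lengths / lengths.sum()
    reads: list[MockRead] = []
    while len(reads) < n:
        ci = int(rng.choice(len(names), p=weights))
        chrom = names[ci]
        start = int(rng.integers(0, len(ref.chroms[chrom]) - read_len + 1))
        iv = GenomicInterval(chrom, start, start + read_len)
        if any(iv.overlap(region) > 0 for region in ref.tiled_regions):
            continue
        reads.append(MockRead(f"{id_prefix}_{len(reads):03d}", ref.fetch(iv), iv))
    return reads


def build_mock_dataset(ref: ReferenceGenome, config: GeneratorConfig,
                       seed=None) -> list[MockRead]:
    """Assemble the full mock dataset: tiled reads from both source regions,
    filled to ``n_total`` with dispersed reads.  Read ids are unique."""
    tiled: list[MockRead] = []
    for ri, region in enumerate(ref.tiled_regions):
        tiled.extend(
            extract_tiled_reads(
                ref, region, config.read_len, config.overlap,
                id_prefix=f"tile{ri + 1}",
            )
        )
    if config.n_tiled is not None:
        if config.n_tiled > len(tiled):
            raise ConfigError(
                f"n_tiled={config.n_tiled} exceeds the {len(tiled)} reads the "
                "tiled regions yield"
            )
        tiled = tiled[:config.n_tiled]
    if len(tiled) > config.n_total:
        raise ConfigError(
            f"tiled reads ({len(tiled)}) exceed n_total ({config.n_total})"
        )
    dispersed = sample_dispersed_reads(
        ref, config.n_total - len(tiled), config.read_len, seed=seed
    )
    return tiled + dispersed


_MOD_MODES = ("substitution", "insertion", "deletion")
_INDEL_LEN = 5


def inject_modifications(dataset: list[MockRead], n_modified: int,
                         seed=None) -> list[MockRead]:
    """Inject modifications into a random subset of ``n_modified`` reads.

    Modes are assigned round-robin (substitution, insertion, deletion) over the
    selected reads in dataset order.  A substitution replaces one base with a
    different base (length unchanged); an insertion adds 5 random bases at
    floor(len/2); a deletion removes 5 bases centered at floor(len/2).
    Unselected reads are returned untouched.
    """
    if n_modified > len(dataset):
        raise ConfigError("n_modified exceeds dataset size")
    rng = _rng(seed)
    chosen = sorted(rng.choice(len(dataset), size=n_modified, replace=False).tolist())
    out = list(dataset)
    for mode_i, idx in enumerate(chosen):
        read = dataset[idx]
        mode = _MOD_MODES[mode_i % len(_MOD_MODES)]
        seq = read.seq
        mid = len(seq) // 2
        if mode == "substitution":
            pos = int(rng.integers(0, len(seq)))
            alternatives = [b for b in "ACGT" if b != seq[pos]]
            new_base = alternatives[int(rng.integers(0, len(alternatives)))]
            new_seq = seq[:pos] + new_base + seq[pos + 1:]
            mod = Modification("substitution", pos, bases=new_base)
        elif mode == "insertion":
            bases = _random_seq(rng, _INDEL_LEN)
            new_seq = seq[:mid] + bases + seq[mid:]
            mod = Modification("insertion", mid, bases=bases)
        else:
            start = mid - _INDEL_LEN // 2
            if start < 0 or start + _INDEL_LEN > len(seq):
                raise ConfigError(
                    f"read {read.read_id} too short to delete {_INDEL_LEN} nt"
                )
            new_seq = seq[:start] + seq[start + _INDEL_LEN:]
            mod = Modification("deletion", start, length=_INDEL_LEN)
        out[idx] = replace(read, seq=new_seq, modification=mod)
    return out


def build_background_set(dataset: list[MockRead], ref: ReferenceGenome,
                         n_background: int, seed=None) -> BackgroundSet:
    """Build the negative-control background set from the *unmodified* dataset.

    Each entry is either an exact copy of a sampled mock read (same sequence
    and coordinates) or a reference extract shifted so that it still overlaps
    the sampled read by more than half the read length.  Provenance recorded.
    """
    if n_background > len(dataset):
        raise ConfigError("n_background exceeds dataset size")
    rng = _rng(seed)
    chosen = rng.choice(len(dataset), size=n_background, replace=False).tolist()
    entries: list[BackgroundEntry] = []
    for i, idx in enumerate(chosen):
        read = dataset[idx]
        read_len = len(read.origin)
        exact = bool(rng.integers(0, 2))
        if exact:
            entries.append(
                BackgroundEntry(f"bg_{i:02d}", read.seq, read.origin, "exact")
            )
            continue
        # shift by < read_len/2 so overlap stays > half the read length
        max_shift = (read_len - 1) // 2
        delta = int(rng.integers(1, max_shift + 1)) if max_shift >= 1 else 0
        if rng.integers(0, 2):
            delta = -delta
        chrom_len = len(ref.chroms[read.origin.chrom])
        start = min(max(read.origin.start + delta, 0), chrom_len - read_len)
        iv = GenomicInterval(read.origin.chrom, start, start + read_len)
        entries.append(BackgroundEntry(f"bg_{i:02d}", ref.fetch(iv), iv, "shifted"))
    return BackgroundSet(entries=entries)
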