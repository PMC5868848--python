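"""Lightweight repeat screen: a masking stand-in for library-based maskers.

Real pipelines hand this step to RepeatMasker with a curated repeat library;
here the library is the set of planted element sequences and matching is exact
substring matching (no divergence model), which is enough to recover the
planted repeat composition of the synthetic data.  A read base is masked when
it lies inside a substring of length >= ``min_match`` that occurs in any
library element, in either orientation.  A read is *repeat-dominated* when
strictly more than ``threshold_bases`` (default 20) of its bases are masked —
such reads are too generic to map to a single genomic location.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from modipkit.core_io import DataError, FormatError, MockRead, revcomp

DEFAULT_MIN_MATCH = 11
DEFAULT_THRESHOLD_BASES = 20

UNIQUE_DOMINATED = "unique-dominated"
REPEAT_DOMINATED = "repeat-dominated"


@dataclass
class MaskResult:
    """Masking outcome for one read."""

    read_id: str
    masked_bases: int
    masked_intervals: list[tuple[int, int]]  # within-read, half-open, disjoint
    classes_hit: set[str] = field(default_factory=set)
    class_bases: dict[str, int] = field(default_factory=dict)


def _union(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of within-read intervals as sorted disjoint intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _total(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def _kmer_classes(library: Mapping[str, Sequence[str] | str],
                  k: int) -> dict[str, set[str]]:
    """k-mer -> set of repeat classes containing it (both orientations).

    Exactness note: a substring match of length L >= k masks exactly the union
    of its k-mer windows, so masking every matching k-mer window reproduces
    maximal-substring masking.
    """
    table: dict[str, set[str]] = {}
    for cls, seqs in library.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        for seq in seqs:
            for oriented in (seq, revcomp(seq)):
                for pos in range(len(oriented) - k + 1):
                    table.setdefault(oriented[pos:pos + k], set()).add(cls)
    return table


def mask_repeats(seq: str, library: Mapping[str, Sequence[str] | str],
                 min_match: int = DEFAULT_MIN_MATCH,
                 read_id: str = "",
                 _table: dict[str, set[str]] | None = None) -> MaskResult:
    """Mask every base of *seq* inside a >= min_match exact library match.

    Overlapping matches are unioned; an empty library masks nothing.
    """
    if min_match < 1:
        raise DataError("min_match must be >= 1")
    table = _table if _table is not None else _kmer_classes(library, min_match)
    per_class: dict[str, list[tuple[int, int]]] = {}
    hits: list[tuple[int, int]] = []
    for pos in range(len(seq) - min_match + 1):
        classes = table.get(seq[pos:pos + min_match])
        if not classes:
            continue
        hits.append((pos, pos + min_match))
        for cls in classes:
            per_class.setdefault(cls, []).append((pos, pos + min_match))
    masked = _union(hits)
    return MaskResult(
        read_id=read_id,
        masked_bases=_total(masked),
        masked_intervals=masked,
        classes_hit=set(per_class),
        class_bases={cls: _total(_union(ivs)) for cls, ivs in per_class.items()},
    )


def classify_composition(mask: MaskResult, read_len: int,
                         threshold_bases: int = DEFAULT_THRESHOLD_BASES) -> str:
    """Repeat-dominated iff strictly more than *threshold_bases* are masked."""
    if mask.masked_bases > read_len:
        raise DataError("masked_bases exceeds read length")
    return REPEAT_DOMINATED if mask.masked_bases > threshold_bases else UNIQUE_DOMINATED


@dataclass
class CompositionSummary:
    """Dataset-level base composition: repetitive vs uniquely identifiable."""

    n_reads: int
    total_bases: int
    masked_bases: int
    class_bases: dict[str, int]
    masks: list[MaskResult]

    @property
    def repetitive_fraction(self) -> float:
        return self.masked_bases / self.total_bases

    @property
    def unique_fraction(self) -> float:
        return 1.0 - self.repetitive_fraction


def write_repeat_library(library: Mapping[str, Sequence[str]],
                         path: str | os.PathLike) -> None:
    """Write a repeat library as FASTA with the class in a ``class:`` token."""
    records = []
    for cls, seqs in library.items():
        slug = cls.replace(" ", "_")
        for i, seq in enumerate(seqs):
            records.append((f"{slug}_{i + 1} class:{cls}", seq))
    # headers carry a space-separated token, so they are written directly
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j:j + 60] + "\n")


def read_repeat_library(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a repeat-library FASTA; each header must carry a ``class:`` token."""
    library: dict[str, list[str]] = {}
    cls: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if cls is not None:
            library.setdefault(cls, []).append("".join(chunks))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                tokens = [t for t in line[1:].split() if t.startswith("class:")]
                if not tokens:
                    raise FormatError(
                        f"{path}:{lineno}: library header lacks a class: token"
                    )
                cls = tokens[0].removeprefix("class:")
                chunks = []
            else:
                if cls is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence before any header"
                    )
                chunks.append(line.upper())
        flush()
    return library


def dataset_composition(reads: Sequence[MockRead] | Sequence[tuple[str, str]],
                        library: Mapping[str, Sequence[str] | str],
                        min_match: int = DEFAULT_MIN_MATCH) -> CompositionSummary:
    """Summarise masked vs unmasked base fractions over a read set."""
    if not reads:
        raise DataError("cannot summarise composition of an empty read set")
    table = _kmer_classes(library, min_match)
    masks: list[MaskResult] = []
    total = masked = 0
    class_bases: dict[str, int] = {}
    for read in reads:
        if isinstance(read, MockRead):
            rid, seq = read.read_id, read.seq
        else:
            rid, seq = read
        result = mask_repeats(seq, library, min_match, read_id=rid, _table=table)
        masks.append(result)
        total += len(seq)
        masked += result.masked_bases
        for cls, n in result.class_bases.items():
            class_bases[cls] = class_bases.get(cls, 0) + n
    return CompositionSummary(
        n_reads=len(masks),
        total_bases=total,
        masked_bases=masked,
        class_bases=class_bases,
        masks=masks,
    )
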