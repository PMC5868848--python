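"""Negative-control background subtraction.

A no-antibody immunoprecipitation recovers fragments that stick to the beads
regardless of the 8OHdG antibody; reads traced to it define experimental
background noise.  A mapped antibody-positive read is discarded when it

1. is *identical* to a background entry (same sequence AND same coordinates),
2. is *contained* — its interval lies entirely within a background interval, or
3. *overlaps* a background entry by strictly more than the threshold fraction
   (default 0.5) of the read's own length.

Rules are evaluated in that order and the first match is recorded as the
removal reason.  Coordinates alone drive rules 2-3; sequence identity matters
only for rule 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from modipkit.core_io import DataError, GenomicInterval, MappedRead

DEFAULT_OVERLAP_THRESHOLD = 0.5

REASON_IDENTICAL = "identical"
REASON_CONTAINED = "contained"
REASON_OVERLAP = "overlap"


@dataclass(frozen=True)
class BackgroundEntry:
    """One negative-control sequence with its genomic coordinates."""

    read_id: str
    seq: str
    interval: GenomicInterval
    provenance: str = ""  # how the entry was derived (e.g. exact / shifted)


@dataclass
class BackgroundSet:
    """The set of negative-control reads used for subtraction."""

    entries: list[BackgroundEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[BackgroundEntry]:
        return iter(self.entries)


@dataclass
class DenoiseResult:
    """Partition of the input reads into kept and removed (with reasons)."""

    kept: list[MappedRead]
    removed: list[tuple[MappedRead, str]]
    threshold: float


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of *a*'s bases shared with *b* (query-length denominator).

    Different chromosomes give 0.  The denominator is the query interval *a*
    because the rule is applied per candidate read.
    """
    return a.overlap(b) / len(a)


def _removal_reason(read: MappedRead,
                    background: Sequence[BackgroundEntry],
                    threshold: float) -> str | None:
    for entry in background:
        if entry.seq == read.seq and entry.interval == read.interval:
            return REASON_IDENTICAL
    for entry in background:
        if entry.interval.contains(read.interval):
            return REASON_CONTAINED
    for entry in background:
        if overlap_fraction(read.interval, entry.interval) > threshold:
            return REASON_OVERLAP
    return None


def remove_background(reads: Iterable[MappedRead],
                      background: BackgroundSet | Sequence[BackgroundEntry],
                      threshold: float = DEFAULT_OVERLAP_THRESHOLD) -> DenoiseResult:
    """Partition mapped reads into kept / removed against the background set.

    Every read must carry a mapped interval; a read without one raises
    :class:`DataError` naming it.  The partition is exact: kept + removed
    reproduce the input, each read appearing exactly once.
    """
    entries = list(background)
    kept: list[MappedRead] = []
    removed: list[tuple[MappedRead, str]] = []
    for read in reads:
        if getattr(read, "interval", None) is None:
            raise DataError(f"read {read.read_id} has no mapped interval")
        reason = _removal_reason(read, entries, threshold)
        if reason is None:
            kept.append(read)
        else:
            removed.append((read, reason))
    return DenoiseResult(kept=kept, removed=removed, threshold=threshold)
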