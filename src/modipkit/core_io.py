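"""Core data model and file I/O: FASTA, BED5 and alignment-record dialects.

Coordinate convention: 0-based half-open intervals everywhere internally and in
BED output (BED's native convention).  Human-readable reports may optionally be
rendered 1-based inclusive at the reporting layer, never in data files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class PipelineError(Exception):
    """Base class for all modipkit errors."""


class FormatError(PipelineError):
    """A file does not conform to its declared format."""


class ValidationError(PipelineError):
    """An in-memory record violates an invariant."""


class ConfigError(PipelineError):
    """A configuration is internally inconsistent or infeasible."""


class DataError(PipelineError):
    """Inputs are structurally valid but mutually inconsistent."""


class UsageError(PipelineError):
    """An operation was invoked with an unsupported option or precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with *other* (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Modification:
    """Record of an injected read modification.

    kind is one of ``substitution`` (one base replaced, length unchanged),
    ``insertion`` (bases added at *position*) or ``deletion`` (*length* bases
    removed starting at *position*).  Positions are 0-based offsets into the
    original, unmodified read.
    """

    kind: str
    position: int
    bases: str = ""
    length: int = 0

    _KINDS = ("substitution", "insertion", "deletion")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown modification kind {self.kind!r}")

    @property
    def is_indel(self) -> bool:
        return self.kind in ("insertion", "deletion")


@dataclass(frozen=True)
class MockRead:
    """A simulated read with its true genomic origin.

    ``origin`` always spans the unmodified read's footprint on the reference;
    ``modification`` is ``None`` for pristine reads.
    """

    read_id: str
    seq: str
    origin: GenomicInterval
    modification: Modification | None = None

    def __post_init__(self) -> None:
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise ValidationError(
                f"read {self.read_id}: non-nucleotide characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class AlignmentRecord:
    """Outcome of mapping one read.

    ``interval`` is present exactly when ``status == "unique"``; ``mismatches``
    (and ``score`` for gapped alignments) are defined only then.
    """

    read_id: str
    status: str  # unique | multi | unaligned
    interval: GenomicInterval | None = None
    strand: str = "+"
    mismatches: int = 0
    score: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("unique", "multi", "unaligned"):
            raise ValidationError(f"unknown alignment status {self.status!r}")
        if (self.interval is not None) != (self.status == "unique"):
            raise ValidationError(
                f"read {self.read_id}: interval present iff status is unique"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if self.mismatches < 0:
            raise ValidationError("mismatch count must be non-negative")


@dataclass(frozen=True)
class MappedRead:
    """A read that survived alignment, carrying its mapped coordinates.

    This is the unit consumed by background subtraction and clustering.
    """

    read_id: str
    seq: str
    interval: GenomicInterval
    strand: str = "+"


@dataclass
class Cluster:
    """A merged run of mapped reads: a candidate oxidation region."""

    interval: GenomicInterval
    members: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (multi-record) FASTA file into an ordered name -> sequence map.

    Sequences are uppercased; record names are taken up to the first
    whitespace.  Raises :class:`FormatError` naming the offending line for a
    malformed header or non-nucleotide sequence characters.
    """
    records: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is not None:
            records[name] = "".join(chunks)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                flush()
                name = header.split()[0]
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                seq = line.upper()
                bad = set(seq) - NUCLEOTIDES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: non-nucleotide characters {sorted(bad)}"
                    )
                chunks.append(seq)
        flush()
    return records


def write_fasta(records: Iterable[tuple[str, str]] | dict[str, str],
                path: str | os.PathLike) -> None:
    """Write (name, sequence) pairs as FASTA (via Biopython)."""
    if isinstance(records, dict):
        records = records.items()
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


# ---------------------------------------------------------------------------
# BED5
# ---------------------------------------------------------------------------


def write_bed(records: Iterable[tuple[GenomicInterval, str, int | float]],
              path: str | os.PathLike) -> None:
    """Write BED5 lines (chrom, start, end, name, score), in the given order."""
    with open(path, "w") as fh:
        for interval, name, score in records:
            if not isinstance(interval, GenomicInterval):
                raise ValidationError(f"not a GenomicInterval: {interval!r}")
            fh.write(
                f"{interval.chrom}\t{interval.start}\t{interval.end}"
                f"\t{name}\t{score}\n"
            )


def read_bed(path: str | os.PathLike) -> list[tuple[GenomicInterval, str, float]]:
    """Parse a BED file with at least 3 columns; name/score default to ''/0."""
    out: list[tuple[GenomicInterval, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            name = cols[3] if len(cols) > 3 else ""
            score = float(cols[4]) if len(cols) > 4 else 0.0
            out.append((iv, name, score))
    return out


# ---------------------------------------------------------------------------
# alignment-record dialects
# ---------------------------------------------------------------------------

TAB_DIALECT = "tab"
SAM_DIALECT = "sam"

_SAM_FLAG_UNMAPPED = 0x4
_SAM_FLAG_REVERSE = 0x10


def parse_alignment_output(path: str | os.PathLike,
                           dialect: str = TAB_DIALECT) -> list[AlignmentRecord]:
    """Parse external aligner output into :class:`AlignmentRecord` objects.

    Two dialects are supported:

    ``tab``
        One aligned read per line:
        ``read_id TAB strand TAB chrom TAB 0-based-offset TAB sequence TAB
        mismatch-count``.  Trailing extra columns are ignored.
    ``sam``
        A minimal SAM subset: ``@``-header lines are skipped; columns 1-6 and
        10 are honored; of the FLAG field only bits 0x4 (unmapped) and 0x10
        (reverse strand) are interpreted.  SAM POS is 1-based and converted.
    """
    if dialect == TAB_DIALECT:
        return _parse_tab(path)
    if dialect == SAM_DIALECT:
        return _parse_sam_subset(path)
    raise UsageError(f"unknown alignment dialect {dialect!r}")


def _parse_tab(path: str | os.PathLike) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(
                    f"{path}:{lineno}: tab dialect requires >= 6 columns"
                )
            read_id, strand, chrom, offset, seq, mism = cols[:6]
            try:
                start = int(offset)
                n_mm = int(mism)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(
                AlignmentRecord(
                    read_id=read_id,
                    status="unique",
                    interval=GenomicInterval(chrom, start, start + len(seq)),
                    strand=strand,
                    mismatches=n_mm,
                )
            )
    return out


def _parse_sam_subset(path: str | os.PathLike) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(
                    f"{path}:{lineno}: SAM subset requires >= 10 columns"
                )
            qname, flag_s, rname, pos_s = cols[0], cols[1], cols[2], cols[3]
            seq = cols[9]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if flag & _SAM_FLAG_UNMAPPED or rname == "*":
                out.append(AlignmentRecord(read_id=qname, status="unaligned"))
                continue
            strand = "-" if flag & _SAM_FLAG_REVERSE else "+"
            start = pos - 1  # SAM POS is 1-based
            out.append(
                AlignmentRecord(
                    read_id=qname,
                    status="unique",
                    interval=GenomicInterval(rname, start, start + len(seq)),
                    strand=strand,
                )
            )
    return out


def write_alignment_tab(alignments: Iterable[AlignmentRecord],
                        seqs: dict[str, str],
                        path: str | os.PathLike) -> None:
    """Write uniquely aligned records in the tab dialect (round-trips through
    :func:`parse_alignment_output`).  Multi/unaligned records are omitted, as
    in the aligner output this dialect models."""
    with open(path, "w") as fh:
        for rec in alignments:
            if rec.status != "unique":
                continue
            assert rec.interval is not None
            fh.write(
                f"{rec.read_id}\t{rec.strand}\t{rec.interval.chrom}"
                f"\t{rec.interval.start}\t{seqs[rec.read_id]}\t{rec.mismatches}\n"
            )


def write_alignment_sam(alignments: Iterable[AlignmentRecord],
                        seqs: dict[str, str],
                        chrom_lengths: dict[str, int],
                        path: str | os.PathLike) -> None:
    """Write all records as a minimal SAM file (flag 4 for multi/unaligned)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in alignments:
            seq = seqs.get(rec.read_id, "*")
            if rec.status != "unique":
                fh.write(f"{rec.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            assert rec.interval is not None
            flag = _SAM_FLAG_REVERSE if rec.strand == "-" else 0
            cigar = f"{len(seq)}M" if len(seq) == len(rec.interval) else "*"
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.interval.chrom}"
                f"\t{rec.interval.start + 1}\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )


def format_interval(interval: GenomicInterval, one_based: bool = False) -> str:
    """Render an interval for reports; optionally 1-based inclusive."""
    if one_based:
        return f"{interval.chrom}:{interval.start + 1}-{interval.end}"
    return f"{interval.chrom}:[{interval.start},{interval.end})"


def iter_intervals(records: Iterable) -> Iterator[GenomicInterval]:
    for rec in records:
        yield rec.interval
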