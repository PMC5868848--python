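"""Read mapping against the synthetic reference, in two regimes.

The *ungapped* regime models a backtracking short-read aligner run in seeded
mode: candidate loci come from exact k-mer seed hits, each candidate is scored
by Hamming mismatches over the full read, candidates violating the
seed-mismatch cap (at most 1 mismatch in the first 5 bases of the read, the
``-n 1 -l 5`` semantics) or the total-mismatch cap are discarded, and with
best-mode the minimum-mismatch candidate wins.  Two or more equally good loci
yield status ``multi``; no surviving locus yields ``unaligned``.

The *gapped* regime models a local/affine aligner able to place reads carrying
5-nt insertions or deletions: candidate windows around seed-hit diagonals are
aligned by a fitting (read-global, window-local) Gotoh dynamic program with
affine gap penalties; the best-scoring placement wins, ties give ``multi`` and
a score below the acceptance threshold gives ``unaligned``.

Neither regime aspires to genome-scale performance; both are exact at the
desk scale they are used at (see the completeness notes in docs/methods.md).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from modipkit.core_io import (
    AlignmentRecord,
    ConfigError,
    DataError,
    GenomicInterval,
    MockRead,
    ValidationError,
    revcomp,
)
from modipkit.mockgen import ReferenceGenome

_INDEL_LEN = 5
_INDEL_START_TOLERANCE = 5  # an indel can legitimately shift the optimal start


@dataclass(frozen=True)
class MappingPolicy:
    """Mismatch policy of the ungapped regime (seeded -n/-l/-best semantics)."""

    seed_len: int = 5
    max_seed_mismatches: int = 1
    max_total_mismatches: int = 2
    best_mode: bool = True
    mode: str = "ungapped"

    def __post_init__(self) -> None:
        if self.seed_len < 1:
            raise ConfigError("seed_len must be >= 1")
        if self.max_seed_mismatches < 0 or self.max_total_mismatches < 0:
            raise ConfigError("mismatch caps must be non-negative")
        if self.mode not in ("ungapped", "gapped"):
            raise ConfigError(f"unknown mapping mode {self.mode!r}")


@dataclass(frozen=True)
class GapScoring:
    """Affine scoring for the gapped regime.

    A gap of length g scores ``gap_open + (g - 1) * gap_extend`` (the first
    gap base pays the open penalty).  ``band`` is the candidate-window margin
    on each side of the seed diagonal and must cover the largest expected
    indel.  An alignment is accepted when its score reaches
    ``min_score_frac * match * read_len``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -6
    gap_extend: int = -1
    band: int = 8
    min_score_frac: float = 0.6

    def min_score(self, read_len: int) -> float:
        return self.min_score_frac * self.match * read_len


class SeedIndex:
    """Exact k-mer index over every chromosome, both orientations.

    Forward occurrences are stored; reverse-strand occurrences of a k-mer are
    resolved as forward occurrences of its reverse complement, so both
    orientations are queryable without duplicating the table.
    """

    def __init__(self, chroms: dict[str, str], k: int):
        self.k = k
        self.chroms = chroms
        self.encoded = {
            name: np.frombuffer(seq.encode(), dtype=np.uint8)
            for name, seq in chroms.items()
        }
        table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in chroms.items():
            for pos in range(len(seq) - k + 1):
                table[seq[pos:pos + k]].append((name, pos))
        self._table = dict(table)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Forward-strand occurrences of *kmer*."""
        return self._table.get(kmer, [])

    def occurrences(self, kmer: str) -> dict[str, list[tuple[str, int]]]:
        """Occurrences on both strands.  A '-' entry (chrom, pos) means the
        reverse complement of chrom[pos:pos+k] equals *kmer*."""
        return {"+": self.lookup(kmer), "-": self.lookup(revcomp(kmer))}


def build_index(ref: ReferenceGenome | dict[str, str], k: int) -> SeedIndex:
    """Build the seed index; k must not exceed the shortest chromosome."""
    chroms = ref.chroms if isinstance(ref, ReferenceGenome) else ref
    if k < 1:
        raise ConfigError("seed length must be >= 1")
    shortest = min((len(s) for s in chroms.values()), default=0)
    if k > shortest:
        raise ConfigError(
            f"seed length {k} exceeds shortest chromosome ({shortest} bp)"
        )
    return SeedIndex(chroms, k)


def _read_parts(read: "MockRead | tuple[str, str]") -> tuple[str, str]:
    if isinstance(read, MockRead):
        return read.read_id, read.seq
    read_id, seq = read
    return read_id, seq


def _candidate_loci(index: SeedIndex, query: str) -> set[tuple[str, int]]:
    """All diagonal start positions implied by exact seed hits at any offset."""
    k = index.k
    out: set[tuple[str, int]] = set()
    for off in range(0, len(query) - k + 1):
        for chrom, pos in index.lookup(query[off:off + k]):
            start = pos - off
            if start >= 0 and start + len(query) <= len(index.chroms[chrom]):
                out.add((chrom, start))
    return out


def map_read_ungapped(index: SeedIndex, read, policy: MappingPolicy | None = None
                      ) -> AlignmentRecord:
    """Map one read in the ungapped regime (see module docstring).

    ``read`` may be a :class:`MockRead` or a ``(read_id, seq)`` pair.  Seed
    mismatches are counted in *read* coordinates: for a reverse-strand
    placement the read's first bases sit at the 3' end of the forward-strand
    window.
    """
    policy = policy or MappingPolicy()
    read_id, seq = _read_parts(read)
    if not seq:
        raise ValidationError(f"read {read_id} is empty")
    if len(seq) < policy.seed_len:
        raise ValidationError(
            f"read {read_id} shorter than seed length {policy.seed_len}"
        )
    length = len(seq)
    survivors: list[tuple[int, str, int, str]] = []  # (mismatches, chrom, start, strand)
    for strand in ("+", "-"):
        query = seq if strand == "+" else revcomp(seq)
        q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
        if strand == "+":
            seed_slice = slice(0, policy.seed_len)
        else:  # read's first seed_len bases are the window's last seed_len
            seed_slice = slice(length - policy.seed_len, length)
        for chrom, start in sorted(_candidate_loci(index, query)):
            window = index.encoded[chrom][start:start + length]
            diffs = window != q_arr
            total = int(diffs.sum())
            if total > policy.max_total_mismatches:
                continue
            if int(diffs[seed_slice].sum()) > policy.max_seed_mismatches:
                continue
            survivors.append((total, chrom, start, strand))
    if not survivors:
        return AlignmentRecord(read_id=read_id, status="unaligned")
    survivors.sort()
    if policy.best_mode:
        best_mm = survivors[0][0]
        best = [s for s in survivors if s[0] == best_mm]
    else:
        best = survivors
    if len(best) > 1:
        return AlignmentRecord(read_id=read_id, status="multi")
    mm, chrom, start, strand = best[0]
    return AlignmentRecord(
        read_id=read_id,
        status="unique",
        interval=GenomicInterval(chrom, start, start + length),
        strand=strand,
        mismatches=mm,
    )


# ---------------------------------------------------------------------------
# gapped regime
# ---------------------------------------------------------------------------

_NEG_INF = float("-inf")


def _fit_align(query: str, window: str, sc: GapScoring
               ) -> tuple[float, int, int, int, int]:
    """Fitting alignment: query global, window local (free end gaps in window).

    Returns (score, window_start, window_end, gaps, mismatches) for the best
    placement, where [window_start, window_end) is the aligned span within
    *window* and ``gaps`` is the total number of gapped bases.  Gotoh affine
    recurrences with full traceback; windows are tiny so no cell-level banding
    is needed.
    """
    m, n = len(query), len(window)
    # H: best ending in match/mismatch; E: gap in query (window base consumed);
    # F: gap in window (query base consumed)
    H = np.full((m + 1, n + 1), _NEG_INF)
    E = np.full((m + 1, n + 1), _NEG_INF)
    F = np.full((m + 1, n + 1), _NEG_INF)
    best = np.full((m + 1, n + 1), _NEG_INF)
    # traceback: 0=H(diag), 1=E(left), 2=F(up)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    best[0, :] = 0.0  # free leading window gap: alignment may start anywhere
    for i in range(1, m + 1):
        F[i, 0] = (best[i - 1, 0] + sc.gap_open
                   if i == 1 else F[i - 1, 0] + sc.gap_extend)
        best[i, 0] = F[i, 0]
        ptr[i, 0] = 2
        qi = query[i - 1]
        for j in range(1, n + 1):
            sub = sc.match if qi == window[j - 1] else sc.mismatch
            H[i, j] = best[i - 1, j - 1] + sub
            E[i, j] = max(best[i, j - 1] + sc.gap_open, E[i, j - 1] + sc.gap_extend)
            F[i, j] = max(best[i - 1, j] + sc.gap_open, F[i - 1, j] + sc.gap_extend)
            b = max(H[i, j], E[i, j], F[i, j])
            best[i, j] = b
            ptr[i, j] = 0 if b == H[i, j] else (1 if b == E[i, j] else 2)
    end_j = int(np.argmax(best[m, :]))
    score = float(best[m, end_j])
    # traceback to find the aligned window span, gap and mismatch counts
    i, j, gaps, mism = m, end_j, 0, 0
    while i > 0:
        p = ptr[i, j]
        if p == 0:
            if query[i - 1] != window[j - 1]:
                mism += 1
            i, j = i - 1, j - 1
        elif p == 1:
            j -= 1
            gaps += 1
        else:
            i -= 1
            gaps += 1
    return score, j, end_j, gaps, mism


def map_read_gapped(index: SeedIndex, read, policy: MappingPolicy | None = None,
                    scoring: GapScoring | None = None) -> AlignmentRecord:
    """Map one read in the gapped regime.

    Candidate windows are built around seed-hit diagonals (diagonals within
    ``band`` of each other are merged; low-support diagonals are pruned when
    many candidates exist).  Each window is aligned by :func:`_fit_align`; the
    best placement wins, distinct equally-best placements give ``multi`` and a
    best score under the threshold gives ``unaligned``.
    """
    policy = policy or MappingPolicy(mode="gapped")
    sc = scoring or GapScoring()
    if sc.band < _INDEL_LEN:
        warnings.warn(
            f"band {sc.band} is smaller than the {_INDEL_LEN}-nt injected "
            "indel length; gapped placements may be missed",
            stacklevel=2,
        )
    read_id, seq = _read_parts(read)
    if not seq:
        raise ValidationError(f"read {read_id} is empty")
    length = len(seq)
    k = index.k

    # gather seed votes per (strand, chrom, diagonal)
    votes: Counter[tuple[str, str, int]] = Counter()
    for strand in ("+", "-"):
        query = seq if strand == "+" else revcomp(seq)
        for off in range(0, len(query) - k + 1):
            for chrom, pos in index.lookup(query[off:off + k]):
                votes[(strand, chrom, pos - off)] += 1

    # merge nearby diagonals into windows; prune weak singletons when crowded
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for (strand, chrom, diag), n_votes in votes.items():
        grouped[(strand, chrom)].append((diag, n_votes))
    candidates: list[tuple[str, str, int]] = []  # (strand, chrom, diag, votes->merged)
    merged_votes: list[int] = []
    for (strand, chrom), diags in grouped.items():
        diags.sort()
        cur_diag, cur_votes = diags[0]
        acc = [diags[0]]
        for diag, n_votes in diags[1:]:
            if diag - acc[-1][0] <= sc.band:
                acc.append((diag, n_votes))
            else:
                best_d = max(acc, key=lambda t: t[1])[0]
                candidates.append((strand, chrom, best_d))
                merged_votes.append(sum(v for _, v in acc))
                acc = [(diag, n_votes)]
        best_d = max(acc, key=lambda t: t[1])[0]
        candidates.append((strand, chrom, best_d))
        merged_votes.append(sum(v for _, v in acc))
    if len(candidates) > 20:
        order = sorted(range(len(candidates)),
                       key=lambda i: (-merged_votes[i], candidates[i]))
        keep = [i for i in order if merged_votes[i] >= 2][:20] or order[:20]
        candidates = [candidates[i] for i in sorted(keep)]

    results: list[tuple[float, str, int, int, str, int, int]] = []
    for strand, chrom, diag in sorted(candidates):
        query = seq if strand == "+" else revcomp(seq)
        chrom_len = len(index.chroms[chrom])
        w_start = max(0, diag - sc.band)
        w_end = min(chrom_len, diag + length + sc.band)
        if w_end - w_start < k:
            continue
        window = index.chroms[chrom][w_start:w_end]
        score, a_start, a_end, gaps, mism = _fit_align(query, window, sc)
        results.append(
            (score, chrom, w_start + a_start, w_start + a_end, strand, gaps, mism)
        )
    results.sort(key=lambda r: (-r[0], r[1], r[2], r[4]))
    if not results or results[0][0] < sc.min_score(length):
        return AlignmentRecord(read_id=read_id, status="unaligned")
    top_score = results[0][0]
    # distinct loci tied at the top (same start within band = same locus)
    top = [r for r in results if r[0] == top_score]
    distinct: list[tuple[float, str, int, int, str, int, int]] = []
    for r in top:
        if not any(
            r[1] == d[1] and abs(r[2] - d[2]) <= sc.band for d in distinct
        ):
            distinct.append(r)
    if len(distinct) > 1:
        return AlignmentRecord(read_id=read_id, status="multi")
    score, chrom, g_start, g_end, strand, gaps, mism = distinct[0]
    return AlignmentRecord(
        read_id=read_id,
        status="unique",
        interval=GenomicInterval(chrom, g_start, g_end),
        strand=strand,
        mismatches=mism,
        score=score,
    )


# ---------------------------------------------------------------------------
# accuracy assessment
# ---------------------------------------------------------------------------


@dataclass
class AccuracyReport:
    """Mapping outcome counts, truth-agreement rate and per-base depth."""

    n_total: int
    n_unique: int
    n_multi: int
    n_unaligned: int
    n_correct: int
    per_base_depth: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        """Fraction of unique alignments agreeing with truth (0 when none)."""
        return self.n_correct / self.n_unique if self.n_unique else 0.0


def assess_mapping_accuracy(alignments: list[AlignmentRecord],
                            truth: dict[str, MockRead]) -> AccuracyReport:
    """Compare unique alignments with the truth set.

    A unique alignment is *correct* when its chromosome matches truth and its
    start equals the truth start — exactly for reads without indels, within
    +/-5 bp for indel-carrying reads (an indel legitimately shifts the optimal
    placement).  Per-base depth accumulates over all unique alignments.
    """
    n_unique = n_multi = n_unaligned = n_correct = 0
    depth: Counter[tuple[str, int]] = Counter()
    for rec in alignments:
        if rec.read_id not in truth:
            raise DataError(f"read {rec.read_id} missing from the truth set")
        if rec.status == "multi":
            n_multi += 1
            continue
        if rec.status == "unaligned":
            n_unaligned += 1
            continue
        n_unique += 1
        assert rec.interval is not None
        read = truth[rec.read_id]
        tol = (
            _INDEL_START_TOLERANCE
            if read.modification is not None and read.modification.is_indel
            else 0
        )
        if (
            rec.interval.chrom == read.origin.chrom
            and abs(rec.interval.start - read.origin.start) <= tol
        ):
            n_correct += 1
        for pos in range(rec.interval.start, rec.interval.end):
            depth[(rec.interval.chrom, pos)] += 1
    return AccuracyReport(
        n_total=len(alignments),
        n_unique=n_unique,
        n_multi=n_multi,
        n_unaligned=n_unaligned,
        n_correct=n_correct,
        per_base_depth=dict(depth),
    )
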