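"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation: exhaustive scans,
all-pairs rule checks and graph closures at tiny problem sizes.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def exhaustive_ungapped_scan(chroms: dict[str, str], seq: str,
                             seed_len: int, max_seed_mm: int,
                             max_total_mm: int, best_mode: bool = True):
    """Scan every offset of every chromosome on both strands, applying the
    seed/total mismatch caps and the best-hit rule.

    Returns (status, locus, mismatches) with locus = (chrom, start, strand)
    for a unique hit, else (status, None, None).
    """
    length = len(seq)
    survivors = []
    for strand in ("+", "-"):
        query = seq if strand == "+" else rc(seq)
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        # read's first seed_len bases: at window start for "+", window end for "-"
        seed_cols = (
            np.arange(seed_len) if strand == "+"
            else np.arange(length - seed_len, length)
        )
        for chrom, cseq in chroms.items():
            g = np.frombuffer(cseq.encode(), dtype=np.uint8)
            if len(g) < length:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(g, length)
            diffs = windows != q
            totals = diffs.sum(axis=1)
            seed_mm = diffs[:, seed_cols].sum(axis=1)
            ok = (totals <= max_total_mm) & (seed_mm <= max_seed_mm)
            for start in np.nonzero(ok)[0]:
                survivors.append((int(totals[start]), chrom, int(start), strand))
    if not survivors:
        return "unaligned", None, None
    survivors.sort()
    if best_mode:
        best_val = survivors[0][0]
        best = [s for s in survivors if s[0] == best_val]
    else:
        best = survivors
    if len(best) > 1:
        return "multi", None, None
    mm, chrom, start, strand = best[0]
    return "unique", (chrom, start, strand), mm


def brute_force_denoise(reads, background, threshold: float):
    """All-pairs application of the three removal rules, first-match-wins.

    Returns {read_id: reason or None}.
    """
    out = {}
    for read in reads:
        reason = None
        for entry in background:
            if entry.seq == read.seq and entry.interval == read.interval:
                reason = "identical"
                break
        if reason is None:
            for entry in background:
                a, b = read.interval, entry.interval
                if a.chrom == b.chrom and b.start <= a.start and a.end <= b.end:
                    reason = "contained"
                    break
        if reason is None:
            for entry in background:
                a, b = read.interval, entry.interval
                if a.chrom != b.chrom:
                    continue
                shared = max(0, min(a.end, b.end) - max(a.start, b.start))
                if shared / (a.end - a.start) > threshold:
                    reason = "overlap"
                    break
        out[read.read_id] = reason
    return out


def closure_clusters(intervals, gap: int):
    """Connected components of the 'distance <= gap' graph over intervals.

    intervals: list of (chrom, start, end).  Returns a sorted list of
    (chrom, start, end, frozenset(member indices)).
    """
    n = len(intervals)
    adj = [[] for _ in range(n)]
    for i in range(n):
        ci, si, ei = intervals[i]
        for j in range(i + 1, n):
            cj, sj, ej = intervals[j]
            if ci != cj:
                continue
            dist = max(si, sj) - min(ei, ej)  # negative when overlapping
            if dist <= gap:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, members = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            members.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        chrom = intervals[i][0]
        start = min(intervals[m][1] for m in members)
        end = max(intervals[m][2] for m in members)
        comps.append((chrom, start, end, frozenset(members)))
    return sorted(comps)
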