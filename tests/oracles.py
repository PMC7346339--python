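"""Independent brute-force oracles used to cross-check the fast implementations.

These deliberately use naive enumeration (all windows, all offsets, all
alignments) so they share no code path with the seeded/DP implementations
they verify.
"""

from __future__ import annotations

import math

from slfinder.core_io import revcomp
from slfinder.variant_builder import (
    GAP_EXTEND,
    GAP_OPEN,
    MATCH,
    MISMATCH,
    TERM_GAP_EXTEND,
    TERM_GAP_OPEN,
)


# ---------------------------------------------------------------------------
# exhaustive hook-hit oracle (every strand, every offset, every window)
# ---------------------------------------------------------------------------

def brute_hook_hits(
    hook: str,
    transcript: str,
    *,
    min_identity: float = 0.90,
    min_cov: float = 0.80,
    seed_len: int = 7,
):
    """All-window scorer for one transcript.

    Returns ("multi", None) when two or more disjoint qualifying windows
    exist, (None, None) when none qualifies, else ("hit", record) with the
    single best window under the same scoring contract: +1 match / -2
    mismatch, best positive-sum window per diagonal (longest then
    smallest start on ties), diagonal eligible only if it carries an exact
    seed_len run, qualifying if span >= min_cov * |hook| and identity >=
    min_identity.
    """
    qualifying = []
    for strand in "+-":
        h = hook if strand == "+" else revcomp(hook)
        for off in range(-(len(h) - 1), len(transcript)):
            q_lo = max(0, -off)
            q_hi = min(len(h), len(transcript) - off)
            if q_hi <= q_lo:
                continue
            cmp = [h[q] == transcript[q + off] for q in range(q_lo, q_hi)]
            # diagonal eligibility: an exact run of >= seed_len anywhere
            run = 0
            eligible = False
            for c in cmp:
                run = run + 1 if c else 0
                if run >= seed_len:
                    eligible = True
                    break
            if not eligible:
                continue
            best = None
            best_sum = 0
            best_span = 0
            for s in range(q_lo, q_hi):
                total = 0
                matches = 0
                for e in range(s + 1, q_hi + 1):
                    total += 1 if cmp[e - 1 - q_lo] else -2
                    matches += 1 if cmp[e - 1 - q_lo] else 0
                    if total > best_sum or (total == best_sum and total > 0 and e - s > best_span):
                        best_sum = total
                        best_span = e - s
                        best = (s, e, matches)
            if best is None:
                continue
            s, e, matches = best
            span = e - s
            if span >= min_cov * len(hook) and matches / span >= min_identity:
                qualifying.append((best_sum, strand, off, s, e, s + off, e + off))
    if not qualifying:
        return None, None
    # group by subject overlap (abutting intervals stay disjoint)
    ordered = sorted(qualifying, key=lambda w: (w[5], w[6]))
    groups = []
    cur_end = None
    for w in ordered:
        if cur_end is not None and w[5] < cur_end:
            groups[-1].append(w)
            cur_end = max(cur_end, w[6])
        else:
            groups.append([w])
            cur_end = w[6]
    if len(groups) >= 2:
        return "multi", None
    best = min(groups[0], key=lambda w: (-w[0], w[1] != "+", w[5], w[2]))
    return "hit", best


# ---------------------------------------------------------------------------
# brute-force genome substring scan
# ---------------------------------------------------------------------------

def brute_genome_hits(variant: str, chrom: str, genome_seq: str, min_cov: float = 0.90):
    """Every maximal exact run of length >= ceil(min_cov * |variant|).

    Slides the variant across every offset of both strands and reports
    maximal match runs, as (chrom, start, end, strand, q_start, q_end).
    """
    need = math.ceil(min_cov * len(variant))
    out = set()
    for strand in "+-":
        v = variant if strand == "+" else revcomp(variant)
        for off in range(-(len(v) - need), len(genome_seq) - need + 1):
            q_lo = max(0, -off)
            q_hi = min(len(v), len(genome_seq) - off)
            if q_hi - q_lo < need:
                continue
            q = q_lo
            while q < q_hi:
                if v[q] == genome_seq[q + off]:
                    start = q
                    while q < q_hi and v[q] == genome_seq[q + off]:
                        q += 1
                    if q - start >= need:
                        if strand == "+":
                            qs, qe = start, q
                        else:
                            qs, qe = len(v) - q, len(v) - start
                        out.add((chrom, start + off, q + off, strand, qs, qe))
                else:
                    q += 1
    return out


# ---------------------------------------------------------------------------
# exhaustive pairwise alignment enumeration
# ---------------------------------------------------------------------------

def score_pairwise_alignment(row_a: str, row_b: str) -> float:
    """Score a gapped pair under the package's affine scheme.

    Matches +2, mismatches -1, a gap run costs open + extend*(len-1), with
    the discounted terminal rates for leading/trailing runs.
    """
    assert len(row_a) == len(row_b)
    score = 0.0
    for row in (row_a, row_b):
        i = 0
        n = len(row)
        while i < n:
            if row[i] != "-":
                i += 1
                continue
            start = i
            while i < n and row[i] == "-":
                i += 1
            terminal = start == 0 or i == n
            opens = TERM_GAP_OPEN if terminal else GAP_OPEN
            ext = TERM_GAP_EXTEND if terminal else GAP_EXTEND
            score += opens + ext * (i - start - 1)
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            score += MATCH if ca == cb else MISMATCH
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every gapped global alignment of two (short) sequences."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb


def best_pairwise_score(a: str, b: str) -> float:
    return max(
        score_pairwise_alignment(ra, rb) for ra, rb in enumerate_alignments(a, b)
    )
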