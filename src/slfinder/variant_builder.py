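"""Step2 — turn a Best Hook's transcript hits into trimmed Hook Variants.

The transcript ends matching a Best Hook are retrieved (through two bases past
the match's inner boundary, to recover as much of the putative SL as
possible), oriented to read 5'->3' in SL sense, deduplicated by exact
containment, aligned, and column-trimmed. The unique ungapped rows of the
trimmed alignment are the Hook Variants: plausible versions of the repeated
sequence behind the Hook, covering both real polymorphism and sequencing or
assembly error. Position-frequency matrices before and after trimming replace
graphical sequence logos.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core_io import Transcript, revcomp
from .hook_discovery import Hook, HookHit, Orientation, PositionClass

logger = logging.getLogger(__name__)

RETRIEVAL_OVERHANG = 2  # bases kept past the hook match's inner boundary

MATCH = 2.0
MISMATCH = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0
# terminal gap runs are discounted so that ragged 5' junk and 3' overhangs
# pack against the conserved core instead of misaligning into it
TERM_GAP_OPEN = -2.0
TERM_GAP_EXTEND = -1.0

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class RetrievedEnd:
    source_id: str
    sequence: str
    truncated: bool


@dataclass
class Alignment:
    rows: list[tuple[str, str]]  # (id, gapped sequence)

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0


@dataclass(frozen=True)
class HookVariant:
    hook_id: str
    variant_id: str
    sequence: str
    support: int
    source_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# retrieval
# ---------------------------------------------------------------------------

def retrieve_hit_ends(
    hook: Hook, hits: list[HookHit], transcripts: dict[str, Transcript]
) -> list[RetrievedEnd]:
    """Retrieve the SL-sense transcript-end sequence behind each hit.

    Only hits in the hook's majority valid configuration are used (Sf+Er for a
    sense hook, Sr+Ef for antisense; an undetermined hook falls back to the
    sense configuration). Start hits yield ``transcript[0 : subject_end + 2]``
    as-is; End hits yield the reverse complement of
    ``transcript[subject_start - 2 :]``, so every output reads 5'->3' in SL
    sense. Windows running past a contig edge are truncated and flagged.
    """
    if hook.orientation_call is Orientation.ANTISENSE:
        wanted = {(PositionClass.START, "-"), (PositionClass.END, "+")}
    else:
        wanted = {(PositionClass.START, "+"), (PositionClass.END, "-")}
    out: list[RetrievedEnd] = []
    for hit in hits:
        if (hit.position_class, hit.strand) not in wanted:
            continue
        t = transcripts[hit.contig_id]
        if hit.position_class is PositionClass.START:
            stop = hit.subject_end + RETRIEVAL_OVERHANG
            truncated = stop > t.length
            seq = t.sequence[: min(stop, t.length)]
        else:
            start = hit.subject_start - RETRIEVAL_OVERHANG
            truncated = start < 0
            seq = revcomp(t.sequence[max(start, 0) :])
        if truncated:
            logger.debug("retrieval window truncated at contig edge for %s", hit.contig_id)
        out.append(RetrievedEnd(hit.contig_id, seq, truncated))
    return out


# ---------------------------------------------------------------------------
# containment clustering (100% identity dedup)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    representative: str
    support: int
    members: tuple[str, ...]  # member source ids


def dedup_cluster(sequences: list[tuple[str, str]], identity: float = 1.0) -> list[Cluster]:
    """Greedy containment clustering at 100% identity.

    ``sequences`` is ``[(source_id, sequence), ...]``. Sorted by descending
    length (ties lexicographic), each sequence joins the first earlier
    representative that contains it as an exact substring, else founds a new
    cluster. Only the 100% identity mode is defined; this is the default the
    pipeline uses everywhere deduplication is needed.
    """
    if identity != 1.0:
        raise NotImplementedError("only the 100% identity threshold is supported")
    ordered = sorted(sequences, key=lambda r: (-len(r[1]), r[1], r[0]))
    reps: list[tuple[str, list[str]]] = []  # (representative sequence, member ids)
    for source_id, seq in ordered:
        for rep_seq, members in reps:
            if seq in rep_seq:
                members.append(source_id)
                break
        else:
            reps.append((seq, [source_id]))
    return [Cluster(rep, len(members), tuple(members)) for rep, members in reps]


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 4) -> float:
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    sb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def _upgma_order(dist: list[list[float]]) -> list[tuple[int, int]]:
    """UPGMA joins on a dense distance matrix; returns merge pairs of node ids.

    Leaves are 0..n-1; internal nodes continue the numbering. Ties break on the
    smallest node-id pair, so the guide tree is deterministic.
    """
    n = len(dist)
    active: dict[int, dict[int, float]] = {
        i: {j: dist[i][j] for j in range(n) if j != i} for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int]] = []
    next_id = n
    while len(active) > 1:
        pair = min(
            ((d, i, j) for i in active for j, d in active[i].items() if i < j),
            key=lambda t: (t[0], t[1], t[2]),
        )
        _, i, j = pair
        merges.append((i, j))
        di, dj = active.pop(i), active.pop(j)
        ni, nj = sizes.pop(i), sizes.pop(j)
        merged: dict[int, float] = {}
        for k_ in active:
            merged[k_] = (di[k_] * ni + dj[k_] * nj) / (ni + nj)
            active[k_].pop(i, None)
            active[k_].pop(j, None)
            active[k_][next_id] = merged[k_]
        active[next_id] = merged
        sizes[next_id] = ni + nj
        next_id += 1
    return merges


def _profile(rows: list[str]) -> list[tuple[list[float], float]]:
    """Per column: ([A,C,G,T] counts], total non-gap non-N count)."""
    cols = []
    for j in range(len(rows[0])):
        counts = [0.0, 0.0, 0.0, 0.0]
        for row in rows:
            c = row[j]
            if c in _BASE_IDX:
                counts[_BASE_IDX[c]] += 1.0
        cols.append((counts, sum(counts)))
    return cols


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global affine-gap alignment of two profiles (Gotoh).

    Column-column score is the normalized sum of pairs (match +2, mismatch -1;
    gaps and N score 0); a gap run of length g costs open + extend*(g-1).
    Returns the two row sets padded with the new gap columns.
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    na, nb = float(len(rows_a)), float(len(rows_b))
    la, lb = len(pa), len(pb)

    def colscore(i: int, j: int) -> float:
        ca, ta = pa[i]
        cb, tb = pb[j]
        dot = ca[0] * cb[0] + ca[1] * cb[1] + ca[2] * cb[2] + ca[3] * cb[3]
        return (3.0 * dot - ta * tb) / (na * nb)

    def gap_costs_x(j: int) -> tuple[float, float]:
        # gap columns in B are terminal when B is not yet started or exhausted
        if j == 0 or j == lb:
            return TERM_GAP_OPEN, TERM_GAP_EXTEND
        return GAP_OPEN, GAP_EXTEND

    def gap_costs_y(i: int) -> tuple[float, float]:
        if i == 0 or i == la:
            return TERM_GAP_OPEN, TERM_GAP_EXTEND
        return GAP_OPEN, GAP_EXTEND

    NEG = float("-inf")
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap columns in B (consume A)
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap columns in A (consume B)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = TERM_GAP_OPEN + TERM_GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = TERM_GAP_OPEN + TERM_GAP_EXTEND * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = colscore(i - 1, j - 1)
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            xo, xe = gap_costs_x(j)
            X[i][j] = max(M[i - 1][j] + xo, X[i - 1][j] + xe, Y[i - 1][j] + xo)
            yo, ye = gap_costs_y(i)
            Y[i][j] = max(M[i][j - 1] + yo, X[i][j - 1] + yo, Y[i][j - 1] + ye)
    # traceback; ties always resolve in M > X > Y order for determinism
    def argbest(candidates: list[tuple[str, float]]) -> str:
        best = max(v for _, v in candidates)
        for st, v in candidates:
            if v == best:
                return st
        raise AssertionError("unreachable")

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    state = argbest([("M", M[la][lb]), ("X", X[la][lb]), ("Y", Y[la][lb])])
    while i > 0 or j > 0:
        if state == "M":
            out_a.append("A")  # marker: consume one column of A
            out_b.append("B")
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = argbest([("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j])])
        elif state == "X":
            out_a.append("A")
            out_b.append("-")
            xo, xe = gap_costs_x(j)
            i -= 1
            if i == 0 and j == 0:
                break
            state = argbest(
                [("M", M[i][j] + xo), ("X", X[i][j] + xe), ("Y", Y[i][j] + xo)]
            )
        else:
            out_a.append("-")
            out_b.append("B")
            yo, ye = gap_costs_y(i)
            j -= 1
            if i == 0 and j == 0:
                break
            state = argbest(
                [("M", M[i][j] + yo), ("X", X[i][j] + yo), ("Y", Y[i][j] + ye)]
            )
    out_a.reverse()
    out_b.reverse()
    new_a = _expand(rows_a, out_a)
    new_b = _expand(rows_b, out_b)
    return new_a, new_b


def _expand(rows: list[str], pattern: list[str]) -> list[str]:
    out = []
    for row in rows:
        chars = []
        pos = 0
        for p in pattern:
            if p == "-":
                chars.append("-")
            else:
                chars.append(row[pos])
                pos += 1
        out.append("".join(chars))
    return out


def _polish_gaps(rows: list[str], max_passes: int = 10) -> list[str]:
    """Resolve indel-placement degeneracy by score-improving gap shifts.

    Progressive alignment places score-equivalent gaps arbitrarily inside
    repeated context (e.g. a homopolymer spanning a conserved core's edge),
    which destabilises column gap fractions and hence trimming. This pass
    slides each maximal gap run one column left or right whenever doing so
    strictly increases the sum-of-pairs score of the affected columns,
    repeating until convergence. Row contents (ungapped sequences) are
    untouched; only column assignment changes. Deterministic.
    """
    if not rows:
        return rows
    ncol = len(rows[0])
    counts = [[0] * 4 for _ in range(ncol)]
    totals = [0] * ncol
    grid = [list(r) for r in rows]
    for row in grid:
        for j, c in enumerate(row):
            if c in _BASE_IDX:
                counts[j][_BASE_IDX[c]] += 1
                totals[j] += 1

    nrow = len(rows)

    def colscore_at(b: int, n_same: int, n_bases: int) -> float:
        # pairwise score of one base against the other rows of a column:
        # +2 per match, -1 per mismatch, -0.5 per gap pair; the gap term makes
        # the pass pack stray flanking bases instead of spreading them
        return 3.0 * n_same - n_bases - 0.5 * (nrow - 1 - n_bases)

    def delta(row: list[str], src: int, dst: int) -> float:
        c = row[src]
        b = _BASE_IDX.get(c)
        if b is None:
            return 0.0
        gain = colscore_at(b, counts[dst][b], totals[dst])
        loss = colscore_at(b, counts[src][b] - 1, totals[src] - 1)
        return gain - loss

    def move(row: list[str], src: int, dst: int) -> None:
        c = row[src]
        b = _BASE_IDX[c]
        counts[src][b] -= 1
        totals[src] -= 1
        counts[dst][b] += 1
        totals[dst] += 1
        row[dst] = c
        row[src] = "-"

    for _ in range(max_passes):
        changed = False
        for row in grid:
            j = 0
            while j < ncol:
                if row[j] != "-":
                    j += 1
                    continue
                g0 = j
                while j < ncol and row[j] == "-":
                    j += 1
                g1 = j  # gap run [g0, g1)
                if g1 < ncol and row[g1] != "-" and delta(row, g1, g0) > 0:
                    move(row, g1, g0)  # slide run right
                    changed = True
                elif g0 > 0 and row[g0 - 1] != "-" and delta(row, g0 - 1, g1 - 1) > 0:
                    move(row, g0 - 1, g1 - 1)  # slide run left
                    changed = True
        if not changed:
            break
    return ["".join(r) for r in grid]


def align_progressive(sequences: list[tuple[str, str]]) -> Alignment:
    """Guide-tree progressive global alignment of ``[(id, sequence), ...]``.

    The guide tree is UPGMA on pairwise k-mer distances; profiles are merged
    with an affine-gap Gotoh aligner. Fully deterministic; ungapping any row
    reproduces its input sequence.
    """
    if not sequences:
        return Alignment(rows=[])
    if len(sequences) == 1:
        return Alignment(rows=[(sequences[0][0], sequences[0][1])])
    n = len(sequences)
    dist = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = _kmer_distance(sequences[i][1], sequences[j][1])
            dist[i][j] = dist[j][i] = d
    merges = _upgma_order(dist)
    nodes: dict[int, tuple[list[str], list[str]]] = {
        i: ([sequences[i][0]], [sequences[i][1]]) for i in range(n)
    }
    next_id = n
    for i, j in merges:
        ids_a, rows_a = nodes.pop(i)
        ids_b, rows_b = nodes.pop(j)
        new_a, new_b = _align_profiles(rows_a, rows_b)
        nodes[next_id] = (ids_a + ids_b, new_a + new_b)
        next_id += 1
    (ids, rows), = nodes.values()
    rows = _polish_gaps(rows)
    # drop columns that became all-gap during polishing
    keep = [j for j in range(len(rows[0])) if any(r[j] != "-" for r in rows)]
    rows = ["".join(r[j] for j in keep) for r in rows]
    by_id = dict(zip(ids, rows))
    ordered_ids = [sid for sid, _ in sequences]
    return Alignment(rows=[(sid, by_id[sid]) for sid in ordered_ids])


# ---------------------------------------------------------------------------
# trimming, variants, PFMs
# ---------------------------------------------------------------------------

def trim_alignment(
    alignment: Alignment, gap_fraction: float = 0.1, min_block: int = 5
) -> tuple[Alignment, bool]:
    """Drop gap-rich columns, then keep only blocks of consecutive survivors.

    A column survives when its gap fraction is strictly below ``gap_fraction``;
    surviving columns must form runs of at least ``min_block``. If nothing
    survives the input is returned untrimmed with a flag, so a hook is carried
    forward for manual inspection rather than silently lost.
    """
    if not alignment.rows:
        return alignment, False
    ncol = alignment.column_count
    nrow = len(alignment.rows)
    keep = []
    for j in range(ncol):
        gaps = sum(1 for _, row in alignment.rows if row[j] == "-")
        keep.append(gaps / nrow < gap_fraction)
    # enforce minimum block length on runs of kept columns
    kept_cols: list[int] = []
    j = 0
    while j < ncol:
        if keep[j]:
            start = j
            while j < ncol and keep[j]:
                j += 1
            if j - start >= min_block:
                kept_cols.extend(range(start, j))
        else:
            j += 1
    if not kept_cols:
        logger.warning("trimming removed every column; alignment kept untrimmed")
        return alignment, True
    rows = [
        (rid, "".join(row[j] for j in kept_cols)) for rid, row in alignment.rows
    ]
    return Alignment(rows=rows), False


def variants_from_alignment(
    hook_id: str, alignment: Alignment, support: dict[str, int]
) -> list[HookVariant]:
    """Unique ungapped row sequences of a (trimmed) alignment, support summed."""
    grouped: dict[str, tuple[int, list[str]]] = {}
    for rid, row in alignment.rows:
        seq = row.replace("-", "")
        if not seq:
            continue
        count, ids = grouped.get(seq, (0, []))
        grouped[seq] = (count + support.get(rid, 1), ids + [rid])
    ordered = sorted(grouped.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [
        HookVariant(hook_id, f"{hook_id}.v{i}", seq, count, tuple(ids))
        for i, (seq, (count, ids)) in enumerate(ordered, start=1)
    ]


PFM_SYMBOLS = ("A", "C", "G", "T", "N", "-")


def position_frequency_matrix(alignment: Alignment) -> list[dict[str, float]]:
    """Per-column frequencies of A/C/G/T/N/gap; each column sums to 1."""
    if not alignment.rows:
        return []
    nrow = len(alignment.rows)
    out = []
    for j in range(alignment.column_count):
        col = {s: 0.0 for s in PFM_SYMBOLS}
        for _, row in alignment.rows:
            col[row[j]] += 1.0
        out.append({s: col[s] / nrow for s in PFM_SYMBOLS})
    return out


def build_variants(
    hook: Hook,
    transcripts: dict[str, Transcript],
    *,
    identity: float = 1.0,
    gap_fraction: float = 0.1,
    min_block: int = 5,
) -> tuple[list[HookVariant], Alignment, Alignment, list[RetrievedEnd], list[Cluster]]:
    """Full Step2 for one Best Hook.

    Returns (variants, alignment, trimmed alignment, retrieved ends, clusters).
    """
    ends = retrieve_hit_ends(hook, hook.hits, transcripts)
    clusters = dedup_cluster([(e.source_id, e.sequence) for e in ends], identity)
    named = [(f"{hook.hook_id}.c{i}", c.representative) for i, c in enumerate(clusters, 1)]
    support = {name: c.support for (name, _), c in zip(named, clusters)}
    aln = align_progressive(named)
    trimmed, trim_failed = trim_alignment(aln, gap_fraction, min_block)
    variants = variants_from_alignment(hook.hook_id, trimmed, support)
    if trim_failed:
        logger.warning("hook %s: untrimmed variants carried forward", hook.hook_id)
    logger.info(
        "hook %s: %d ends retrieved, %d clusters, %d variants",
        hook.hook_id,
        len(ends),
        len(clusters),
        len(variants),
    )
    return variants, aln, trimmed, ends, clusters
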