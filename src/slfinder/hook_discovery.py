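"""Step1 — kmer enrichment on transcript ends, Hook assembly and selection.

The terminal regions produced by Step0 are decomposed into canonical kmers.
Kmers observed in enough distinct contigs are assembled greedily into longer
"Hook" sequences — candidate repeated elements, of which a true spliced leader
(if present) is one. Each Hook is then searched against the *full, unfiltered*
transcriptome; the strand/position pattern of its hits decides whether it
behaves like a 5′ spliced leader.

Because library preparation loses strand information, a contig may represent
the mRNA (sense) or its reverse complement (antisense). A genuine 5′ SL
therefore produces hits in exactly two mutually exclusive, valid
configurations:

* configuration A — forward at the Start of sense contigs (Sf) together with
  reverse at the End of antisense contigs (Er);
* configuration B — reverse at the Start (Sr) together with forward at the End
  (Ef).

The consistency orientation index summarises this::

    coi = max(Sf + Er, Sr + Ef) / (Sf + Sr + Ef + Er + middle)

so coi == 1 means every hit falls in one and only one valid configuration,
and hits in the middle of a contig, or split across both configurations, pull
the index down. Hooks with few hits reach a high coi by chance, hence the
observation-count cutoff (occ): the median total hit count over all Hooks.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from enum import Enum

from .core_io import Transcript, canonical, revcomp
from .reduce_ends import EndRegion

logger = logging.getLogger(__name__)

MIN_COUNT_K = 8  # below this, canonical collisions dominate end-kmer counts


# ---------------------------------------------------------------------------
# kmer counting and thresholding
# ---------------------------------------------------------------------------

@dataclass
class KmerTable:
    k: int
    counts: dict[str, int]
    total_contigs: int


def count_end_kmers(end_regions: list[EndRegion], k: int) -> KmerTable:
    """Count canonical kmers over all end regions (both strands implicitly).

    Every length-k window contributes one count to its canonical form
    (lexicographic min of the window and its reverse complement); windows
    containing N are skipped. Regions shorter than k contribute nothing.
    """
    if k < MIN_COUNT_K:
        raise ValueError(f"k must be >= {MIN_COUNT_K}, got {k}")
    counts: dict[str, int] = {}
    contigs = set()
    for region in end_regions:
        contigs.add(region.source_contig)
        seq = region.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            ck = canonical(kmer)
            counts[ck] = counts.get(ck, 0) + 1
    return KmerTable(k=k, counts=counts, total_contigs=len(contigs))


def threshold_kmers(table: KmerTable, min_fraction: float = 0.000005) -> dict[str, int]:
    """Keep kmers seen at least ``max(2, ceil(min_fraction * total_contigs))`` times.

    The default fraction (0.0005% of filtered contigs) corresponds to roughly
    ten contigs on a multi-million-contig assembly; the floor of 2 removes
    singletons on small inputs.
    """
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must be in (0, 1)")
    cutoff = max(2, math.ceil(min_fraction * table.total_contigs))
    return {kmer: n for kmer, n in table.counts.items() if n >= cutoff}


# ---------------------------------------------------------------------------
# greedy Hook assembly
# ---------------------------------------------------------------------------

def assemble_hooks(kept_kmers: dict[str, int], assembly_k: int, *, count_k: int | None = None) -> list[str]:
    """Assemble kept kmers into Hook sequences by greedy extension.

    The kept kmers are decomposed into canonical ``assembly_k``-mers whose
    counts sum over their sources. Contigs are then built greedily: seed at the
    highest-count unused assembly kmer, extend right then left, at each step
    appending the highest-count unused assembly kmer overlapping by
    ``assembly_k - 1`` (ties broken lexicographically); consumed kmers are
    removed. Contigs shorter than ``assembly_k + 2`` are discarded. Output
    sequences are reported in canonical orientation, sorted for determinism.
    """
    if count_k is not None and assembly_k >= count_k:
        raise ValueError("assembly_k must be smaller than the counting k")
    ak = assembly_k
    sub: dict[str, int] = {}
    for kmer, count in kept_kmers.items():
        for i in range(len(kmer) - ak + 1):
            ck = canonical(kmer[i : i + ak])
            sub[ck] = sub.get(ck, 0) + count
    unused = dict(sub)
    hooks: list[str] = []
    while unused:
        # highest count, lexicographically smallest on ties
        seed = min(unused, key=lambda s: (-unused[s], s))
        del unused[seed]
        contig = seed
        contig = _extend(contig, unused, ak, direction=+1)
        contig = _extend(contig, unused, ak, direction=-1)
        if len(contig) >= ak + 2:
            hooks.append(canonical(contig))
    return sorted(set(hooks))


def _extend(contig: str, unused: dict[str, int], ak: int, direction: int) -> str:
    while True:
        candidates = []
        for base in "ACGT":
            if direction > 0:
                nxt = contig[-(ak - 1) :] + base
            else:
                nxt = base + contig[: ak - 1]
            key = canonical(nxt)
            if key in unused:
                candidates.append((-unused[key], base, key))
        if not candidates:
            return contig
        _, base, key = min(candidates)
        del unused[key]
        contig = contig + base if direction > 0 else base + contig


# ---------------------------------------------------------------------------
# hit search on the unfiltered transcriptome
# ---------------------------------------------------------------------------

class PositionClass(str, Enum):
    START = "Start"
    END = "End"
    MIDDLE = "Middle"


class Orientation(str, Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class HookHit:
    hook_id: str
    contig_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str  # "+" forward, "-" reverse
    identity: float
    position_class: PositionClass


@dataclass
class Hook:
    hook_id: str
    sequence: str
    hits: list[HookHit] = field(default_factory=list)
    multi_hit_transcripts: list[str] = field(default_factory=list)
    sf: int = 0
    sr: int = 0
    ef: int = 0
    er: int = 0
    middle: int = 0
    coi: float = 0.0
    orientation_call: Orientation = Orientation.UNDETERMINED

    @property
    def total_hits(self) -> int:
        return self.sf + self.sr + self.ef + self.er + self.middle


def _best_window(hook_oriented: str, transcript: str, offset: int) -> tuple[int, int, int, int] | None:
    """Best-scoring ungapped window on one diagonal.

    Scores +1 per match, -2 per mismatch; returns (q_start, q_end, score,
    matches) for the maximum-score window, preferring the longest window and
    then the smallest start on ties, or None if no positive window exists.
    """
    h, t = len(hook_oriented), len(transcript)
    q_lo = max(0, -offset)
    q_hi = min(h, t - offset)
    n = q_hi - q_lo
    if n <= 0:
        return None
    # prefix sums of the +1/-2 score and of match counts; the best window is
    # the exact argmax of P[e]-P[s], smallest start then smallest end on ties
    P = [0] * (n + 1)
    M = [0] * (n + 1)
    for i in range(n):
        m = hook_oriented[q_lo + i] == transcript[q_lo + i + offset]
        P[i + 1] = P[i] + (1 if m else -2)
        M[i + 1] = M[i] + (1 if m else 0)
    suffmax = [0] * (n + 2)
    suffmax[n] = P[n]
    for i in range(n - 1, -1, -1):
        suffmax[i] = max(P[i], suffmax[i + 1])
    best_sum = max(suffmax[s + 1] - P[s] for s in range(n))
    if best_sum <= 0:
        return None
    # among max-score windows prefer the longest (maximal extension at no
    # score cost — and, unlike a positional preference, invariant under
    # reverse complementing the input), then the smallest start
    s_star = e_star = -1
    for s in range(n):
        if suffmax[s + 1] - P[s] != best_sum:
            continue
        for e in range(s + 1, n + 1):
            if P[e] - P[s] == best_sum and e - s > e_star - s_star:
                s_star, e_star = s, e
    return (
        q_lo + s_star,
        q_lo + e_star,
        best_sum,
        M[e_star] - M[s_star],
    )


def _seed_diagonals(hook_oriented: str, transcript: str, seed_len: int) -> set[int]:
    """Diagonals (subject_pos - query_pos) sharing at least one exact seed."""
    index: dict[str, list[int]] = {}
    for q in range(len(hook_oriented) - seed_len + 1):
        word = hook_oriented[q : q + seed_len]
        if "N" not in word:
            index.setdefault(word, []).append(q)
    diagonals: set[int] = set()
    for t in range(len(transcript) - seed_len + 1):
        word = transcript[t : t + seed_len]
        for q in index.get(word, ()):  # noqa: B905
            diagonals.add(t - q)
    return diagonals


def find_hook_hits(
    hook_id: str,
    hook: str,
    transcripts: list[Transcript],
    *,
    min_identity: float = 0.90,
    min_cov: float = 0.80,
    seed_len: int = 7,
    end_window: int = 50,
) -> tuple[list[HookHit], list[str]]:
    """Locate a Hook in the full transcriptome by seeded ungapped alignment.

    Exact ``seed_len``-mer matches (both strands) select candidate diagonals;
    on each, the best-scoring ungapped window (+1/-2) is taken. Windows with
    identity >= ``min_identity`` over a span >= ``min_cov`` x hook length
    qualify. Per transcript, at most the single best hit is reported;
    transcripts carrying two or more disjoint qualifying hits are excluded and
    returned separately (possible chimeras or short repeats).
    """
    if len(hook) < seed_len:
        raise ValueError("hook shorter than the seed length")
    hits: list[HookHit] = []
    multi: list[str] = []
    oriented = {"+": hook, "-": revcomp(hook)}
    for transcript in transcripts:
        qualifying: list[tuple[int, str, int, int, int, int, int]] = []
        for strand, hseq in oriented.items():
            for off in sorted(_seed_diagonals(hseq, transcript.sequence, seed_len)):
                win = _best_window(hseq, transcript.sequence, off)
                if win is None:
                    continue
                q_start, q_end, score, matches = win
                span = q_end - q_start
                identity = matches / span
                if span >= min_cov * len(hook) and identity >= min_identity:
                    qualifying.append(
                        (score, strand, off, q_start, q_end, q_start + off, q_end + off)
                    )
        if not qualifying:
            continue
        groups = _group_by_subject_overlap(qualifying)
        if len(groups) >= 2:
            multi.append(transcript.contig_id)
            continue
        best = min(groups[0], key=lambda w: (-w[0], w[1] != "+", w[5], w[2]))
        score, strand, off, q_start, q_end, s_start, s_end = best
        pos = classify_hit_position(s_start, s_end, transcript.length, end_window)
        span = q_end - q_start
        matches = sum(
            1
            for q in range(q_start, q_end)
            if oriented[strand][q] == transcript.sequence[q + off]
        )
        hits.append(
            HookHit(
                hook_id=hook_id,
                contig_id=transcript.contig_id,
                query_start=q_start,
                query_end=q_end,
                subject_start=s_start,
                subject_end=s_end,
                strand=strand,
                identity=matches / span,
                position_class=pos,
            )
        )
    return hits, multi


def _group_by_subject_overlap(windows: list[tuple]) -> list[list[tuple]]:
    """Group qualifying windows whose subject intervals overlap."""
    ordered = sorted(windows, key=lambda w: (w[5], w[6]))
    groups: list[list[tuple]] = []
    cur_end = None
    for w in ordered:
        if cur_end is not None and w[5] < cur_end:
            groups[-1].append(w)
            cur_end = max(cur_end, w[6])
        else:
            groups.append([w])
            cur_end = w[6]
    return groups


def classify_hit_position(
    subject_start: int, subject_end: int, transcript_length: int, end_window: int
) -> PositionClass:
    """Start/End/Middle call for a hit, by its distance to the contig termini.

    A hit inside both terminal windows (short contig) is classed by the nearer
    terminus, Start on an exact tie.
    """
    is_start = subject_start < end_window
    is_end = subject_end > transcript_length - end_window
    if is_start and is_end:
        d_start = subject_start
        d_end = transcript_length - subject_end
        return PositionClass.START if d_start <= d_end else PositionClass.END
    if is_start:
        return PositionClass.START
    if is_end:
        return PositionClass.END
    return PositionClass.MIDDLE


# ---------------------------------------------------------------------------
# coi and Best Hook selection
# ---------------------------------------------------------------------------

def compute_coi(sf: int, sr: int, ef: int, er: int, middle: int) -> float:
    """Consistency orientation index: majority valid configuration / all hits."""
    total = sf + sr + ef + er + middle
    if total == 0:
        raise ValueError("coi undefined for a hook with zero hits")
    return max(sf + er, sr + ef) / total


def tally_hits(hook: Hook) -> None:
    """Fill a Hook's orientation counters, coi and orientation call from its hits."""
    hook.sf = hook.sr = hook.ef = hook.er = hook.middle = 0
    for hit in hook.hits:
        if hit.position_class is PositionClass.MIDDLE:
            hook.middle += 1
        elif hit.position_class is PositionClass.START:
            if hit.strand == "+":
                hook.sf += 1
            else:
                hook.sr += 1
        else:
            if hit.strand == "+":
                hook.ef += 1
            else:
                hook.er += 1
    if hook.total_hits == 0:
        logger.info("hook %s has no transcriptome hits; skipped", hook.hook_id)
        hook.coi = 0.0
        hook.orientation_call = Orientation.UNDETERMINED
        return
    hook.coi = compute_coi(hook.sf, hook.sr, hook.ef, hook.er, hook.middle)
    a, b = hook.sf + hook.er, hook.sr + hook.ef
    if a > b:
        hook.orientation_call = Orientation.SENSE
    elif a < b:
        hook.orientation_call = Orientation.ANTISENSE
    else:
        hook.orientation_call = Orientation.UNDETERMINED


def occ_cutoff(hooks: list[Hook]) -> float:
    """Observation-count cutoff: median of total hit counts over all hooks."""
    return statistics.median(h.total_hits for h in hooks) if hooks else 0.0


def select_best_hooks(
    hooks: list[Hook], coi_cutoff: float = 0.95, apply_occ: bool = True
) -> tuple[list[Hook], float]:
    """Best Hooks: coi strictly above the cutoff, and hit count >= occ if applied.

    Returns the selection (sorted by descending hit count, then id) and the occ
    value computed over *all* hooks. An empty result is a valid outcome — the
    expected one for a species without spliced leaders.
    """
    occ = occ_cutoff(hooks)
    selected = [
        h
        for h in hooks
        if h.total_hits > 0 and h.coi > coi_cutoff and (not apply_occ or h.total_hits >= occ)
    ]
    selected.sort(key=lambda h: (-h.total_hits, h.hook_id))
    logger.info(
        "hooks: %d assembled, occ=%.1f, %d pass coi>%.2f%s",
        len(hooks),
        occ,
        len(selected),
        coi_cutoff,
        " + occ" if apply_occ else " (occ off)",
    )
    return selected, occ


def discover_hooks(
    end_regions: list[EndRegion],
    transcripts: list[Transcript],
    *,
    k: int = 20,
    assembly_k: int = 19,
    min_kmer_fraction: float = 0.000005,
    min_identity: float = 0.90,
    min_cov: float = 0.80,
    seed_len: int = 7,
    end_window: int = 50,
    coi_cutoff: float = 0.95,
    apply_occ: bool = True,
) -> tuple[list[Hook], list[Hook], float]:
    """Full Step1: returns (all hooks with stats, best hooks, occ)."""
    table = count_end_kmers(end_regions, k)
    kept = threshold_kmers(table, min_kmer_fraction)
    logger.info(
        "kmer table: %d canonical %d-mers over %d contigs; %d pass the count threshold",
        len(table.counts),
        k,
        table.total_contigs,
        len(kept),
    )
    sequences = assemble_hooks(kept, assembly_k, count_k=k)
    hooks: list[Hook] = []
    for i, seq in enumerate(sequences, start=1):
        hook = Hook(hook_id=f"hook-{i}", sequence=seq)
        hook.hits, hook.multi_hit_transcripts = find_hook_hits(
            hook.hook_id,
            seq,
            transcripts,
            min_identity=min_identity,
            min_cov=min_cov,
            seed_len=seed_len,
            end_window=end_window,
        )
        tally_hits(hook)
        hooks.append(hook)
    best, occ = select_best_hooks(hooks, coi_cutoff=coi_cutoff, apply_occ=apply_occ)
    return hooks, best, occ
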