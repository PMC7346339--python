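"""Step3 — map Hook Variants onto the reference genome and call pSL loci.

Each Hook Variant (read 5'->3' in SL sense) is located in the genome by exact
ungapped matching: every maximal exact match covering at least ``min_cov`` of
the variant counts as a hit, so only terminal variant bases — where sequencing
noise and imprecise trimming accumulate — may go unmatched. Overlapping hits
merge into loci; a canonical splice donor dinucleotide (GT) is sought in the 4
bases around each variant's 3' boundary; loci sitting next to a known
protein-coding sequence are discarded; and the surviving locus sequences are
clustered into putative spliced-leader (pSL) candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core_io import GenomeSequence, revcomp
from .hook_discovery import Orientation
from .variant_builder import Cluster, HookVariant, dedup_cluster

logger = logging.getLogger(__name__)

DONOR = "GT"
DONOR_WINDOW_MATCHED = 2  # matched bases included in the donor search window
DONOR_WINDOW_DOWNSTREAM = 2  # genomic bases past the 3' boundary
ANNOTATION_SEARCH_MARGIN = 100  # extra flank searched beyond the distance cutoff

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(seq: str) -> str:
    return "".join(GENETIC_CODE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3))


@dataclass(frozen=True)
class VariantHit:
    variant_id: str
    hook_id: str
    chrom: str
    start: int  # 0-based half-open genomic interval of the matched span
    end: int
    strand: str  # "+": variant matches the forward genome strand
    matched_span: int
    query_start: int  # matched interval on the variant (forward variant coords)
    query_end: int

    @property
    def three_prime_pos(self) -> int:
        """Genomic coordinate of the matched 3' boundary in SL sense.

        For a plus-strand hit the SL 3' end is at ``end`` (half-open); for a
        minus-strand hit it is at ``start``.
        """
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class DonorCall:
    variant_id: str
    donor_found: bool
    label: str  # "3prima" (plus strand) or "5prima" (minus strand), "" if none
    overlap_star: bool
    incomplete: bool = False  # window ran past the chromosome edge


@dataclass
class GenomeLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    variant_hits: list[VariantHit] = field(default_factory=list)
    donor_calls: list[DonorCall] = field(default_factory=list)
    status: str = "Undetermined"  # Clear / Unclear / NoDonor / Undetermined
    annotation_distance: int | None = None
    discarded: bool = False

    def sequence(self, genome: dict[str, str]) -> str:
        """Locus sequence in SL sense (reverse complemented for minus strand)."""
        raw = genome[self.chrom][self.start : self.end]
        return raw if self.strand == "+" else revcomp(raw)


@dataclass(frozen=True)
class PSLCandidate:
    psl_id: str
    sequence: str
    member_loci: tuple[str, ...]
    donor_class: str  # "Clear" or "Unclear"


# ---------------------------------------------------------------------------
# genome search
# ---------------------------------------------------------------------------

def map_variants_to_genome(
    variants: list[HookVariant],
    genome: list[GenomeSequence],
    min_cov: float = 0.90,
    seed_len: int = 12,
) -> list[VariantHit]:
    """All maximal exact genomic matches covering >= ``min_cov`` of a variant.

    Matching is ungapped and 100% identical inside the matched span; only
    terminal variant bases may be unmatched. Implemented by indexing genome
    seed words and extending each seed exact-match only, in both directions,
    as far as the variant allows.
    """
    import math

    index: dict[str, list[tuple[int, int]]] = {}
    for ci, chrom in enumerate(genome):
        seq = chrom.sequence
        for p in range(len(seq) - seed_len + 1):
            word = seq[p : p + seed_len]
            if "N" not in word:
                index.setdefault(word, []).append((ci, p))
    hits: set[VariantHit] = set()
    for variant in variants:
        if len(variant.sequence) < seed_len:
            raise ValueError(
                f"variant {variant.variant_id} shorter than the seed length {seed_len}"
            )
        need = math.ceil(min_cov * len(variant.sequence))
        for strand in "+-":
            vseq = variant.sequence if strand == "+" else revcomp(variant.sequence)
            for q in range(len(vseq) - seed_len + 1):
                for ci, p in index.get(vseq[q : q + seed_len], ()):  # noqa: B905
                    gseq = genome[ci].sequence
                    lo_q, lo_p = q, p
                    while lo_q > 0 and lo_p > 0 and vseq[lo_q - 1] == gseq[lo_p - 1]:
                        lo_q -= 1
                        lo_p -= 1
                    hi_q, hi_p = q + seed_len, p + seed_len
                    while hi_q < len(vseq) and hi_p < len(gseq) and vseq[hi_q] == gseq[hi_p]:
                        hi_q += 1
                        hi_p += 1
                    span = hi_q - lo_q
                    if span < need:
                        continue
                    if strand == "+":
                        q_start, q_end = lo_q, hi_q
                    else:  # map back to forward variant coordinates
                        q_start, q_end = len(vseq) - hi_q, len(vseq) - lo_q
                    hits.add(
                        VariantHit(
                            variant_id=variant.variant_id,
                            hook_id=variant.hook_id,
                            chrom=genome[ci].chrom_id,
                            start=lo_p,
                            end=hi_p,
                            strand=strand,
                            matched_span=span,
                            query_start=q_start,
                            query_end=q_end,
                        )
                    )
    return sorted(hits, key=lambda h: (h.chrom, h.start, h.end, h.strand, h.variant_id))


def group_hits_into_loci(hits: list[VariantHit], merge_gap: int = 5) -> list[GenomeLocus]:
    """Merge same-chromosome, same-strand hits overlapping or within ``merge_gap`` bp."""
    loci: list[GenomeLocus] = []
    by_key: dict[tuple[str, str], list[VariantHit]] = {}
    for h in hits:
        by_key.setdefault((h.chrom, h.strand), []).append(h)
    raw: list[tuple[str, str, int, int, list[VariantHit]]] = []
    for (chrom, strand), group in by_key.items():
        group.sort(key=lambda h: (h.start, h.end))
        cur: list[VariantHit] = []
        cur_start = cur_end = 0
        for h in group:
            if cur and h.start <= cur_end + merge_gap:
                cur.append(h)
                cur_end = max(cur_end, h.end)
            else:
                if cur:
                    raw.append((chrom, strand, cur_start, cur_end, cur))
                cur = [h]
                cur_start, cur_end = h.start, h.end
        if cur:
            raw.append((chrom, strand, cur_start, cur_end, cur))
    raw.sort(key=lambda r: (r[0], r[2], r[3], r[1]))
    for i, (chrom, strand, start, end, group) in enumerate(raw, start=1):
        loci.append(
            GenomeLocus(
                locus_id=f"Locus-{i}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                variant_hits=group,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# donor sites and locus status
# ---------------------------------------------------------------------------

def detect_donor_site(hit: VariantHit, genome: dict[str, str]) -> DonorCall:
    """Look for a splice donor GT in the 4 bp around a hit's 3' boundary.

    The window is the last two *matched* bases plus the two genomic bases
    immediately downstream of the 3' boundary, read in SL sense on the hit
    strand. A GT at any of the three dinucleotide offsets counts as a donor;
    one starting at or before the last matched base (the variant itself ends
    in "G" or "GT") raises the overlap star, advising manual inspection. A
    window running past the chromosome edge yields no donor and an
    "incomplete" flag (missing information in the reference genome).
    """
    seq = genome[hit.chrom]
    label = "3prima" if hit.strand == "+" else "5prima"
    if hit.strand == "+":
        lo = hit.end - DONOR_WINDOW_MATCHED
        hi = hit.end + DONOR_WINDOW_DOWNSTREAM
        if hi > len(seq):
            return DonorCall(hit.variant_id, False, "", False, incomplete=True)
        window = seq[lo:hi]
    else:
        lo = hit.start - DONOR_WINDOW_DOWNSTREAM
        hi = hit.start + DONOR_WINDOW_MATCHED
        if lo < 0:
            return DonorCall(hit.variant_id, False, "", False, incomplete=True)
        window = revcomp(seq[lo:hi])
    offsets = [k for k in range(len(window) - 1) if window[k : k + 2] == DONOR]
    if not offsets:
        return DonorCall(hit.variant_id, False, "", False)
    star = any(k <= DONOR_WINDOW_MATCHED - 1 for k in offsets)
    return DonorCall(hit.variant_id, True, label, star)


def call_locus_status(
    locus: GenomeLocus,
    genome: dict[str, str],
    hook_orientations: dict[str, Orientation],
    clear_fraction: float = 0.80,
) -> None:
    """Fill a locus's donor calls and Clear/Unclear/NoDonor/Undetermined status.

    Donor presence is aggregated per distinct variant (a variant counts as
    donor-bearing if any of its hits in the locus shows a donor). A locus whose
    supporting hooks all have undetermined orientation is Undetermined and its
    donor analysis is skipped — without an orientation the 3' end is unknown.
    """
    hooks = {h.hook_id for h in locus.variant_hits}
    if hooks and all(
        hook_orientations.get(h, Orientation.UNDETERMINED) is Orientation.UNDETERMINED
        for h in hooks
    ):
        locus.status = "Undetermined"
        locus.donor_calls = []
        return
    calls = [detect_donor_site(h, genome) for h in locus.variant_hits]
    locus.donor_calls = calls
    per_variant: dict[str, bool] = {}
    for call in calls:
        per_variant[call.variant_id] = per_variant.get(call.variant_id, False) or call.donor_found
    n_with = sum(1 for v in per_variant.values() if v)
    if n_with == 0:
        locus.status = "NoDonor"
    elif n_with / len(per_variant) >= clear_fraction:
        locus.status = "Clear"
    else:
        locus.status = "Unclear"


# ---------------------------------------------------------------------------
# annotation-proximity filter
# ---------------------------------------------------------------------------

def _diagonal_matches(
    query: str, subject: str, seed_len: int, min_span: int, min_identity: float
) -> list[tuple[int, int]]:
    """Qualifying ungapped matches of query in subject: (subject_start, subject_end).

    Same contract as the hook hit search: exact seeds select diagonals, the
    best-scoring (+1/-2) window on each diagonal is kept if it is long and
    identical enough.
    """
    from .hook_discovery import _best_window, _seed_diagonals

    out = []
    for off in sorted(_seed_diagonals(query, subject, seed_len)):
        win = _best_window(query, subject, off)
        if win is None:
            continue
        q_start, q_end, _, matches = win
        span = q_end - q_start
        if span >= min_span and matches / span >= min_identity:
            out.append((q_start + off, q_end + off))
    return out


def annotation_matches(
    region: str,
    reference: list[tuple[str, str]],
    mode: str = "nucleotide",
) -> list[tuple[int, int]]:
    """Subject intervals of ``region`` matching any reference record.

    nucleotide mode: seeded ungapped search (seed 11) requiring >= 30 aligned
    bases at >= 80% identity. protein mode: the region is six-frame translated
    and searched with exact 8-residue peptide seeds extended to >= 20 aligned
    residues at >= 50% identity; intervals are reported in nucleotide
    coordinates of the region.
    """
    out: list[tuple[int, int]] = []
    if mode == "nucleotide":
        for _, ref_seq in reference:
            for q_start, q_end in _diagonal_matches(ref_seq, region, 11, 30, 0.8):
                out.append((q_start, q_end))
        return out
    if mode != "protein":
        raise ValueError(f"unknown annotation mode {mode!r}")
    frames = []
    for strand_seq, is_rc in ((region, False), (revcomp(region), True)):
        for shift in range(3):
            frames.append((translate(strand_seq[shift:]), shift, is_rc))
    for _, ref_pep in reference:
        for pep, shift, is_rc in frames:
            for p_start, p_end in _diagonal_matches(ref_pep, pep, 8, 20, 0.5):
                nt_start = shift + 3 * p_start
                nt_end = shift + 3 * p_end
                if is_rc:
                    nt_start, nt_end = len(region) - nt_end, len(region) - nt_start
                out.append((nt_start, nt_end))
    return out


def annotate_and_filter(
    loci: list[GenomeLocus],
    genome: dict[str, str],
    reference: list[tuple[str, str]],
    distance_bp: int = 100,
    mode: str = "nucleotide",
) -> None:
    """Discard loci with a reference (cDNA/protein) match within ``distance_bp``.

    The flank searched extends ``distance_bp`` plus a fixed margin beyond the
    locus so that a qualifying match sitting exactly at the cutoff is still
    findable; the recorded annotation distance is the gap between the locus
    interval and the nearest match (0 when they overlap), and a locus is
    discarded when that distance is <= ``distance_bp`` (inclusive).
    """
    if not reference:
        logger.warning("empty annotation reference; all loci retained")
        for locus in loci:
            locus.annotation_distance = None
            locus.discarded = False
        return
    reach = distance_bp + ANNOTATION_SEARCH_MARGIN
    for locus in loci:
        chrom_seq = genome[locus.chrom]
        flank_lo = max(0, locus.start - reach)
        flank_hi = min(len(chrom_seq), locus.end + reach)
        region = chrom_seq[flank_lo:flank_hi]
        best: int | None = None
        for m_start, m_end in annotation_matches(region, reference, mode):
            g_start, g_end = flank_lo + m_start, flank_lo + m_end
            if g_end <= locus.start:
                gap = locus.start - g_end
            elif g_start >= locus.end:
                gap = g_start - locus.end
            else:
                gap = 0
            if best is None or gap < best:
                best = gap
        locus.annotation_distance = best
        locus.discarded = best is not None and best <= distance_bp


# ---------------------------------------------------------------------------
# pSL clustering and reporting
# ---------------------------------------------------------------------------

def cluster_psl(loci: list[GenomeLocus], genome: dict[str, str]) -> list[PSLCandidate]:
    """Cluster surviving locus sequences (SL sense) into pSL candidates.

    Clear and Unclear pools are clustered separately at 100% identity by
    containment; ids are assigned by descending member count (pSL-n for Clear,
    UnpSL-n for Unclear). Discarded and NoDonor/Undetermined loci never enter.
    """
    candidates: list[PSLCandidate] = []
    for donor_class, prefix in (("Clear", "pSL"), ("Unclear", "UnpSL")):
        pool = [l for l in loci if not l.discarded and l.status == donor_class]
        if not pool:
            continue
        clusters: list[Cluster] = dedup_cluster(
            [(l.locus_id, l.sequence(genome)) for l in pool]
        )
        ordered = sorted(clusters, key=lambda c: (-c.support, c.representative))
        for i, c in enumerate(ordered, start=1):
            candidates.append(
                PSLCandidate(
                    psl_id=f"{prefix}-{i}",
                    sequence=c.representative,
                    member_loci=c.members,
                    donor_class=donor_class,
                )
            )
    return candidates


def run_step3(
    variants: list[HookVariant],
    genome: list[GenomeSequence],
    reference: list[tuple[str, str]],
    hook_orientations: dict[str, Orientation],
    *,
    min_cov: float = 0.90,
    clear_fraction: float = 0.80,
    distance_bp: int = 100,
    mode: str = "nucleotide",
    merge_gap: int = 5,
) -> tuple[list[GenomeLocus], list[PSLCandidate]]:
    """Full Step3: genome search, donor analysis, annotation filter, clustering."""
    genome_map = {g.chrom_id: g.sequence for g in genome}
    usable = [v for v in variants if len(v.sequence) >= 12]
    if len(usable) < len(variants):
        logger.warning(
            "%d variants shorter than the genome seed word were skipped",
            len(variants) - len(usable),
        )
    hits = map_variants_to_genome(usable, genome, min_cov=min_cov)
    loci = group_hits_into_loci(hits, merge_gap=merge_gap)
    for locus in loci:
        call_locus_status(locus, genome_map, hook_orientations, clear_fraction)
    annotate_and_filter(loci, genome_map, reference, distance_bp, mode)
    psl = cluster_psl(loci, genome_map)
    logger.info(
        "step3: %d variant hits, %d loci (%d Clear, %d Unclear, %d NoDonor, "
        "%d Undetermined, %d discarded), %d pSL candidates",
        len(hits),
        len(loci),
        sum(1 for l in loci if l.status == "Clear"),
        sum(1 for l in loci if l.status == "Unclear"),
        sum(1 for l in loci if l.status == "NoDonor"),
        sum(1 for l in loci if l.status == "Undetermined"),
        sum(1 for l in loci if l.discarded),
        len(psl),
    )
    return loci, psl
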