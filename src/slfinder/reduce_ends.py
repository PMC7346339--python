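"""Step0 — collapse assembly redundancy and extract transcript terminal regions.

A de novo transcriptome assembly carries heavy redundancy: one gene is
represented by several isoform contigs. Keeping only the longest isoform per
gene, then cutting out both terminal regions of each retained contig, yields a
reduced sequence set in which a spliced leader — present on the transcripts of
many genes — becomes one of the most over-represented subsequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .core_io import Transcript


class WhichEnd(str, Enum):
    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"


@dataclass(frozen=True)
class EndRegion:
    source_contig: str
    which_end: WhichEnd
    sequence: str
    region_length: int

    @property
    def fasta_id(self) -> str:
        return f"{self.source_contig}|{self.which_end.value}"


def select_longest_isoforms(transcripts: list[Transcript]) -> list[Transcript]:
    """Keep exactly one transcript per gene: the longest isoform.

    Equal-length ties go to the lexicographically smaller isoform id so the
    result is independent of input order.
    """
    best: dict[str, Transcript] = {}
    order: list[str] = []
    for t in transcripts:
        cur = best.get(t.gene_id)
        if cur is None:
            best[t.gene_id] = t
            order.append(t.gene_id)
        elif t.length > cur.length or (
            t.length == cur.length and _iso_sort_key(t.isoform_id) < _iso_sort_key(cur.isoform_id)
        ):
            best[t.gene_id] = t
    return [best[g] for g in sorted(order)]


def _iso_sort_key(isoform_id: str) -> tuple:
    # i10 must sort after i2: numeric ordering when the tag is i<int>
    if isoform_id.startswith("i") and isoform_id[1:].isdigit():
        return (0, int(isoform_id[1:]), isoform_id)
    return (1, 0, isoform_id)


def extract_end_regions(transcript: Transcript, region_length: int) -> tuple[EndRegion, EndRegion]:
    """Return the (5′, 3′) terminal regions of a contig.

    For contigs shorter than ``region_length`` both regions are the whole
    contig.
    """
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    seq = transcript.sequence
    five = seq[:region_length]
    three = seq[-region_length:] if len(seq) >= region_length else seq
    return (
        EndRegion(transcript.contig_id, WhichEnd.FIVE_PRIME, five, region_length),
        EndRegion(transcript.contig_id, WhichEnd.THREE_PRIME, three, region_length),
    )


def reduce_assembly(transcripts: list[Transcript], region_length: int) -> tuple[list[Transcript], list[EndRegion]]:
    """Longest-isoform selection followed by end extraction (Step0)."""
    retained = select_longest_isoforms(transcripts)
    regions: list[EndRegion] = []
    for t in retained:
        regions.extend(extract_end_regions(t, region_length))
    return retained, regions
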