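"""Sequence and table I/O, identifier parsing, and elementary sequence algebra.

All coordinates inside the package are 0-based half-open; conversion to the
1-based inclusive convention happens only when GFF3/TSV files are emitted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Trinity contig naming: <prefix>_c<int>_g<int>_i<int>; the gene identifier is
# everything up to and including _g<int>, the isoform tag is the trailing i<int>.
_TRINITY_RE = re.compile(r"^(?P<gene>.+_c\d+_g\d+)_(?P<iso>i\d+)$")


class FastaParseError(ValueError):
    """Malformed FASTA input (empty id/sequence or illegal characters)."""


@dataclass(frozen=True)
class Transcript:
    """An assembled contig with its parsed gene/isoform identity."""

    contig_id: str
    gene_id: str
    isoform_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.contig_id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeSequence:
    chrom_id: str
    sequence: str


def normalize_sequence(raw: str, *, line_no: int | None = None, record_id: str = "") -> str:
    """Uppercase, convert U to T, and reject characters outside {A,C,G,T,N}."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        where = f" at line {line_no}" if line_no is not None else ""
        raise FastaParseError(
            f"record {record_id!r}{where}: illegal characters {sorted(bad)!r} "
            "(alphabet is A/C/G/T/N, case-insensitive, U tolerated)"
        )
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased, U is converted to T, and any character outside
    {A,C,G,T,N} raises :class:`FastaParseError` naming the offending line.
    Empty ids or empty records are also parse errors.
    """
    records: list[tuple[str, str]] = []
    current_id: str | None = None
    current_parts: list[str] = []
    header_line = 0

    def flush() -> None:
        if current_id is None:
            return
        if not current_parts:
            raise FastaParseError(
                f"record {current_id!r} at line {header_line} has no sequence"
            )
        records.append((current_id, "".join(current_parts)))

    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if len(line) > 1 and line[1:].strip() else ""
                if not current_id:
                    raise FastaParseError(f"empty record id at line {line_no}")
                header_line = line_no
                current_parts = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"sequence data before any FASTA header at line {line_no}"
                    )
                current_parts.append(
                    normalize_sequence(line, line_no=line_no, record_id=current_id)
                )
    flush()
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def parse_trinity_id(contig_id: str) -> tuple[str, str]:
    """Split a Trinity-style contig id into (gene_id, isoform_id).

    Ids not matching the ``<prefix>_c<int>_g<int>_i<int>`` convention degrade
    gracefully: the whole id becomes the gene id, the isoform is "i1", and the
    event is logged so alternative grouping strategies can be considered.
    """
    m = _TRINITY_RE.match(contig_id)
    if m:
        return m.group("gene"), m.group("iso")
    logger.debug("contig id %r does not follow the Trinity convention; treated as its own gene", contig_id)
    return contig_id, "i1"


def make_transcript(contig_id: str, sequence: str) -> Transcript:
    gene_id, isoform_id = parse_trinity_id(contig_id)
    return Transcript(contig_id=contig_id, gene_id=gene_id, isoform_id=isoform_id, sequence=sequence)


def read_transcripts(path: str | Path, *, namespace: str | None = None) -> list[Transcript]:
    """Read an assembly FASTA into Transcripts, optionally namespacing contig ids.

    Namespacing (``<namespace>::<contig_id>``) keeps contig ids unique when
    several independent assemblies of one species are pooled.
    """
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec_id, seq in read_fasta(path):
        gene_id, isoform_id = parse_trinity_id(rec_id)
        contig_id = rec_id if namespace is None else f"{namespace}::{rec_id}"
        if namespace is not None:
            gene_id = f"{namespace}::{gene_id}"
        if contig_id in seen:
            raise FastaParseError(f"duplicate contig id {contig_id!r} in {path}")
        seen.add(contig_id)
        out.append(Transcript(contig_id, gene_id, isoform_id, seq))
    return out


def read_genome(path: str | Path) -> list[GenomeSequence]:
    genome = [GenomeSequence(rec_id, seq) for rec_id, seq in read_fasta(path)]
    ids = [g.chrom_id for g in genome]
    if len(set(ids)) != len(ids):
        raise FastaParseError(f"duplicate chromosome ids in {path}")
    return genome


def revcomp(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, N maps to N."""
    return sequence.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a kmer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            if len(row) != len(header):
                raise ValueError(f"row has {len(row)} fields, header has {len(header)}")
            handle.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path) as handle:
        lines = [line.rstrip("\n") for line in handle if line.strip()]
    if not lines:
        return [], []
    header = lines[0].split("\t")
    return header, [line.split("\t") for line in lines[1:]]


@dataclass(frozen=True)
class Gff3Feature:
    """One GFF3 feature; start/end are internal 0-based half-open coordinates."""

    seqid: str
    source: str
    ftype: str
    start: int  # 0-based inclusive
    end: int  # half-open
    score: str
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff3(path: str | Path, features: Iterable[Gff3Feature]) -> None:
    """Write features as GFF3 (1-based inclusive coordinates on output)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            handle.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        f.score,
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
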