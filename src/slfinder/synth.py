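"""Synthetic genomes, transcriptomes and references with planted spliced leaders.

The generator emulates what the pipeline actually consumes: Trinity-style
multi-isoform contig FASTA in which a configurable fraction of transcripts
carries a planted SL exon at the 5' end (behind random low-quality leading
bases, with 5' truncation, substitution errors and random sense/antisense
strand), a genome containing tandem SL-RNA loci (exon + GT donor + intron)
and protein-coding loci, and a matching cDNA/protein reference. Ground truth
(planted exons, locus coordinates, per-contig SL carriage) is recorded so
recovery can be scored exactly.

Everything is driven by ``random.Random(seed)`` and is byte-identical across
runs and platforms for a fixed seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .core_io import GenomeSequence, Transcript, revcomp
from .locus_mapper import translate

BASES = "ACGT"
INTRON_LEN = 60
ARRAY_SPACER = 200
PAD = 1000
GENE_SPACER_MIN, GENE_SPACER_MAX = 10, 20
GENE_CODONS = 75
UTR5_LEN = 30
UTR3_LEN = 45
# gene segment = 30 UTR + ATG + 75 codons + stop + 45 UTR = 306 bp

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SLClass:
    sl_id: str
    exon: str
    prevalence: float


@dataclass
class SyntheticTruth:
    sl_classes: list[SLClass] = field(default_factory=list)
    sl_loci: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    # (chrom, exon_start, exon_end, strand, sl_id)
    gene_loci: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    # (chrom, start, end, strand, cDNA)
    mutated_donor_loci: list[int] = field(default_factory=list)  # indices into sl_loci
    contig_sl: dict[str, str | None] = field(default_factory=dict)
    contig_strand: dict[str, str] = field(default_factory=dict)
    params_used: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sl_classes": [[c.sl_id, c.exon, c.prevalence] for c in self.sl_classes],
                "sl_loci": self.sl_loci,
                "gene_loci": self.gene_loci,
                "mutated_donor_loci": self.mutated_donor_loci,
                "contig_sl": self.contig_sl,
                "contig_strand": self.contig_strand,
                "params_used": self.params_used,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        data = json.loads(text)
        return cls(
            sl_classes=[SLClass(*row) for row in data["sl_classes"]],
            sl_loci=[tuple(row) for row in data["sl_loci"]],
            gene_loci=[tuple(row) for row in data["gene_loci"]],
            mutated_donor_loci=list(data["mutated_donor_loci"]),
            contig_sl=dict(data["contig_sl"]),
            contig_strand=dict(data["contig_strand"]),
            params_used=dict(data["params_used"]),
        )


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(BASES[rng.randrange(4)] for _ in range(n))


def _random_cdna(rng: random.Random, n_codons: int = GENE_CODONS) -> str:
    """A gene segment: random 5'UTR + intact ORF + random 3'UTR.

    The per-gene random UTRs matter: they are what keeps kmers spanning the
    SL/mRNA junction private to one gene, exactly as real 5' ends do.
    """
    codons = []
    while len(codons) < n_codons:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    return (
        _random_seq(rng, UTR5_LEN) + "ATG" + "".join(codons) + "TAA" + _random_seq(rng, UTR3_LEN)
    )


def generate_genome(
    seed: int,
    *,
    n_chroms: int = 1,
    chrom_len: int = 100_000,
    sl_classes: list[SLClass] | None = None,
    copies_per_class: int = 8,
    n_genes: int = 300,
    gene_near_sl: int | None = None,
    mutate_donor_copies: tuple[int, ...] = (),
    n_repeat_families: int = 12,
    repeat_len: int = 60,
    repeat_prevalence: float = 0.25,
    gene_spacer: tuple[int, int] = (GENE_SPACER_MIN, GENE_SPACER_MAX),
) -> tuple[list[GenomeSequence], SyntheticTruth]:
    """Random genome with planted tandem SL-RNA arrays and protein-coding loci.

    Each SL class is planted as ``copies_per_class`` tandem copies of
    exon + GT + intron (the intron fixed within a class, as in a tandem
    repeat), separated by random spacers; genes are random ORF-bearing
    segments planted at least a kilobase away from any SL array.

    Real transcriptomes carry repeated sequences besides any SL (rRNA
    fragments, transposable elements, shared motifs); these are what the coi
    and occ filters exist to reject. Each of ``n_repeat_families`` repeat
    families is a fixed random segment inserted into a ``repeat_prevalence``
    fraction of gene bodies at a random position and strand.

    ``gene_near_sl`` plants one extra gene cDNA exactly that many bases after
    the last SL exon, for annotation-filter tests. ``mutate_donor_copies``
    replaces the donor GT by CC at the given copy indices of the first class.
    """
    sl_classes = list(sl_classes or [])
    rng = random.Random(seed)
    truth = SyntheticTruth(sl_classes=sl_classes)
    truth.params_used = {
        "seed": seed,
        "n_chroms": n_chroms,
        "chrom_len": chrom_len,
        "copies_per_class": copies_per_class,
        "n_genes": n_genes,
        "gene_near_sl": gene_near_sl,
        "mutate_donor_copies": list(mutate_donor_copies),
        "n_repeat_families": n_repeat_families,
        "repeat_len": repeat_len,
        "repeat_prevalence": repeat_prevalence,
    }
    repeats = [_random_seq(rng, repeat_len) for _ in range(n_repeat_families)]
    truth.params_used["repeat_families"] = repeats

    orf_end = UTR5_LEN + 3 * (GENE_CODONS + 2)

    def with_repeats(cdna: str) -> str:
        # repeats land in the 3' UTR so reading frames stay intact
        for rep in repeats:
            if rng.random() < repeat_prevalence:
                ins = rep if rng.random() < 0.5 else revcomp(rep)
                pos = rng.randint(orf_end + 2, max(orf_end + 2, len(cdna) - 5))
                cdna = cdna[:pos] + ins + cdna[pos:]
        return cdna
    genome: list[GenomeSequence] = []
    chrom_id = "chr1"
    parts: list[str] = []
    pos = 0

    def emit(seq: str) -> int:
        nonlocal pos
        parts.append(seq)
        start = pos
        pos += len(seq)
        return start

    if gene_near_sl is not None:
        if not sl_classes:
            raise ValueError("gene_near_sl requires at least one SL class")
        if gene_near_sl < 2:
            raise ValueError("gene_near_sl must be >= 2 (the donor GT sits at distance 0-1)")
    emit(_random_seq(rng, PAD))
    copy_index = 0
    for class_i, sl in enumerate(sl_classes):
        intron = _random_seq(rng, INTRON_LEN)
        for copy in range(copies_per_class):
            exon_start = emit(sl.exon)
            truth.sl_loci.append((chrom_id, exon_start, exon_start + len(sl.exon), "+", sl.sl_id))
            donor = "GT"
            if class_i == 0 and copy in mutate_donor_copies:
                donor = "CC"
                truth.mutated_donor_loci.append(copy_index)
            emit(donor)
            is_target = (
                gene_near_sl is not None
                and class_i == len(sl_classes) - 1
                and copy == copies_per_class - 1
            )
            if is_target:
                # the planted cDNA starts exactly gene_near_sl bases after the
                # exon end, taking the place of this copy's intron
                emit(_random_seq(rng, gene_near_sl - len(donor)))
                cdna = with_repeats(_random_cdna(rng))
                start = emit(cdna)
                truth.gene_loci.append((chrom_id, start, start + len(cdna), "+", cdna))
            else:
                emit(intron)
            emit(_random_seq(rng, ARRAY_SPACER))
            copy_index += 1
    emit(_random_seq(rng, PAD))
    for _ in range(n_genes):
        cdna = with_repeats(_random_cdna(rng))
        start = emit(cdna)
        truth.gene_loci.append((chrom_id, start, start + len(cdna), "+", cdna))
        emit(_random_seq(rng, rng.randint(*gene_spacer)))
    if pos > chrom_len:
        raise ValueError(
            f"requested content ({pos} bp) exceeds chrom_len ({chrom_len} bp)"
        )
    emit(_random_seq(rng, chrom_len - pos))
    genome.append(GenomeSequence(chrom_id, "".join(parts)))
    for extra in range(2, n_chroms + 1):
        genome.append(GenomeSequence(f"chr{extra}", _random_seq(rng, chrom_len)))
    return genome, truth


def generate_transcriptome(
    truth: SyntheticTruth,
    seed: int,
    *,
    n_genes_expressed: int | None = None,
    isoforms_per_gene: int = 2,
    junk_5p_max: int = 8,
    trunc_5p_max: int = 10,
    sub_rate: float = 0.005,
    antisense_fraction: float = 0.5,
) -> list[Transcript]:
    """Trinity-style contigs expressed from the planted genes.

    Per contig, an SL class is attached with its prevalence: the contig is
    prefixed by random leading junk (0..junk_5p_max bases, emulating the
    low-quality sequence that precedes SLs in real assemblies) plus the exon
    truncated at its 5' end by 0..trunc_5p_max bases. Substitution errors are
    applied at ``sub_rate`` and the whole contig is reverse-complemented with
    probability ``antisense_fraction``. Carriage and strand are recorded in
    the truth object.
    """
    rng = random.Random(seed)
    genes = truth.gene_loci
    if n_genes_expressed is None:
        n_genes_expressed = len(genes)
    n_genes_expressed = min(n_genes_expressed, len(genes))
    cum: list[tuple[float, SLClass]] = []
    acc = 0.0
    for sl in truth.sl_classes:
        acc += sl.prevalence
        cum.append((acc, sl))
    if acc > 1.0 + 1e-9:
        raise ValueError("SL class prevalences sum above 1")
    transcripts: list[Transcript] = []
    for g in range(1, n_genes_expressed + 1):
        cdna = genes[g - 1][4]
        n_iso = rng.randint(1, isoforms_per_gene)
        for j in range(1, n_iso + 1):
            body = cdna
            if j > 1:  # shorter 3'-truncated isoform
                keep = rng.randint(int(len(cdna) * 0.6), len(cdna) - 1)
                body = cdna[:keep]
            u = rng.random()
            sl_attached: SLClass | None = None
            for edge, sl in cum:
                if u < edge:
                    sl_attached = sl
                    break
            if sl_attached is not None:
                trunc = rng.randint(0, min(trunc_5p_max, len(sl_attached.exon) - 1))
                junk = _random_seq(rng, rng.randint(0, junk_5p_max))
                body = junk + sl_attached.exon[trunc:] + body
            if sub_rate > 0:
                chars = list(body)
                for i, c in enumerate(chars):
                    if rng.random() < sub_rate:
                        chars[i] = rng.choice([b for b in BASES if b != c])
                body = "".join(chars)
            strand = "-" if rng.random() < antisense_fraction else "+"
            if strand == "-":
                body = revcomp(body)
            contig_id = f"TRINITY_DN{g}_c0_g{g}_i{j}"
            transcripts.append(
                Transcript(
                    contig_id=contig_id,
                    gene_id=f"TRINITY_DN{g}_c0_g{g}",
                    isoform_id=f"i{j}",
                    sequence=body,
                )
            )
            truth.contig_sl[contig_id] = sl_attached.sl_id if sl_attached else None
            truth.contig_strand[contig_id] = strand
    return transcripts


def generate_reference(
    truth: SyntheticTruth, *, include_sl: bool = False, mode: str = "nucleotide"
) -> list[tuple[str, str]]:
    """cDNA (or translated protein) reference matching the planted genes.

    Never contains SL exon sequence unless ``include_sl`` is set (a stress
    test: the annotation filter should then discard the SL loci themselves).
    """
    out: list[tuple[str, str]] = []
    orf_span = 3 * (GENE_CODONS + 2)
    for i, (_, _, _, _, cdna) in enumerate(truth.gene_loci, start=1):
        if mode == "protein":
            orf = cdna[UTR5_LEN : UTR5_LEN + orf_span]
            out.append((f"gene{i}", translate(orf).rstrip("*")))
        else:
            out.append((f"gene{i}", cdna))
    if include_sl:
        for sl in truth.sl_classes:
            if mode == "protein":
                out.append((sl.sl_id, translate(sl.exon)))
            else:
                out.append((sl.sl_id, sl.exon))
    return out


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

LONG_SL_EXON = "CTAGCGTTACCGATTAGCAAGCTTAGGACCTTACAA"  # 36 bp
SHORT_SL_EXON = "CGTTACGGATCCTACA"  # 16 bp
MULTI_SL_SHARED_3P = "GATCCATTGCAA"  # 12 bp common 3' terminus
MULTI_SL_EXON_A = "CTTGACCGTAAGCC" + MULTI_SL_SHARED_3P  # 26 bp
MULTI_SL_EXON_B = "AGCATGCTTCGATT" + MULTI_SL_SHARED_3P  # 26 bp


@dataclass(frozen=True)
class Scenario:
    name: str
    sl_classes: tuple[SLClass, ...]
    n_genes: int
    copies_per_class: int
    chrom_len: int
    trunc_5p_max: int
    junk_5p_max: int = 8
    sub_rate: float = 0.005
    antisense_fraction: float = 0.5
    isoforms_per_gene: int = 2
    # a few pervasive elements (rRNA-like contamination) rather than many
    # rare ones: their hooks exercise the coi filter in every scenario
    n_repeat_families: int = 3
    repeat_len: int = 60
    repeat_prevalence: float = 0.5
    gene_spacer: tuple[int, int] = (10, 20)


SCENARIOS: dict[str, Scenario] = {
    # the negative control is pinned to 300 genes in a 100-kb genome, which
    # leaves room only for a light repeat background
    "no-sl": Scenario(
        name="no-sl",
        sl_classes=(),
        n_genes=300,
        copies_per_class=0,
        chrom_len=100_000,
        trunc_5p_max=0,
        n_repeat_families=2,
        repeat_len=25,
        repeat_prevalence=0.15,
        gene_spacer=(3, 6),
    ),
    "one-long-sl": Scenario(
        name="one-long-sl",
        sl_classes=(SLClass("SL-long", LONG_SL_EXON, 0.4),),
        n_genes=220,
        copies_per_class=8,
        chrom_len=130_000,
        trunc_5p_max=10,
    ),
    "one-short-sl": Scenario(
        name="one-short-sl",
        sl_classes=(SLClass("SL-short", SHORT_SL_EXON, 0.4),),
        n_genes=220,
        copies_per_class=8,
        chrom_len=130_000,
        trunc_5p_max=0,
    ),
    "multi-sl": Scenario(
        name="multi-sl",
        sl_classes=(
            SLClass("SL-A", MULTI_SL_EXON_A, 0.3),
            SLClass("SL-B", MULTI_SL_EXON_B, 0.3),
        ),
        n_genes=220,
        copies_per_class=6,
        chrom_len=130_000,
        trunc_5p_max=6,
    ),
}


def generate_scenario(
    name: str,
    seed: int,
    *,
    gene_near_sl: int | None = None,
    mutate_donor_copies: tuple[int, ...] = (),
) -> tuple[list[GenomeSequence], list[Transcript], list[tuple[str, str]], SyntheticTruth]:
    """Generate (genome, transcripts, reference, truth) for a named scenario."""
    sc = SCENARIOS[name]
    genome, truth = generate_genome(
        seed,
        chrom_len=sc.chrom_len,
        sl_classes=list(sc.sl_classes),
        copies_per_class=sc.copies_per_class,
        n_genes=sc.n_genes,
        gene_near_sl=gene_near_sl,
        mutate_donor_copies=mutate_donor_copies,
        n_repeat_families=sc.n_repeat_families,
        repeat_len=sc.repeat_len,
        repeat_prevalence=sc.repeat_prevalence,
        gene_spacer=sc.gene_spacer,
    )
    transcripts = generate_transcriptome(
        truth,
        seed + 1,
        isoforms_per_gene=sc.isoforms_per_gene,
        junk_5p_max=sc.junk_5p_max,
        trunc_5p_max=sc.trunc_5p_max,
        sub_rate=sc.sub_rate,
        antisense_fraction=sc.antisense_fraction,
    )
    reference = generate_reference(truth)
    truth.params_used["scenario"] = name
    return genome, transcripts, reference, truth


def write_scenario(outdir: str | Path, name: str, seed: int, **kwargs) -> SyntheticTruth:
    from .core_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, transcripts, reference, truth = generate_scenario(name, seed, **kwargs)
    write_fasta(outdir / "genome.fa", [(g.chrom_id, g.sequence) for g in genome])
    write_fasta(outdir / "transcripts.fa", [(t.contig_id, t.sequence) for t in transcripts])
    write_fasta(outdir / "reference.fa", reference)
    (outdir / "truth.json").write_text(truth.to_json())
    return truth
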