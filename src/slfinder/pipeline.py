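"""Pipeline orchestration: configuration, per-step entry points, validation.

The pipeline is split into four re-runnable steps so a user can intervene
between them (inspect hooks, re-trim alignments, adjust parameters). Each
step writes its outputs plus a manifest (hashes of its inputs and of the
effective configuration); a downstream step refuses to consume outputs
produced under a different configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import core_io, hook_discovery, locus_mapper, variant_builder
from .core_io import (
    Gff3Feature,
    Transcript,
    read_fasta,
    read_transcripts,
    read_tsv,
    write_fasta,
    write_gff3,
    write_tsv,
)
from .hook_discovery import Hook, HookHit, Orientation, PositionClass
from .reduce_ends import reduce_assembly
from .synth import SyntheticTruth
from .variant_builder import HookVariant, PFM_SYMBOLS, align_progressive

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its default."""

    end_length: int = 50
    k: int = 20
    assembly_k: int = 19
    min_kmer_fraction: float = 0.000005
    coi_cutoff: float = 0.95
    apply_occ: bool = True
    min_identity: float = 0.90
    min_cov: float = 0.80
    seed_len: int = 7
    variant_identity: float = 1.0
    gap_fraction: float = 0.1
    min_block: int = 5
    genome_min_cov: float = 0.90
    clear_fraction: float = 0.80
    annotation_distance: int = 100
    annotation_mode: str = "nucleotide"

    def __post_init__(self) -> None:
        for name in (
            "min_kmer_fraction",
            "coi_cutoff",
            "min_identity",
            "min_cov",
            "variant_identity",
            "gap_fraction",
            "genome_min_cov",
            "clear_fraction",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.assembly_k >= self.k:
            raise ValueError("assembly_k must be smaller than k")

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name}={getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            t = types[key]
            if t == "int":
                kwargs[key] = int(value)
            elif t == "float":
                kwargs[key] = float(value)
            elif t == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, config: PipelineConfig, inputs: dict[str, Path]) -> None:
    manifest = {
        "config": config.digest(),
        "inputs": {name: _file_digest(p) for name, p in inputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "config.txt").write_text(config.to_text())


def _check_manifest(step_dir: Path, config: PipelineConfig, step_name: str) -> None:
    manifest_path = step_dir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"{step_name} outputs at {step_dir} carry no manifest")
    manifest = json.loads(manifest_path.read_text())
    if manifest["config"] != config.digest():
        raise PipelineError(
            f"{step_name} outputs at {step_dir} were produced under a different "
            "configuration; re-run that step or restore its config"
        )


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------

def run_step0(assemblies: list[Path], outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = _load_assemblies(assemblies)
    retained, regions = reduce_assembly(transcripts, config.end_length)
    logger.info(
        "step0: %d contigs in, %d longest isoforms retained, %d end regions",
        len(transcripts),
        len(retained),
        len(regions),
    )
    write_fasta(outdir / "retained.fa", [(t.contig_id, t.sequence) for t in retained])
    write_fasta(outdir / "ends.fa", [(r.fasta_id, r.sequence) for r in regions])
    _write_manifest(outdir, config, {p.name: p for p in assemblies})


def _load_assemblies(assemblies: list[Path]) -> list[Transcript]:
    if len(assemblies) == 1:
        return read_transcripts(assemblies[0])
    out: list[Transcript] = []
    for path in assemblies:
        out.extend(read_transcripts(path, namespace=path.stem))
    return out


def run_step1(step0_dir: Path, assemblies: list[Path], outdir: Path, config: PipelineConfig) -> None:
    _check_manifest(step0_dir, config, "step0")
    outdir.mkdir(parents=True, exist_ok=True)
    from .reduce_ends import EndRegion, WhichEnd

    regions = []
    for rec_id, seq in read_fasta(step0_dir / "ends.fa"):
        contig, _, end_tag = rec_id.rpartition("|")
        regions.append(
            EndRegion(contig, WhichEnd(end_tag), seq, config.end_length)
        )
    transcripts = _load_assemblies(assemblies)
    hooks, best, occ = hook_discovery.discover_hooks(
        regions,
        transcripts,
        k=config.k,
        assembly_k=config.assembly_k,
        min_kmer_fraction=config.min_kmer_fraction,
        min_identity=config.min_identity,
        min_cov=config.min_cov,
        seed_len=config.seed_len,
        end_window=config.end_length,
        coi_cutoff=config.coi_cutoff,
        apply_occ=config.apply_occ,
    )
    best_ids = {h.hook_id for h in best}
    write_fasta(outdir / "hooks.fa", [(h.hook_id, h.sequence) for h in hooks])
    write_fasta(outdir / "best_hooks.fa", [(h.hook_id, h.sequence) for h in best])
    write_tsv(
        outdir / "hook_stats.tsv",
        [
            "hook_id", "length", "Sf", "Sr", "Ef", "Er", "middle", "total",
            "coi", "occ_cutoff", "selected", "orientation_call",
        ],
        [
            [
                h.hook_id, len(h.sequence), h.sf, h.sr, h.ef, h.er, h.middle,
                h.total_hits, f"{h.coi:.4f}", occ,
                "yes" if h.hook_id in best_ids else "no", h.orientation_call.value,
            ]
            for h in hooks
        ],
    )
    write_tsv(
        outdir / "multi_hit_transcripts.tsv",
        ["hook_id", "contig_id"],
        [[h.hook_id, c] for h in hooks for c in h.multi_hit_transcripts],
    )
    hit_rows = []
    hit_contigs: set[str] = set()
    for h in best:
        for hit in h.hits:
            hit_rows.append(
                [
                    hit.hook_id, hit.contig_id, hit.query_start, hit.query_end,
                    hit.subject_start, hit.subject_end, hit.strand,
                    f"{hit.identity:.4f}", hit.position_class.value,
                ]
            )
            hit_contigs.add(hit.contig_id)
    write_tsv(
        outdir / "best_hook_hits.tsv",
        [
            "hook_id", "contig_id", "query_start", "query_end",
            "subject_start", "subject_end", "strand", "identity", "position_class",
        ],
        hit_rows,
    )
    by_id = {t.contig_id: t for t in transcripts}
    write_fasta(
        outdir / "hit_transcripts.fa",
        [(cid, by_id[cid].sequence) for cid in sorted(hit_contigs)],
    )
    _write_manifest(outdir, config, {"ends.fa": step0_dir / "ends.fa"})


def _load_best_hooks(step1_dir: Path) -> list[Hook]:
    hooks = {hid: Hook(hook_id=hid, sequence=seq) for hid, seq in read_fasta(step1_dir / "best_hooks.fa")}
    _, stat_rows = read_tsv(step1_dir / "hook_stats.tsv")
    for row in stat_rows:
        if row[0] in hooks:
            h = hooks[row[0]]
            h.sf, h.sr, h.ef, h.er, h.middle = map(int, row[2:7])
            h.coi = float(row[8])
            h.orientation_call = Orientation(row[11])
    _, hit_rows = read_tsv(step1_dir / "best_hook_hits.tsv")
    for row in hit_rows:
        hook_id, contig_id = row[0], row[1]
        hooks[hook_id].hits.append(
            HookHit(
                hook_id=hook_id,
                contig_id=contig_id,
                query_start=int(row[2]),
                query_end=int(row[3]),
                subject_start=int(row[4]),
                subject_end=int(row[5]),
                strand=row[6],
                identity=float(row[7]),
                position_class=PositionClass(row[8]),
            )
        )
    ordered = sorted(hooks.values(), key=lambda h: (-h.total_hits, h.hook_id))
    return ordered


def run_step2(step1_dir: Path, outdir: Path, config: PipelineConfig) -> None:
    _check_manifest(step1_dir, config, "step1")
    outdir.mkdir(parents=True, exist_ok=True)
    best = _load_best_hooks(step1_dir)
    transcripts = {t.contig_id: t for t in read_transcripts(step1_dir / "hit_transcripts.fa")}
    all_variants: list[HookVariant] = []
    meta_rows = []
    for hook in best:
        variants, aln, trimmed, ends, clusters = variant_builder.build_variants(
            hook,
            transcripts,
            identity=config.variant_identity,
            gap_fraction=config.gap_fraction,
            min_block=config.min_block,
        )
        prefix = outdir / hook.hook_id
        write_fasta(f"{prefix}.hits.fa", [(e.source_id, e.sequence) for e in ends])
        write_fasta(f"{prefix}.alignment.afa", aln.rows)
        write_fasta(f"{prefix}.alignment.trimmed.afa", trimmed.rows)
        write_fasta(f"{prefix}.variants.fa", [(v.variant_id, v.sequence) for v in variants])
        _write_pfm(f"{prefix}.pfm_before.tsv", variant_builder.position_frequency_matrix(aln))
        _write_pfm(f"{prefix}.pfm_after.tsv", variant_builder.position_frequency_matrix(trimmed))
        for v in variants:
            meta_rows.append([v.variant_id, v.hook_id, v.support, hook.orientation_call.value])
        all_variants.extend(variants)
    write_fasta(outdir / "variants.fa", [(v.variant_id, v.sequence) for v in all_variants])
    write_tsv(
        outdir / "variant_meta.tsv",
        ["variant_id", "hook_id", "support", "hook_orientation"],
        meta_rows,
    )
    _write_manifest(outdir, config, {"best_hooks.fa": step1_dir / "best_hooks.fa"})


def _write_pfm(path, pfm: list[dict[str, float]]) -> None:
    write_tsv(
        path,
        ["column", *PFM_SYMBOLS],
        [[i + 1, *(f"{col[s]:.4f}" for s in PFM_SYMBOLS)] for i, col in enumerate(pfm)],
    )


def run_step3(
    step2_dir: Path,
    genome_path: Path,
    reference_path: Path,
    outdir: Path,
    config: PipelineConfig,
) -> None:
    _check_manifest(step2_dir, config, "step2")
    if not genome_path.exists():
        raise PipelineError(f"reference genome {genome_path} is required for step3")
    outdir.mkdir(parents=True, exist_ok=True)
    _, meta_rows = read_tsv(step2_dir / "variant_meta.tsv")
    meta = {row[0]: (row[1], int(row[2]), Orientation(row[3])) for row in meta_rows}
    variants = [
        HookVariant(meta[vid][0], vid, seq, meta[vid][1], ())
        for vid, seq in read_fasta(step2_dir / "variants.fa")
    ]
    hook_orientations = {hook_id: orient for hook_id, _, orient in meta.values()}
    genome = core_io.read_genome(genome_path)
    reference = read_fasta(reference_path) if reference_path.exists() else []
    loci, psl = locus_mapper.run_step3(
        variants,
        genome,
        reference,
        hook_orientations,
        min_cov=config.genome_min_cov,
        clear_fraction=config.clear_fraction,
        distance_bp=config.annotation_distance,
        mode=config.annotation_mode,
        merge_gap=5,
    )
    genome_map = {g.chrom_id: g.sequence for g in genome}
    _emit_locus_report(outdir, loci, psl, variants, genome_map)
    _write_manifest(outdir, config, {"variants.fa": step2_dir / "variants.fa"})


def _emit_locus_report(outdir: Path, loci, psl, variants, genome_map) -> None:
    by_vid = {v.variant_id: v for v in variants}
    rows = []
    features = []
    for locus in loci:
        star = any(c.overlap_star for c in locus.donor_calls)
        rows.append(
            [
                locus.locus_id, locus.chrom, locus.start, locus.end, locus.strand,
                locus.status, "*" if star else "",
                locus.annotation_distance if locus.annotation_distance is not None else "NA",
                "yes" if locus.discarded else "no",
                ",".join(sorted({h.variant_id for h in locus.variant_hits})),
            ]
        )
        features.append(
            Gff3Feature(
                seqid=locus.chrom,
                source="slfinder",
                ftype="putative_SL_locus",
                start=locus.start,
                end=locus.end,
                score=".",
                strand=locus.strand,
                attributes={
                    "ID": locus.locus_id,
                    "status": locus.status,
                    "discarded": "yes" if locus.discarded else "no",
                },
            )
        )
        # per-locus alignment of the locus sequence with its matching variants
        seqs = [(locus.locus_id, locus.sequence(genome_map))]
        for vid in sorted({h.variant_id for h in locus.variant_hits}):
            seqs.append((vid, by_vid[vid].sequence))
        aln = align_progressive(seqs)
        write_fasta(outdir / f"locus_{locus.locus_id}.afa", aln.rows)
    write_tsv(
        outdir / "loci.tsv",
        [
            "locus_id", "chrom", "start", "end", "strand", "status", "star",
            "annotation_distance", "discarded", "variants",
        ],
        rows,
    )
    write_gff3(outdir / "loci.gff3", features)
    write_fasta(
        outdir / "pSL_clear.fa",
        [(p.psl_id, p.sequence) for p in psl if p.donor_class == "Clear"],
    )
    write_fasta(
        outdir / "pSL_unclear.fa",
        [(p.psl_id, p.sequence) for p in psl if p.donor_class == "Unclear"],
    )
    # cross-reference identical Clear/Unclear sequences for manual inspection
    clear_seqs = {p.sequence: p.psl_id for p in psl if p.donor_class == "Clear"}
    write_tsv(
        outdir / "psl_summary.tsv",
        ["psl_id", "donor_class", "length", "n_loci", "loci", "identical_clear_psl"],
        [
            [
                p.psl_id, p.donor_class, len(p.sequence), len(p.member_loci),
                ",".join(p.member_loci),
                clear_seqs.get(p.sequence, "") if p.donor_class == "Unclear" else "",
            ]
            for p in psl
        ],
    )


def run_all(
    assemblies: list[Path],
    genome: Path,
    reference: Path,
    outdir: Path,
    config: PipelineConfig | None = None,
) -> Path:
    """Execute Step0 through Step3 and write a final candidate summary.

    Exit with zero candidates is a valid outcome — the expected one for a
    species without spliced leaders.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.txt").write_text(config.to_text())
    run_step0(assemblies, outdir / "step0", config)
    run_step1(outdir / "step0", assemblies, outdir / "step1", config)
    run_step2(outdir / "step1", outdir / "step2", config)
    run_step3(outdir / "step2", genome, reference, outdir / "step3", config)
    header, psl_rows = read_tsv(outdir / "step3" / "psl_summary.tsv")
    write_tsv(outdir / "summary.tsv", header or ["psl_id", "donor_class", "length",
              "n_loci", "loci", "identical_clear_psl"], psl_rows)
    logger.info("pipeline finished: %d pSL candidates", len(psl_rows))
    return outdir / "summary.tsv"


# ---------------------------------------------------------------------------
# validation against synthetic truth
# ---------------------------------------------------------------------------

def validate_against_truth(outdir: Path, truth: SyntheticTruth, window: int = 100) -> dict:
    """Score a finished run against the generator's planted truth.

    Per SL class: ``recovered`` (a Clear pSL carries the exon's 3' 20-mer,
    allowing the two-base retrieval overhang), and ``locus_recall`` (fraction
    of planted loci within ``window`` bp, inclusive, of a reported
    non-discarded locus). Also reports the number of false-positive Clear
    pSLs: those containing no 15-mer of any planted exon.
    """
    outdir = Path(outdir)
    step3 = outdir / "step3" if (outdir / "step3").exists() else outdir
    clear = read_fasta(step3 / "pSL_clear.fa") if (step3 / "pSL_clear.fa").exists() else []
    _, locus_rows = (
        read_tsv(step3 / "loci.tsv") if (step3 / "loci.tsv").exists() else ([], [])
    )
    reported = [
        (row[1], int(row[2]), int(row[3]), row[5])
        for row in locus_rows
        if row[8] == "no"
    ]
    report: dict = {"classes": {}, "false_positive_psls": 0}
    for sl in truth.sl_classes:
        probe = sl.exon[-min(20, len(sl.exon)) :]
        recovered = any(probe in seq for _, seq in clear)
        planted = [loc for loc in truth.sl_loci if loc[4] == sl.sl_id]
        n_hit = 0
        for chrom, start, end, _, _ in planted:
            for r_chrom, r_start, r_end, _status in reported:
                if r_chrom != chrom:
                    continue
                gap = max(r_start - end, start - r_end, 0)
                if gap <= window:
                    n_hit += 1
                    break
        report["classes"][sl.sl_id] = {
            "recovered": recovered,
            "locus_recall": n_hit / len(planted) if planted else 0.0,
            "n_planted": len(planted),
        }
    probes = [sl.exon for sl in truth.sl_classes]
    for _, seq in clear:
        if not any(
            any(exon[i : i + 15] in seq for i in range(len(exon) - 14))
            for exon in probes
        ):
            report["false_positive_psls"] += 1
    return report
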