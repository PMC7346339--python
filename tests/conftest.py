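import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from slfinder.core_io import write_fasta
from slfinder.pipeline import PipelineConfig, run_all
from slfinder.synth import generate_scenario

FIXTURE_SEED = 42  # the documented seed of the synthetic study conditions


def materialize(tmpdir: Path, name: str, seed: int = FIXTURE_SEED, **kwargs):
    """Generate a scenario to disk; returns (fixture dir, truth)."""
    genome, transcripts, reference, truth = generate_scenario(name, seed, **kwargs)
    tmpdir.mkdir(parents=True, exist_ok=True)
    write_fasta(tmpdir / "genome.fa", [(g.chrom_id, g.sequence) for g in genome])
    write_fasta(tmpdir / "transcripts.fa", [(t.contig_id, t.sequence) for t in transcripts])
    write_fasta(tmpdir / "reference.fa", reference)
    return tmpdir, truth


def run_pipeline(fixture_dir: Path, outdir: Path, config: PipelineConfig | None = None,
                 transcripts: str = "transcripts.fa", genome: str = "genome.fa") -> Path:
    run_all(
        [fixture_dir / transcripts],
        fixture_dir / genome,
        fixture_dir / "reference.fa",
        outdir,
        config,
    )
    return outdir


@pytest.fixture(scope="session")
def no_sl_run(tmp_path_factory):
    base = tmp_path_factory.mktemp("no_sl")
    fixture, truth = materialize(base / "fix", "no-sl")
    out = run_pipeline(fixture, base / "run")
    return out, truth


@pytest.fixture(scope="session")
def long_sl_run(tmp_path_factory):
    base = tmp_path_factory.mktemp("long_sl")
    fixture, truth = materialize(base / "fix", "one-long-sl")
    out = run_pipeline(fixture, base / "run")
    return fixture, out, truth


@pytest.fixture(scope="session")
def short_sl_runs(tmp_path_factory):
    base = tmp_path_factory.mktemp("short_sl")
    fixture, truth = materialize(base / "fix", "one-short-sl")
    default = run_pipeline(fixture, base / "run_default")
    custom = run_pipeline(
        fixture,
        base / "run_custom",
        PipelineConfig(k=15, assembly_k=14, apply_occ=False),
    )
    return default, custom, truth


@pytest.fixture(scope="session")
def multi_sl_run(tmp_path_factory):
    base = tmp_path_factory.mktemp("multi_sl")
    fixture, truth = materialize(base / "fix", "multi-sl")
    out = run_pipeline(fixture, base / "run")
    return out, truth
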