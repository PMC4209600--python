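import numpy as np
import pytest

from mirescape import MIR155, derive_seed_motifs
from mirescape.pipeline import RunConfig, run_all
from mirescape.synthetic import (
    SimulationConfig,
    simulate_paper_mimic,
    simulate_screen,
)


@pytest.fixture(scope="session")
def motifs():
    """miR-155-5p target motifs."""
    return derive_seed_motifs(MIR155)


@pytest.fixture(scope="session")
def small_screen():
    """A compact simulated screen shared across in-memory tests."""
    return simulate_screen(SimulationConfig(n_genes=80), seed=7)


@pytest.fixture(scope="session")
def paper_mimic(tmp_path_factory):
    """Paper-mimic preset, emitted to disk and run end to end once."""
    indir = tmp_path_factory.mktemp("pm_in")
    outdir = tmp_path_factory.mktemp("pm_out")
    screen = simulate_paper_mimic(seed=3, outdir=indir)
    config = RunConfig(
        utr_fasta=str(indir / "utrs.fasta"),
        counts=str(indir / "counts.tsv"),
        outdir=str(outdir),
        bed12=str(indir / "transcripts.bed"),
        coverage_vector=str(indir / "coverage_vector.bedgraph"),
        coverage_mir155=str(indir / "coverage_mir155.bedgraph"),
        gmt=str(indir / "genesets.gmt"),
        library_vector=screen.config.library_vector,
        library_mir155=screen.config.library_mir155,
        filter_scope="increased_only",
    )
    bundle = run_all(config)
    return screen, bundle
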