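"""The synthetic-screen generator: truth consistency and determinism."""

import filecmp

import numpy as np
import pytest

from mirescape.quantify import CLASS_INCREASED, CLASS_LOW_READ, quantify_table
from mirescape.seedscan import scan_utr
from mirescape.synthetic import (
    SimulationConfig,
    assign_effects,
    simulate_counts,
    simulate_paper_mimic,
    simulate_screen,
    simulate_utrs,
)


def test_no_planting_means_no_sites(motifs):
    config = SimulationConfig(n_genes=15, p_site_8mer=0.0, p_site_7mer=0.0,
                              utr_length_range=(200, 400))
    seqs, truth = simulate_utrs(config, np.random.default_rng(2))
    assert all(scan_utr(s, motifs) == [] for s in seqs.values())
    assert (truth["sites"] == "").all()


def test_one_8mer_per_gene_recovered(motifs):
    config = SimulationConfig(n_genes=15, p_site_8mer=1.0, p_site_7mer=0.0,
                              utr_length_range=(300, 500))
    seqs, truth = simulate_utrs(config, np.random.default_rng(5))
    for row in truth.itertuples(index=False):
        sites = scan_utr(seqs[row.gene], motifs)
        assert [(s.site_type, s.start) for s in sites] == [
            ("8mer", int(row.site_8mer_start))
        ]


def test_counts_centre_on_planted_folds():
    """Near-Poisson counts at fold 1 average out to fold ~1 (law of large
    numbers on the count ratio)."""
    config = SimulationConfig(nb_dispersion=1e-4, n_low_read=0, frac_up=0.0,
                              frac_down=0.0, base_mean_median=500.0,
                              base_mean_sigma=0.2)
    rng = np.random.default_rng(8)
    n = 4000
    truth = assign_effects(
        config,
        _skeleton_truth(n),
        rng,
    )
    counts = simulate_counts(config, truth, rng)
    fold = counts["count_mir155"].sum() / counts["count_vector"].sum()
    assert fold == pytest.approx(1.0, rel=0.02)


def _skeleton_truth(n):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": [f"G{i:05d}" for i in range(n)],
            "strand": "+",
            "utr_length": 500,
            "sites": "",
            "n_8mer": 0,
            "n_7mer": 0,
            "site_8mer_start": -1,
        }
    )


def test_planted_fold4_classified_increased():
    config = SimulationConfig(nb_dispersion=0.01, n_low_read=0,
                              frac_up=1.0, frac_down=0.0,
                              fold_up_range=(4.0, 4.0),
                              base_mean_median=500.0, base_mean_sigma=0.3)
    rng = np.random.default_rng(12)
    truth = assign_effects(config, _skeleton_truth(400), rng)
    counts = simulate_counts(config, truth, rng)
    table = quantify_table(counts, library_vector=10**6, library_mir155=10**6)
    frac = (table["class_label"] == CLASS_INCREASED).mean()
    assert frac >= 0.95


def test_zero_mean_gene_has_zero_counts():
    config = SimulationConfig()
    rng = np.random.default_rng(3)
    truth = assign_effects(config, _skeleton_truth(5), rng)
    truth["base_mean"] = 0.0
    counts = simulate_counts(config, truth, rng)
    assert (counts["count_vector"] == 0).all() and (counts["count_mir155"] == 0).all()


def test_low_read_genes_fall_under_floor(small_screen):
    table = quantify_table(small_screen.counts)
    merged = table.merge(small_screen.truth[["gene", "low_read"]], on="gene")
    low = merged[merged["low_read"]]
    assert (low["class_label"] == CLASS_LOW_READ).mean() >= 0.99


def test_emitted_files_byte_identical_across_runs(tmp_path):
    config = SimulationConfig(n_genes=25, utr_length_range=(200, 500))
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_screen(config, seed=42, outdir=a)
    simulate_screen(config, seed=42, outdir=b)
    names = [p.name for p in sorted(a.iterdir())]
    match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
    assert mismatch == [] and errors == []
    assert set(names) >= {"utrs.fasta", "transcripts.bed", "counts.tsv",
                          "coverage_vector.bedgraph", "coverage_mir155.bedgraph",
                          "genesets.gmt", "truth.tsv", "metadata.json"}


def test_different_seeds_differ(tmp_path):
    config = SimulationConfig(n_genes=10, utr_length_range=(200, 300))
    s1 = simulate_screen(config, seed=1)
    s2 = simulate_screen(config, seed=2)
    assert s1.utrs != s2.utrs


def test_truth_file_consistency_after_emission(tmp_path, motifs):
    from mirescape import io as mio

    screen = simulate_screen(SimulationConfig(n_genes=20), seed=6, outdir=tmp_path)
    utrs = mio.read_fasta(tmp_path / "utrs.fasta")
    truth = mio.read_tsv(tmp_path / "truth.tsv").fillna({"sites": ""})
    for row in truth.itertuples(index=False):
        expected = set()
        if row.sites:
            expected = {
                (i.split(":")[0], int(i.split(":")[1])) for i in row.sites.split(";")
            }
        found = {(s.site_type, s.start) for s in scan_utr(utrs[row.gene], motifs)}
        assert found == expected


def test_shortened_breakpoints_proximal_to_seed(small_screen):
    shortened = small_screen.truth[small_screen.truth["shortened"]]
    assert (shortened["breakpoint"] < shortened["site_8mer_start"]).all()
    assert shortened["seed_lost"].all()


def test_paper_mimic_structure():
    screen = simulate_paper_mimic(seed=0)
    truth = screen.truth
    up8 = truth[(truth["true_class"] == "up") & (truth["n_8mer"] > 0)]
    assert len(up8) == 30
    assert int(up8["low_read"].sum()) == 14
    retained = up8[~up8["low_read"]]
    assert len(retained) == 16
    assert int(retained["shortened"].sum()) == 11
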