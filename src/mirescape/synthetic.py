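"""Truth-annotated synthetic inputs for a two-condition miRNA screen.

The generator emulates the statistical structure of an overexpression
screen (empty-vector line vs miRNA line, one RNA-seq library each):

* 3'UTR sequences with seed sites planted at recorded offsets into
  motif-free background (background is rejection-sampled so the scanner
  finds exactly the planted sites and nothing else);
* per-gene raw counts, negative binomial with planted fold effects
  (up > 1.5, down <= 0.5, null = 1) and a block of genes forced below
  the low-read floor in both conditions;
* per-base 3'UTR coverage, Poisson, with a step-drop by a configured
  attenuation factor beyond a planted breakpoint in the miRNA-condition
  track of shortened genes, the breakpoint placed proximal to the
  planted seed site so the seed is lost;
* a GMT collection with one set enriched among the true up-regulated
  genes at configured odds.

Every operation draws from one :class:`numpy.random.Generator`, so a
fixed seed reproduces every emitted file byte for byte.  A
``paper-mimic`` preset (:func:`simulate_paper_mimic`) reproduces the
published screen's cohort arithmetic: thirty increased-expression 8-mer
targets of which fourteen are low-read, with per-gene shortening flags
and fold effects transcribed from the published cohort table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio
from . import screen_tables
from .seedscan import (
    MIR155,
    MatureMiRNA,
    SeedMotifSet,
    SeedSite,
    derive_seed_motifs,
    scan_utr,
)

__all__ = [
    "SimulationConfig",
    "SimulatedScreen",
    "simulate_utrs",
    "assign_effects",
    "simulate_counts",
    "simulate_coverage",
    "simulate_gene_sets",
    "simulate_screen",
    "simulate_paper_mimic",
]

_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated screen.

    Defaults describe a desk-scale screen with clear planted effects:
    a few hundred genes, moderately deep libraries, fold effects well
    clear of the classification thresholds, and an eight-fold coverage
    step for shortened transcripts.
    """

    n_genes: int = 300
    utr_length_range: tuple[int, int] = (400, 1500)
    p_site_8mer: float = 0.35
    p_site_7mer: float = 0.35
    frac_up: float = 0.20
    frac_down: float = 0.30
    fold_up_range: tuple[float, float] = (2.0, 5.0)
    fold_down_range: tuple[float, float] = (0.10, 0.45)
    frac_shortened_of_increased: float = 0.5
    base_mean_median: float = 200.0
    base_mean_sigma: float = 1.0
    nb_dispersion: float = 0.05
    deterministic_counts: bool = False
    n_low_read: int = 20
    low_read_mean: float = 1.5
    coverage_depth: float = 30.0
    step_factor: float = 8.0
    cds_length_bp: int = 1200
    n_gene_sets: int = 20
    gene_set_size: int = 40
    enrichment_odds: float = 9.0
    library_vector: int = 1_000_000
    library_mir155: int = 1_000_000
    mirna_name: str = MIR155.name
    mirna_sequence: str = MIR155.sequence

    def __post_init__(self) -> None:
        if not 0 <= self.p_site_8mer <= 1 or not 0 <= self.p_site_7mer <= 1:
            raise ValueError("site-planting probabilities must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.step_factor <= 1:
            raise ValueError("step factor must exceed 1")
        if self.utr_length_range[0] < 120:
            raise ValueError("UTR lengths below 120 bp cannot host the "
                             "planted site / breakpoint layout")

    @property
    def mirna(self) -> MatureMiRNA:
        return MatureMiRNA(self.mirna_name, self.mirna_sequence)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_DNA, size=length))


def _motif_free_background(
    rng: np.random.Generator, length: int, motifs: SeedMotifSet
) -> str:
    """Random DNA with no seed site anywhere (rejection sampling)."""
    for _ in range(200):
        seq = _random_dna(rng, length)
        if not scan_utr(seq, motifs):
            return seq
    raise RuntimeError("could not sample a motif-free background sequence")


def _dna(motif_rna: str) -> str:
    return motif_rna.replace("U", "T")


def simulate_utrs(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate UTR sequences with planted seed sites and their truth.

    Returns ``(sequences, truth)`` where ``truth`` has one row per gene
    with the planted site offsets/types (``sites`` column,
    ``type:start`` entries joined by ``;``), strand, and UTR length.
    The scanner run on each emitted sequence recovers exactly the
    planted sites: the 8mer (when planted) sits in the distal part of
    the UTR, a 7mer (when planted) in the proximal part.
    """
    motifs = derive_seed_motifs(config.mirna)
    lo, hi = config.utr_length_range
    names = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    rows = []
    sequences: dict[str, str] = {}
    for name in names:
        length = int(rng.integers(lo, hi + 1))
        plant8 = rng.random() < config.p_site_8mer
        plant7 = rng.random() < config.p_site_7mer
        type7 = str(rng.choice(["7mer-m8", "7mer-A1"])) if plant7 else ""
        strand = "+" if rng.random() < 0.5 else "-"
        planted: list[tuple[str, int]] = []
        off8 = int(rng.integers(int(0.35 * length), int(0.85 * length) - 8)) if plant8 else -1
        off7 = int(rng.integers(15, max(16, int(0.30 * length) - 7))) if plant7 else -1
        for attempt in range(100):
            seq = list(_motif_free_background(rng, length, motifs))
            planted = []
            if plant8:
                motif = _dna(motifs.motif_8mer)
                seq[off8 : off8 + 8] = motif
                planted.append(("8mer", off8))
            if plant7:
                motif_rna = (
                    motifs.motif_7mer_m8 if type7 == "7mer-m8" else motifs.motif_7mer_A1
                )
                motif = _dna(motif_rna)
                seq[off7 : off7 + 7] = motif
                # avoid accidentally upgrading the planted 7mer to an 8mer
                if type7 == "7mer-m8" and seq[off7 + 7] == "A":
                    seq[off7 + 7] = str(rng.choice(["C", "G", "T"]))
                if type7 == "7mer-A1" and off7 > 0 and seq[off7 - 1] == _dna(motifs.motif_7mer_m8)[0]:
                    choices = [b for b in "ACGT" if b != seq[off7 - 1]]
                    seq[off7 - 1] = str(rng.choice(choices))
                planted.append((type7, off7))
            candidate = "".join(seq)
            found = {(s.site_type, s.start) for s in scan_utr(candidate, motifs)}
            if found == set(planted):
                break
        else:
            raise RuntimeError(f"{name}: could not plant sites cleanly")
        sequences[name] = candidate
        planted.sort(key=lambda p: p[1])
        rows.append(
            {
                "gene": name,
                "strand": strand,
                "utr_length": length,
                "sites": ";".join(f"{t}:{o}" for t, o in planted),
                "n_8mer": int(plant8),
                "n_7mer": int(plant7),
                "site_8mer_start": off8,
            }
        )
    return sequences, pd.DataFrame(rows)


def assign_effects(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Add expression effects and shortening events to a site truth table.

    Up/down/null classes are drawn per gene; shortened genes are a
    configured fraction of the up-regulated 8mer-carrying genes, each
    with a planted breakpoint strictly proximal to its 8mer seed site
    (so the planted shortening always loses the seed).
    """
    truth = truth.copy()
    n = len(truth)
    u = rng.random(n)
    cls = np.where(u < config.frac_up, "up",
                   np.where(u < config.frac_up + config.frac_down, "down", "null"))
    fold = np.ones(n)
    fold[cls == "up"] = rng.uniform(*config.fold_up_range, size=(cls == "up").sum())
    fold[cls == "down"] = rng.uniform(*config.fold_down_range, size=(cls == "down").sum())
    base_mean = np.exp(
        rng.normal(np.log(config.base_mean_median), config.base_mean_sigma, size=n)
    )
    low_read = np.zeros(n, dtype=bool)
    if config.n_low_read > 0:
        idx = rng.choice(n, size=min(config.n_low_read, n), replace=False)
        low_read[idx] = True
        base_mean[idx] = config.low_read_mean
        # keep both condition means under the read floor: a low-read gene's
        # fold is clipped to 2 (still above the increased threshold)
        fold[idx] = np.minimum(fold[idx], 2.0)
    shortened = np.zeros(n, dtype=bool)
    breakpoint = np.full(n, -1)
    candidates = np.flatnonzero(
        (cls == "up") & (truth["n_8mer"].to_numpy() > 0) & ~low_read
    )
    for i in candidates:
        if rng.random() < config.frac_shortened_of_increased:
            seed_start = int(truth["site_8mer_start"].iloc[i])
            shortened[i] = True
            breakpoint[i] = int(rng.integers(40, seed_start - 10))
    truth["true_class"] = cls
    truth["true_fold"] = fold
    truth["base_mean"] = base_mean
    truth["low_read"] = low_read
    truth["shortened"] = shortened
    truth["seed_lost"] = shortened  # planted breakpoints are always proximal to the seed
    truth["breakpoint"] = breakpoint
    return truth


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial via the gamma-Poisson mixture; dispersion 0 is
    pure Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw count table (gene, count_vector, count_mir155, exon_length_bp).

    Vector counts ~ NB(mu_g, dispersion), miRNA-line counts ~
    NB(mu_g * fold_g, dispersion).  With ``deterministic_counts`` the
    expectations are emitted directly (rounded), which pins empirical
    folds to the planted effects -- used by the paper-mimic preset.
    """
    mu_v = truth["base_mean"].to_numpy(dtype=float)
    mu_m = mu_v * truth["true_fold"].to_numpy(dtype=float)
    if config.deterministic_counts:
        cv = np.rint(mu_v).astype(int)
        cm = np.rint(mu_m).astype(int)
    else:
        cv = _nb_sample(rng, mu_v, config.nb_dispersion)
        cm = _nb_sample(rng, mu_m, config.nb_dispersion)
    return pd.DataFrame(
        {
            "gene": truth["gene"].to_numpy(),
            "count_vector": cv,
            "count_mir155": cm,
            "exon_length_bp": truth["utr_length"].to_numpy() + config.cds_length_bp,
        }
    )


def simulate_coverage(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-base UTR coverage (transcript 5'->3') for both conditions.

    Coverage ~ Poisson(depth x condition scale); the miRNA-condition
    scale follows the planted fold (clipped to [0.25, 4]) and is
    attenuated by the step factor beyond the planted breakpoint of
    shortened genes.  Coverage depth is deliberately decoupled from the
    count table's base means: it models UTR read pile-up at a common
    working depth, not library-wide abundance.
    """
    tracks_v: dict[str, np.ndarray] = {}
    tracks_m: dict[str, np.ndarray] = {}
    for row in truth.itertuples(index=False):
        length = int(row.utr_length)
        scale_m = float(np.clip(row.true_fold, 0.25, 4.0))
        rate_v = np.full(length, config.coverage_depth)
        rate_m = np.full(length, config.coverage_depth * scale_m)
        if row.shortened:
            rate_m[int(row.breakpoint):] /= config.step_factor
        tracks_v[row.gene] = rng.poisson(rate_v).astype(float)
        tracks_m[row.gene] = rng.poisson(rate_m).astype(float)
    return tracks_v, tracks_m


def simulate_gene_sets(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """GMT collection with one set enriched among the true up genes.

    The enriched set is a weighted sample without replacement in which
    true up-regulated genes carry ``enrichment_odds`` times the weight
    of other genes (odds 1 gives a uniform, null set); the remaining
    sets are uniform samples.  Returns the collection and the truth
    table with an ``enriched_member`` column added.
    """
    truth = truth.copy()
    genes = truth["gene"].to_numpy()
    n = len(genes)
    size = min(config.gene_set_size, n)
    weights = np.where(truth["true_class"].to_numpy() == "up",
                       config.enrichment_odds, 1.0)
    # Efraimidis-Spirakis weighted sampling without replacement
    keys = rng.random(n) ** (1.0 / weights)
    enriched_idx = np.argsort(keys)[-size:]
    sets: dict[str, list[str]] = {
        "SET_ENRICHED": sorted(genes[enriched_idx].tolist())
    }
    for j in range(max(0, config.n_gene_sets - 1)):
        members = rng.choice(genes, size=size, replace=False)
        sets[f"SET_{j + 1:02d}"] = sorted(members.tolist())
    member = np.zeros(n, dtype=bool)
    member[enriched_idx] = True
    truth["enriched_member"] = member
    return sets, truth


@dataclass
class SimulatedScreen:
    """All artifacts of one simulated screen, plus file emission."""

    config: SimulationConfig
    seed: int
    utrs: dict[str, str]
    truth: pd.DataFrame
    counts: pd.DataFrame
    coverage_vector: dict[str, np.ndarray]
    coverage_mir155: dict[str, np.ndarray]
    gene_sets: dict[str, list[str]]

    def intervals(self) -> list[mio.UtrInterval]:
        """One single-block genomic interval per transcript, each on its
        own contig, with the strand recorded in the truth table."""
        return [
            mio.UtrInterval(
                transcript_id=row.gene, chrom=row.gene, start=0,
                end=int(row.utr_length), strand=row.strand,
            )
            for row in self.truth.itertuples(index=False)
        ]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit all input files plus truth and metadata; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "utr_fasta": outdir / "utrs.fasta",
            "bed12": outdir / "transcripts.bed",
            "counts": outdir / "counts.tsv",
            "coverage_vector": outdir / "coverage_vector.bedgraph",
            "coverage_mir155": outdir / "coverage_mir155.bedgraph",
            "gmt": outdir / "genesets.gmt",
            "truth": outdir / "truth.tsv",
            "metadata": outdir / "metadata.json",
        }
        mio.write_fasta(self.utrs, paths["utr_fasta"])
        mio.write_bed12(self.intervals(), paths["bed12"])
        mio.write_tsv(self.counts, paths["counts"])
        strands = dict(zip(self.truth["gene"], self.truth["strand"]))
        for key, tracks in (
            ("coverage_vector", self.coverage_vector),
            ("coverage_mir155", self.coverage_mir155),
        ):
            genomic = {
                gene: (0, cov[::-1] if strands[gene] == "-" else cov)
                for gene, cov in tracks.items()
            }
            mio.write_bedgraph(genomic, paths[key])
        mio.write_gmt(self.gene_sets, paths["gmt"])
        mio.write_tsv(self.truth, paths["truth"])
        meta = dataclasses.asdict(self.config)
        meta["seed"] = self.seed
        paths["metadata"].write_text(json.dumps(meta, indent=2, default=str) + "\n")
        return paths


def simulate_screen(
    config: SimulationConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SimulatedScreen:
    """Run the full generator; optionally emit files to ``outdir``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    utrs, truth = simulate_utrs(config, rng)
    truth = assign_effects(config, truth, rng)
    counts = simulate_counts(config, truth, rng)
    cov_v, cov_m = simulate_coverage(config, truth, rng)
    sets, truth = simulate_gene_sets(config, truth, rng)
    screen = SimulatedScreen(
        config=config, seed=seed, utrs=utrs, truth=truth, counts=counts,
        coverage_vector=cov_v, coverage_mir155=cov_m, gene_sets=sets,
    )
    if outdir is not None:
        screen.write(outdir)
    return screen


# ---------------------------------------------------------------------------
# paper-mimic preset


def _paper_mimic_truth(rng: np.random.Generator) -> pd.DataFrame:
    """Explicit per-gene truth reproducing the published cohort structure.

    Thirty increased-expression genes carrying one 8mer site each:
    the sixteen published cohort genes with their published fold effects
    and shortening flags, plus fourteen low-read genes.  Background:
    forty repressed seed-carrying genes, twenty null genes with a 7mer
    site and forty without any site.
    """
    rows = []
    cohort = screen_tables.eight_mer_cohort()
    length, seed_start = 800, 500
    for rec in cohort.itertuples(index=False):
        rows.append(
            dict(gene=rec.gene, strand="+", utr_length=length,
                 sites=f"8mer:{seed_start}", n_8mer=1, n_7mer=0,
                 site_8mer_start=seed_start, true_class="up",
                 true_fold=float(rec.relative_expression), base_mean=1000.0,
                 low_read=False, shortened=bool(rec.utr_shortening),
                 seed_lost=bool(rec.utr_shortening),
                 breakpoint=300 if rec.utr_shortening else -1)
        )
    for i in range(screen_tables.LOW_READ_EXCLUDED):
        rows.append(
            dict(gene=f"LOWRD{i + 1:02d}", strand="+", utr_length=length,
                 sites=f"8mer:{seed_start}", n_8mer=1, n_7mer=0,
                 site_8mer_start=seed_start, true_class="up", true_fold=2.0,
                 base_mean=3.0, low_read=True, shortened=False,
                 seed_lost=False, breakpoint=-1)
        )
    for i in range(40):
        has8 = i % 2 == 0
        rows.append(
            dict(gene=f"REPR{i + 1:03d}", strand="+" if i % 3 else "-",
                 utr_length=length,
                 sites=f"8mer:{seed_start}" if has8 else "7mer-m8:100",
                 n_8mer=int(has8), n_7mer=int(not has8),
                 site_8mer_start=seed_start if has8 else -1,
                 true_class="down", true_fold=0.25, base_mean=500.0,
                 low_read=False, shortened=False, seed_lost=False,
                 breakpoint=-1)
        )
    for i in range(20):
        rows.append(
            dict(gene=f"NUL7M{i + 1:03d}", strand="+", utr_length=length,
                 sites="7mer-A1:120", n_8mer=0, n_7mer=1,
                 site_8mer_start=-1, true_class="null", true_fold=1.0,
                 base_mean=500.0, low_read=False, shortened=False,
                 seed_lost=False, breakpoint=-1)
        )
    for i in range(40):
        rows.append(
            dict(gene=f"NOSITE{i + 1:03d}", strand="+", utr_length=length,
                 sites="", n_8mer=0, n_7mer=0, site_8mer_start=-1,
                 true_class="null", true_fold=1.0, base_mean=500.0,
                 low_read=False, shortened=False, seed_lost=False,
                 breakpoint=-1)
        )
    return pd.DataFrame(rows)


def _sequences_from_truth(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> dict[str, str]:
    """Motif-free backgrounds with the truth table's sites planted."""
    motifs = derive_seed_motifs(config.mirna)
    by_type = {
        "8mer": _dna(motifs.motif_8mer),
        "7mer-m8": _dna(motifs.motif_7mer_m8),
        "7mer-A1": _dna(motifs.motif_7mer_A1),
    }
    sequences = {}
    for row in truth.itertuples(index=False):
        planted = []
        if row.sites:
            for item in row.sites.split(";"):
                site_type, start = item.split(":")
                planted.append((site_type, int(start)))
        for _ in range(100):
            seq = list(_motif_free_background(rng, int(row.utr_length), motifs))
            for site_type, start in planted:
                motif = by_type[site_type]
                seq[start : start + len(motif)] = motif
                if site_type == "7mer-m8" and seq[start + 7] == "A":
                    seq[start + 7] = str(rng.choice(["C", "G", "T"]))
            candidate = "".join(seq)
            found = {(s.site_type, s.start) for s in scan_utr(candidate, motifs)}
            if found == set(planted):
                break
        else:
            raise RuntimeError(f"{row.gene}: could not plant sites cleanly")
        sequences[row.gene] = candidate
    return sequences


def simulate_paper_mimic(
    seed: int = 0, outdir: str | Path | None = None
) -> SimulatedScreen:
    """The paper-mimic preset: published cohort structure, pinned folds.

    Counts are deterministic expectations so that empirical folds equal
    the published relative-expression values; coverage keeps Poisson
    noise.  Nominal equal library sizes are recorded in the metadata so
    RPKM folds equal count ratios.
    """
    config = SimulationConfig(
        n_genes=130,
        deterministic_counts=True,
        nb_dispersion=0.0,
        n_low_read=screen_tables.LOW_READ_EXCLUDED,
        low_read_mean=3.0,
        n_gene_sets=10,
        gene_set_size=30,
    )
    rng = np.random.default_rng(seed)
    truth = _paper_mimic_truth(rng)
    utrs = _sequences_from_truth(config, truth, rng)
    counts = simulate_counts(config, truth, rng)
    cov_v, cov_m = simulate_coverage(config, truth, rng)
    sets, truth = simulate_gene_sets(config, truth, rng)
    screen = SimulatedScreen(
        config=config, seed=seed, utrs=utrs, truth=truth, counts=counts,
        coverage_vector=cov_v, coverage_mir155=cov_m, gene_sets=sets,
    )
    if outdir is not None:
        screen.write(outdir)
    return screen
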