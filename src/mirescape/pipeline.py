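"""End-to-end orchestration: scan -> quantify -> apa -> enrich -> report.

Mirrors the screen's analysis flow: pool genes carrying any seed site,
classify them by RPKM fold change with the low-read filter, call 3'UTR
shortening / seed-site loss from per-base coverage, and run gene-set
over-representation for the up-regulated, down-regulated and
seed-containing lists.  Stage record counts (genes in, genes filtered,
calls made) are logged so the cohort arithmetic is visible in the log.

All outputs are TSV with a header row and a leading ``#`` metadata
comment; the run is deterministic given inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .apa import ApaParams, CoverageTrack, call_shortening
from .enrich import GeneSetCollection, rank_pathways
from .quantify import (
    CLASS_INCREASED,
    CLASS_LOW_READ,
    CLASS_REPRESSED,
    Thresholds,
    fold_histogram,
    quantify_table,
)
from .seedscan import MatureMiRNA, SeedSite, count_sites, derive_seed_motifs, scan_utr

__all__ = ["RunConfig", "ReportBundle", "run_all", "StageError"]

logger = logging.getLogger(__name__)

_CLASS_ORDER = [CLASS_REPRESSED, "unchanged", CLASS_INCREASED, CLASS_LOW_READ]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters for one end-to-end run.

    ``library_vector`` / ``library_mir155`` default to the counts-table
    column sums when left ``None``.  ``filter_scope`` selects whether
    the low-read filter applies to every gene (``all``) or only to the
    would-be increased set (``increased_only``).
    """

    utr_fasta: str
    counts: str
    outdir: str
    mirna_name: str = "miR-155-5p"
    mirna_sequence: str = "UUAAUGCUAAUCGUGAUAGGGGU"
    bed12: str | None = None
    coverage_vector: str | None = None
    coverage_mir155: str | None = None
    gmt: str | None = None
    library_vector: int | None = None
    library_mir155: int | None = None
    pseudocount: float = 0.0
    filter_scope: str = "all"
    up_threshold: float = 1.5
    down_threshold: float = 0.5
    read_floor: int = 10
    dui_tau: float = 0.5
    min_proximal_mean: float = 5.0
    epsilon: float = 0.5
    universe: str = "counts"  # or "gmt"
    include_7mer_a1: bool = True
    hist_max_fold: float = 5.0
    hist_bin_width: float = 0.25

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` config file (# comments allowed).

        Values are parsed as JSON literals where possible, else kept as
        strings.
        """
        values: dict[str, object] = {}
        known = {f.name for f in dataclasses.fields(cls)}
        with open(path) as handle:
            for line_no, line in enumerate(handle, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{line_no}: expected 'key = value'")
                key, _, raw = line.partition("=")
                key = key.strip()
                if key not in known:
                    raise ValueError(f"{path}:{line_no}: unknown key {key!r}")
                raw = raw.strip()
                try:
                    values[key] = json.loads(raw)
                except json.JSONDecodeError:
                    values[key] = raw
        return cls(**values)  # type: ignore[arg-type]

    def thresholds(self) -> Thresholds:
        return Thresholds(self.up_threshold, self.down_threshold, self.read_floor)

    def apa_params(self) -> ApaParams:
        return ApaParams(
            tau=self.dui_tau,
            min_proximal_mean=self.min_proximal_mean,
            epsilon=self.epsilon,
        )


@dataclass
class ReportBundle:
    """Tables produced by one run, with the paths they were written to."""

    sites: pd.DataFrame
    site_counts: pd.DataFrame
    expression: pd.DataFrame
    shortening: pd.DataFrame
    targets: pd.DataFrame
    histograms: pd.DataFrame
    enrichment: dict[str, pd.DataFrame]
    metadata: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _scan_stage(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    mirna = MatureMiRNA(config.mirna_name, config.mirna_sequence)
    motifs = derive_seed_motifs(mirna)
    utrs = mio.read_fasta(config.utr_fasta)
    all_sites: dict[str, list[SeedSite]] = {}
    rows = []
    for transcript, seq in utrs.items():
        sites = scan_utr(seq, motifs, transcript_id=transcript)
        all_sites[transcript] = sites
        rows.extend(
            (transcript, s.start, s.end, s.site_type) for s in sites
        )
    sites_table = pd.DataFrame(
        rows, columns=["transcript", "start", "end", "site_type"]
    )
    count_rows = count_sites(all_sites, include_7mer_a1=config.include_7mer_a1)
    counts_table = pd.DataFrame(
        [(r.gene, r.n_7mer, r.n_8mer) for r in count_rows],
        columns=["gene", "n_7mer", "n_8mer"],
    )
    logger.info(
        "scan: %d UTRs, %d sites, %d genes with >= 1 site",
        len(utrs), len(sites_table),
        int(((counts_table["n_7mer"] + counts_table["n_8mer"]) > 0).sum()),
    )
    return sites_table, counts_table


def _apa_stage(
    config: RunConfig, sites_table: pd.DataFrame
) -> pd.DataFrame:
    columns = [
        "gene", "breakpoint", "proximal_mean_vector", "distal_mean_vector",
        "proximal_mean_mir155", "distal_mean_mir155", "dui_vector",
        "dui_mir155", "dui_ratio", "shortened", "seed_lost", "lost_in_both",
        "qc_fail", "qc_reason", "utr_shortening",
    ]
    if not (config.bed12 and config.coverage_vector and config.coverage_mir155):
        logger.info("apa: no coverage inputs; stage skipped")
        return pd.DataFrame(columns=columns)
    intervals = mio.read_bed12(config.bed12)
    runs_v = mio.read_bedgraph(config.coverage_vector)
    runs_m = mio.read_bedgraph(config.coverage_mir155)
    params = config.apa_params()
    sites_by_tx = {
        tx: [
            SeedSite(tx, int(r.start), int(r.end), r.site_type)
            for r in grp.itertuples(index=False)
        ]
        for tx, grp in sites_table.groupby("transcript")
    }
    rows = []
    for iv in intervals:
        cov_v = mio.project_coverage(runs_v, iv)
        cov_m = mio.project_coverage(runs_m, iv)
        call = call_shortening(
            CoverageTrack(iv.transcript_id, "vector", cov_v),
            CoverageTrack(iv.transcript_id, "mir155", cov_m),
            sites_by_tx.get(iv.transcript_id, []),
            params,
        )
        record = dataclasses.asdict(call)
        record["utr_shortening"] = "Yes" if call.seed_lost else "No"
        rows.append(record)
    table = pd.DataFrame(rows, columns=columns)
    logger.info(
        "apa: %d transcripts, %d qc failures, %d shortened, %d seed-lost",
        len(table), int(table["qc_fail"].sum()),
        int(table["shortened"].sum()), int(table["seed_lost"].sum()),
    )
    return table


def run_all(config: RunConfig) -> ReportBundle:
    """Run every stage and write the report tables to ``config.outdir``.

    Stage failures raise :class:`StageError` naming the stage.  An empty
    seed-site table is not an error: the targets table is empty and the
    run completes with a warning.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        sites_table, site_counts = _scan_stage(config)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("scan", str(exc)) from exc

    try:
        counts = mio.read_tsv(config.counts)
        expression = quantify_table(
            counts,
            library_vector=config.library_vector,
            library_mir155=config.library_mir155,
            pseudocount=config.pseudocount,
            thresholds=config.thresholds(),
            filter_scope=config.filter_scope,
        )
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc
    class_counts = expression["class_label"].value_counts().to_dict()
    logger.info("quantify: %d genes, classes %s", len(expression), class_counts)

    try:
        shortening = _apa_stage(config, sites_table)
    except Exception as exc:
        raise StageError("apa", str(exc)) from exc

    # targets table: the pooled seed-containing genes, Table-style layout
    seeded = site_counts[(site_counts["n_7mer"] + site_counts["n_8mer"]) > 0]
    if seeded.empty:
        logger.warning("no gene carries a seed site; targets table is empty")
    targets = seeded.merge(expression, on="gene", how="inner")
    if not shortening.empty:
        targets = targets.merge(
            shortening[["gene", "shortened", "seed_lost", "lost_in_both",
                        "utr_shortening", "qc_fail"]],
            on="gene", how="left",
        )
    else:
        targets["shortened"] = False
        targets["seed_lost"] = False
        targets["lost_in_both"] = False
        targets["utr_shortening"] = "No"
        targets["qc_fail"] = True
    targets["_class_rank"] = targets["class_label"].map(
        {c: i for i, c in enumerate(_CLASS_ORDER)}
    )
    targets = (
        targets.sort_values(["_class_rank", "fold_change", "gene"])
        .drop(columns="_class_rank")
        .reset_index(drop=True)
    )
    increased_8mer = targets[
        (targets["class_label"] == CLASS_INCREASED) & (targets["n_8mer"] > 0)
    ]
    logger.info(
        "targets: %d seed-containing genes; %d increased with an 8mer site; "
        "%d low-read-excluded",
        len(targets), len(increased_8mer),
        int((targets["class_label"] == CLASS_LOW_READ).sum()),
    )

    # fold-distribution histograms for the three seed-class panels
    edges = list(np.arange(0.0, config.hist_max_fold + 1e-9, config.hist_bin_width))
    edges.append(np.inf)
    panels = {
        "any_site": seeded["gene"],
        "8mer": site_counts.loc[site_counts["n_8mer"] > 0, "gene"],
        "7mer": site_counts.loc[site_counts["n_7mer"] > 0, "gene"],
    }
    hist_frames = []
    for panel, genes in panels.items():
        h = fold_histogram(expression, edges, genes=genes)
        h.insert(0, "panel", panel)
        hist_frames.append(h)
    histograms = pd.concat(hist_frames, ignore_index=True)

    # over-representation for the three query lists
    enrichment: dict[str, pd.DataFrame] = {}
    if config.gmt:
        try:
            raw_sets = mio.read_gmt(config.gmt)
            if config.universe == "counts":
                universe = expression.loc[
                    (expression["count_vector"] + expression["count_mir155"]) > 0,
                    "gene",
                ]
                collection = GeneSetCollection.from_sets(raw_sets, universe)
            else:
                collection = GeneSetCollection.from_sets(raw_sets)
            queries = {
                "up": expression.loc[
                    expression["class_label"] == CLASS_INCREASED, "gene"
                ],
                "down": expression.loc[
                    expression["class_label"] == CLASS_REPRESSED, "gene"
                ],
                "seed_containing": seeded["gene"],
            }
            enrichment = rank_pathways(queries, collection)
            for name, table in enrichment.items():
                top = table.iloc[0]["set_name"] if len(table) else "-"
                logger.info("enrich[%s]: %d sets, top %s", name, len(table), top)
        except Exception as exc:
            raise StageError("enrich", str(exc)) from exc

    metadata = {
        "config": dataclasses.asdict(config),
        "n_genes": int(len(expression)),
        "class_counts": {k: int(v) for k, v in class_counts.items()},
        "n_seed_genes": int(len(seeded)),
        "n_increased_8mer": int(len(increased_8mer)),
    }

    meta_line = "mirescape run"
    paths: dict[str, Path] = {}

    def _emit(name: str, table: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        mio.write_tsv(table, path, metadata=meta_line)
        paths[name] = path

    _emit("sites", sites_table)
    _emit("site_counts", site_counts)
    _emit("expression", expression)
    _emit("shortening", shortening)
    _emit("targets", targets)
    _emit("fold_histogram", histograms)
    for name, table in enrichment.items():
        _emit(f"enrichment_{name}", table)
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=2, default=str) + "\n")
    paths["metadata"] = meta_path

    return ReportBundle(
        sites=sites_table, site_counts=site_counts, expression=expression,
        shortening=shortening, targets=targets, histograms=histograms,
        enrichment=enrichment, metadata=metadata, paths=paths,
    )
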