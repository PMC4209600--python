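"""RPKM expression quantification and fold-change target classification.

A two-condition screen (empty-vector control vs miRNA-overexpressing
line, one library per condition) is summarised gene by gene: RPKM per
condition, fold change (overexpressing / vector), and a class label.

Classes partition the gene universe:

* ``low_read_excluded`` -- raw counts below the read floor (default 10)
  in *both* conditions;
* ``repressed``        -- fold <= 0.5 (inclusive);
* ``increased``        -- fold > 1.5 (strict);
* ``unchanged``        -- everything else.

By default the low-read filter is evaluated first for every gene; with
``filter_scope="increased_only"`` it is applied only to genes that would
otherwise be called ``increased``, reproducing the screen workflow that
drops low-read genes only from the increased-expression cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneCounts",
    "ExpressionRecord",
    "Thresholds",
    "rpkm",
    "fold_change",
    "classify_target",
    "quantify_table",
    "fold_histogram",
    "CLASS_REPRESSED",
    "CLASS_INCREASED",
    "CLASS_UNCHANGED",
    "CLASS_LOW_READ",
]

CLASS_REPRESSED = "repressed"
CLASS_INCREASED = "increased"
CLASS_UNCHANGED = "unchanged"
CLASS_LOW_READ = "low_read_excluded"


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds.

    ``up`` is a strict lower bound for the increased class, ``down`` an
    inclusive upper bound for the repressed class, ``read_floor`` a
    strict raw-count bound below which a gene (in both conditions) is
    excluded as low-read.
    """

    up: float = 1.5
    down: float = 0.5
    read_floor: int = 10


@dataclass(frozen=True)
class GeneCounts:
    gene: str
    raw_count_vector: int
    raw_count_mir155: int
    exon_length_bp: int
    library_vector: int
    library_mir155: int

    def __post_init__(self) -> None:
        if self.exon_length_bp <= 0:
            raise ValueError(f"{self.gene}: exon length must be positive")
        if self.library_vector <= 0 or self.library_mir155 <= 0:
            raise ValueError(f"{self.gene}: library sizes must be positive")
        if self.raw_count_vector < 0 or self.raw_count_mir155 < 0:
            raise ValueError(f"{self.gene}: counts must be non-negative")


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    rpkm_vector: float
    rpkm_mir155: float
    fold_change: float
    class_label: str


def rpkm(raw_count: float, exon_length_bp: float, library_mapped_reads: float) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_length_bp <= 0:
        raise ValueError("exon length must be positive")
    if library_mapped_reads <= 0:
        raise ValueError("library size must be positive")
    return raw_count / (exon_length_bp / 1e3) / (library_mapped_reads / 1e6)


def fold_change(rpkm_mir155: float, rpkm_vector: float, pseudocount: float = 0.0) -> float:
    """(rpkm_mir155 + eps) / (rpkm_vector + eps).

    The pseudocount is opt-in (default 0) so that folds are never
    silently shifted; a zero denominator with eps = 0 raises.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    denom = rpkm_vector + pseudocount
    if denom == 0:
        raise ZeroDivisionError(
            "vector RPKM is 0 and pseudocount is 0; pass pseudocount > 0"
        )
    return (rpkm_mir155 + pseudocount) / denom


def classify_target(
    fold: float,
    raw_count_vector: int,
    raw_count_mir155: int,
    thresholds: Thresholds = Thresholds(),
    filter_scope: str = "all",
) -> str:
    """Assign one class label; see the module docstring for the rules."""
    if filter_scope not in ("all", "increased_only"):
        raise ValueError(f"unknown filter_scope {filter_scope!r}")
    low = (
        raw_count_vector < thresholds.read_floor
        and raw_count_mir155 < thresholds.read_floor
    )
    if filter_scope == "all" and low:
        return CLASS_LOW_READ
    if fold <= thresholds.down:
        return CLASS_REPRESSED
    if fold > thresholds.up:
        return CLASS_LOW_READ if low else CLASS_INCREASED
    return CLASS_UNCHANGED


def quantify_table(
    counts: pd.DataFrame,
    library_vector: int | None = None,
    library_mir155: int | None = None,
    pseudocount: float = 0.0,
    thresholds: Thresholds = Thresholds(),
    filter_scope: str = "all",
) -> pd.DataFrame:
    """Quantify a counts table into an expression table.

    ``counts`` needs columns ``gene``, ``count_vector``, ``count_mir155``
    and ``exon_length_bp``.  Library sizes default to the column sums.
    When several rows share a gene (isoform-level counts), they are
    summed to gene level first, with the length of the longest isoform
    as the gene's exon length.
    """
    required = {"gene", "count_vector", "count_mir155", "exon_length_bp"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if counts["gene"].duplicated().any():
        counts = (
            counts.groupby("gene", sort=False)
            .agg(
                count_vector=("count_vector", "sum"),
                count_mir155=("count_mir155", "sum"),
                exon_length_bp=("exon_length_bp", "max"),
            )
            .reset_index()
        )
    lib_v = int(library_vector or counts["count_vector"].sum())
    lib_m = int(library_mir155 or counts["count_mir155"].sum())
    rpkm_v = np.array(
        [rpkm(c, l, lib_v) for c, l in zip(counts["count_vector"], counts["exon_length_bp"])]
    )
    rpkm_m = np.array(
        [rpkm(c, l, lib_m) for c, l in zip(counts["count_mir155"], counts["exon_length_bp"])]
    )
    # table-level fold policy: with a zero pseudocount, a gene absent from
    # the vector library gets fold inf (nan when absent from both) rather
    # than aborting the whole table; such genes sit under the read floor
    # and are classified low_read_excluded anyway
    with np.errstate(divide="ignore", invalid="ignore"):
        folds = (rpkm_m + pseudocount) / (rpkm_v + pseudocount)
    labels = [
        classify_target(f, cv, cm, thresholds, filter_scope)
        for f, cv, cm in zip(folds, counts["count_vector"], counts["count_mir155"])
    ]
    return pd.DataFrame(
        {
            "gene": counts["gene"].to_numpy(),
            "count_vector": counts["count_vector"].to_numpy(),
            "count_mir155": counts["count_mir155"].to_numpy(),
            "rpkm_vector": rpkm_v,
            "rpkm_mir155": rpkm_m,
            "fold_change": folds,
            "class_label": labels,
        }
    )


def fold_histogram(
    expression: pd.DataFrame,
    bin_edges: Sequence[float],
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Bin fold changes into a gene-count histogram.

    ``genes`` optionally restricts to a subset (e.g. genes with any seed
    site, 8mer-only, or 7mer-only, mirroring the three panels of a
    fold-distribution figure).  Bin counts sum to the number of selected
    genes whose fold falls inside the edges.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    table = expression
    if genes is not None:
        table = table[table["gene"].isin(set(genes))]
    folds = table["fold_change"].to_numpy(dtype=float)
    counts, _ = np.histogram(folds[np.isfinite(folds)], bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_genes": counts}
    )
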