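"""Readers and writers for the text formats the pipeline consumes.

Coordinate conventions: everything is 0-based half-open internally.
BED12/bedGraph are already 0-based half-open; GFF3 is 1-based inclusive
and converted at this boundary.  Minus-strand transcripts are handled
here: extracted UTR sequences are reverse-complemented and coverage
tracks reversed, so downstream modules always see transcript 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "UtrInterval",
    "read_fasta",
    "write_fasta",
    "read_bed12",
    "write_bed12",
    "read_gff3_utrs",
    "extract_utr_sequences",
    "read_bedgraph",
    "project_coverage",
    "write_bedgraph",
    "read_gmt",
    "write_gmt",
    "write_tsv",
    "read_tsv",
]


@dataclass(frozen=True)
class UtrInterval:
    """A transcript's 3'UTR footprint on the genome (0-based half-open).

    ``blocks`` lists (start, end) exon pieces in ascending genomic
    order; single-block UTRs have one entry spanning start..end.
    """

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.blocks:
            object.__setattr__(self, "blocks", ((self.start, self.end),))

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an id -> sequence dict (sequence uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_bed12(path: str | Path) -> list[UtrInterval]:
    """BED12 (or BED6) records describing 3'UTR intervals.

    With 12 columns the block structure is honoured; with 6 the record
    is a single block.
    """
    intervals = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{line_no}: BED needs >= 6 columns")
            chrom, start, end, name, _, strand = fields[:6]
            start, end = int(start), int(end)
            blocks: tuple[tuple[int, int], ...] = ()
            if len(fields) >= 12:
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                blocks = tuple(
                    (start + off, start + off + size)
                    for off, size in zip(offsets, sizes)
                )
            intervals.append(
                UtrInterval(
                    transcript_id=name, chrom=chrom, start=start, end=end,
                    strand=strand, blocks=blocks,
                )
            )
    return intervals


def write_bed12(intervals: Sequence[UtrInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            sizes = ",".join(str(e - s) for s, e in iv.blocks)
            offsets = ",".join(str(s - iv.start) for s, e in iv.blocks)
            handle.write(
                "\t".join(
                    [
                        iv.chrom, str(iv.start), str(iv.end), iv.transcript_id,
                        "0", iv.strand, str(iv.start), str(iv.end), "0",
                        str(len(iv.blocks)), sizes, offsets,
                    ]
                )
                + "\n"
            )


def read_gff3_utrs(path: str | Path, feature: str = "three_prime_UTR") -> list[UtrInterval]:
    """Collect 3'UTR features from a GFF3 file, grouped by Parent.

    GFF3 coordinates are 1-based inclusive and converted to 0-based
    half-open here.  Multi-exon UTRs become multi-block intervals.
    """
    pieces: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{line_no}: GFF3 needs 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != feature:
                continue
            attr_map = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            parent = attr_map.get("Parent") or attr_map.get("ID")
            if parent is None:
                raise ValueError(f"{path}:{line_no}: feature lacks Parent/ID")
            pieces.setdefault(parent, []).append(
                (chrom, int(start) - 1, int(end), strand)
            )
    intervals = []
    for parent, feats in pieces.items():
        feats.sort(key=lambda f: f[1])
        chroms = {f[0] for f in feats}
        strands = {f[3] for f in feats}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{parent}: UTR pieces span chromosomes or strands")
        blocks = tuple((s, e) for _, s, e, _ in feats)
        intervals.append(
            UtrInterval(
                transcript_id=parent, chrom=feats[0][0], start=blocks[0][0],
                end=blocks[-1][1], strand=feats[0][3], blocks=blocks,
            )
        )
    return intervals


_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def extract_utr_sequences(
    genome: Mapping[str, str], intervals: Sequence[UtrInterval]
) -> dict[str, str]:
    """Pull UTR sequences from genomic FASTA, transcript-oriented.

    Blocks are concatenated in genomic order, then the whole sequence is
    reverse-complemented for minus-strand transcripts so every output
    reads 5'->3' of the transcript.
    """
    out = {}
    for iv in intervals:
        if iv.chrom not in genome:
            raise KeyError(f"{iv.transcript_id}: chromosome {iv.chrom!r} not in genome")
        contig = genome[iv.chrom]
        seq = "".join(contig[s:e] for s, e in iv.blocks)
        if iv.strand == "-":
            seq = seq.translate(_DNA_COMPLEMENT)[::-1]
        out[iv.transcript_id] = seq
    return out


def read_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """Parse a bedGraph into per-chromosome (start, end, value) runs."""
    runs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{line_no}: bedGraph needs 4 columns")
            chrom, start, end, value = fields[:4]
            runs.setdefault(chrom, []).append((int(start), int(end), float(value)))
    for chrom in runs:
        runs[chrom].sort(key=lambda r: r[0])
    return runs


def project_coverage(
    runs: Mapping[str, list[tuple[int, int, float]]], interval: UtrInterval
) -> np.ndarray:
    """Per-base coverage over a UTR interval, oriented transcript 5'->3'.

    Positions without a bedGraph run are 0.  Minus-strand intervals are
    reversed after extraction.
    """
    arrays = []
    chrom_runs = runs.get(interval.chrom, [])
    for b_start, b_end in interval.blocks:
        block = np.zeros(b_end - b_start, dtype=float)
        for r_start, r_end, value in chrom_runs:
            lo = max(r_start, b_start)
            hi = min(r_end, b_end)
            if lo < hi:
                block[lo - b_start : hi - b_start] = value
        arrays.append(block)
    cov = np.concatenate(arrays) if arrays else np.zeros(0)
    if interval.strand == "-":
        cov = cov[::-1]
    return cov


def write_bedgraph(
    tracks: Mapping[str, tuple[int, np.ndarray]], path: str | Path
) -> None:
    """Write per-chromosome coverage arrays as run-length bedGraph lines.

    ``tracks`` maps chromosome -> (offset, per-base array in genomic
    orientation); consecutive equal values are collapsed into one run
    and zero runs are omitted.
    """
    with open(path, "w") as handle:
        for chrom in sorted(tracks):
            offset, cov = tracks[chrom]
            cov = np.asarray(cov)
            if cov.size == 0:
                continue
            change = np.flatnonzero(np.diff(cov)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [cov.size]))
            for s, e in zip(starts, ends):
                value = cov[s]
                if value == 0:
                    continue
                value_str = str(int(value)) if float(value).is_integer() else repr(float(value))
                handle.write(f"{chrom}\t{offset + s}\t{offset + e}\t{value_str}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: tab-separated name, description, members."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT needs name, description, >= 1 member"
                )
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, description, *members]) + "\n")


def write_tsv(table: pd.DataFrame, path: str | Path, metadata: str = "") -> None:
    """Tab-separated table with a header row and an optional leading
    ``#``-commented metadata line."""
    with open(path, "w") as handle:
        if metadata:
            handle.write(f"# {metadata}\n")
        table.to_csv(handle, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
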