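"""miRNA seed-site scanning of 3'UTR sequences.

The seed region of a miRNA (positions 2-8, 1-based from the 5' end)
dominates target recognition.  Three canonical site classes are scanned
on the mRNA (sense) strand of a 3'UTR:

* **8mer** -- perfect match to the reverse complement of seed positions
  2-8, followed by an ``A`` opposite miRNA position 1;
* **7mer-m8** -- match to the reverse complement of positions 2-8 only;
* **7mer-A1** -- match to the reverse complement of positions 2-7,
  followed by the ``A`` opposite position 1.

Sites are reported *maximal-type*: a position matching the 8mer motif is
reported once as an 8mer, never additionally as either 7mer class (the
8mer span necessarily contains a 7mer-m8 match at its start and a
7mer-A1 match one base downstream).  Wobble (G:U) pairing, 6mer sites
and context scoring are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MatureMiRNA",
    "SeedMotifSet",
    "SeedSite",
    "SiteCountRecord",
    "MIR155",
    "derive_seed_motifs",
    "scan_utr",
    "count_sites",
]

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_VALID_MIRNA = frozenset("ACGU")
_VALID_UTR = frozenset("ACGUN")

SITE_8MER = "8mer"
SITE_7MER_M8 = "7mer-m8"
SITE_7MER_A1 = "7mer-A1"


def _normalize(sequence: str) -> str:
    """Uppercase and rewrite DNA-style T as U."""
    return sequence.upper().replace("T", "U")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA, 5'->3', RNA alphabet, length >= 8.

    Position indexing is 1-based from the 5' end, the miRNA convention:
    position 1 is the 5'-terminal nucleotide and the seed is positions
    2-8.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = _normalize(self.sequence)
        if len(seq) < 8:
            raise ValueError(
                f"miRNA {self.name!r}: sequence length {len(seq)} < 8; "
                "a full seed (positions 1-8) is required"
            )
        bad = set(seq) - _VALID_MIRNA
        if bad:
            raise ValueError(
                f"miRNA {self.name!r}: invalid characters {sorted(bad)} "
                "(alphabet is ACGU, T accepted as U)"
            )
        object.__setattr__(self, "sequence", seq)


#: The mature miR-155-5p sequence, the packaged default guide.
MIR155 = MatureMiRNA("miR-155-5p", "UUAAUGCUAAUCGUGAUAGGGGU")


@dataclass(frozen=True)
class SeedMotifSet:
    """Target-site motifs, written mRNA-sense 5'->3' in RNA alphabet."""

    motif_8mer: str
    motif_7mer_m8: str
    motif_7mer_A1: str

    def __post_init__(self) -> None:
        if self.motif_8mer != self.motif_7mer_m8 + "A":
            raise ValueError("8mer motif must be the 7mer-m8 motif plus 'A'")
        if self.motif_7mer_A1 != self.motif_7mer_m8[1:] + "A":
            raise ValueError(
                "7mer-A1 motif must be the 3'-most six characters of the "
                "7mer-m8 motif plus 'A'"
            )


@dataclass(frozen=True, order=True)
class SeedSite:
    """A seed-site match on a 3'UTR, 0-based half-open coordinates."""

    transcript_id: str
    start: int
    end: int
    site_type: str

    def __post_init__(self) -> None:
        width = self.end - self.start
        expected = 8 if self.site_type == SITE_8MER else 7
        if width != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} bases, got {width}"
            )


@dataclass(frozen=True)
class SiteCountRecord:
    """Per-gene site tally; 7mer-m8 and 7mer-A1 share one 7mer column."""

    gene: str
    n_7mer: int
    n_8mer: int


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an RNA string (5'->3' in, 5'->3' out)."""
    return _normalize(sequence).translate(_RNA_COMPLEMENT)[::-1]


def derive_seed_motifs(mirna: MatureMiRNA) -> SeedMotifSet:
    """Derive the three canonical target motifs from a mature miRNA.

    The 7mer-m8 motif is the reverse complement of miRNA positions 2-8
    written mRNA-sense 5'->3'; the 8mer appends the ``A`` opposite
    position 1; the 7mer-A1 is the reverse complement of positions 2-7
    followed by that ``A``.
    """
    seed_2_8 = mirna.sequence[1:8]
    m8 = reverse_complement(seed_2_8)
    return SeedMotifSet(
        motif_8mer=m8 + "A",
        motif_7mer_m8=m8,
        motif_7mer_A1=m8[1:] + "A",
    )


def _match_starts(sequence: str, motif: str) -> list[int]:
    """All start offsets where motif occurs exactly (N never matches)."""
    starts = []
    pos = sequence.find(motif)
    while pos != -1:
        starts.append(pos)
        pos = sequence.find(motif, pos + 1)
    return starts


def scan_utr(
    utr_sequence: str,
    motifs: SeedMotifSet,
    transcript_id: str = "",
) -> list[SeedSite]:
    """Scan a 3'UTR (sense strand) for seed sites, maximal type per match.

    ``T`` is normalised to ``U``; ``N`` never matches any motif.  A
    position matching the 8mer is reported once as 8mer; the 7mer-m8
    match at the same start and the 7mer-A1 match one base downstream
    that the 8mer implies are suppressed.  Distinct matches may overlap.
    Output is sorted by start offset.
    """
    seq = _normalize(utr_sequence)
    bad = set(seq) - _VALID_UTR
    if bad:
        raise ValueError(
            f"UTR {transcript_id!r}: invalid characters {sorted(bad)} "
            "(alphabet is ACGUN, T accepted as U)"
        )
    eight_starts = set(_match_starts(seq, motifs.motif_8mer))
    sites: list[SeedSite] = [
        SeedSite(transcript_id, s, s + 8, SITE_8MER) for s in eight_starts
    ]
    m8_taken = set(eight_starts)
    for s in _match_starts(seq, motifs.motif_7mer_m8):
        if s in eight_starts:
            continue  # subsumed by the 8mer at the same start
        m8_taken.add(s)
        sites.append(SeedSite(transcript_id, s, s + 7, SITE_7MER_M8))
    a1_implied = {s + 1 for s in eight_starts}
    for s in _match_starts(seq, motifs.motif_7mer_A1):
        if s in a1_implied:
            continue  # the trailing 7 bases of an 8mer match
        if s in m8_taken and motifs.motif_7mer_A1 == motifs.motif_7mer_m8:
            continue  # degenerate seed where both 7mer motifs coincide
        sites.append(SeedSite(transcript_id, s, s + 7, SITE_7MER_A1))
    sites.sort(key=lambda site: (site.start, site.site_type))
    return sites


def count_sites(
    sites_by_gene: Mapping[str, Iterable[SeedSite]],
    include_7mer_a1: bool = True,
) -> list[SiteCountRecord]:
    """Tally per-gene site counts into disjoint 7mer / 8mer columns.

    Sites are the union over a gene's scanned UTR isoforms, deduplicated
    by (start, end, type).  ``include_7mer_a1=False`` restricts the 7mer
    column to 7mer-m8 sites only.
    """
    records = []
    for gene, sites in sites_by_gene.items():
        unique = {(s.start, s.end, s.site_type) for s in sites}
        n8 = sum(1 for _, _, t in unique if t == SITE_8MER)
        kinds = {SITE_7MER_M8, SITE_7MER_A1} if include_7mer_a1 else {SITE_7MER_M8}
        n7 = sum(1 for _, _, t in unique if t in kinds)
        records.append(SiteCountRecord(gene=gene, n_7mer=n7, n_8mer=n8))
    return records
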