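"""Seed-motif derivation and UTR scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirescape.seedscan import (
    MIR155,
    MatureMiRNA,
    SeedMotifSet,
    SeedSite,
    count_sites,
    derive_seed_motifs,
    scan_utr,
)
from oracles import brute_force_scan


@pytest.mark.parametrize(
    ("sequence", "expected"),
    [
        # miR-155-5p: revcomp of seed positions 2-8, hand-checked
        ("UUAAUGCUAAUCGUGAUAGGGGU", ("AGCAUUAA", "AGCAUUA", "GCAUUAA")),
        # homopolymer symmetry
        ("AAAAAAAA", ("UUUUUUUA", "UUUUUUU", "UUUUUUA")),
        # let-7-style guide, same hand oracle
        ("UGAGGUAGUAGGUUGUAUAGUU", ("CUACCUCA", "CUACCUC", "UACCUCA")),
    ],
)
def test_derive_seed_motifs(sequence, expected):
    motifs = derive_seed_motifs(MatureMiRNA("m", sequence))
    assert (motifs.motif_8mer, motifs.motif_7mer_m8, motifs.motif_7mer_A1) == expected


def test_motifs_accept_dna_alphabet():
    rna = derive_seed_motifs(MatureMiRNA("m", "UUAAUGCUAAUCGUGAUAGGGGU"))
    dna = derive_seed_motifs(MatureMiRNA("m", "TTAATGCTAATCGTGATAGGGGT"))
    assert rna == dna


@pytest.mark.parametrize("bad", ["UUAAUGC", "UUAAUGXUAAU", ""])
def test_invalid_mirna_rejected(bad):
    with pytest.raises(ValueError):
        MatureMiRNA("bad", bad)


def test_motif_set_invariants_enforced():
    with pytest.raises(ValueError):
        SeedMotifSet("AGCAUUAG", "AGCAUUA", "GCAUUAA")
    with pytest.raises(ValueError):
        SeedMotifSet("AGCAUUAA", "AGCAUUA", "GCAUUAG")


class TestScanUtr:
    def test_8mer_reported_once(self, motifs):
        sites = scan_utr("AAGCAUUAAGG", motifs, "tx")
        assert sites == [SeedSite("tx", 1, 9, "8mer")]

    def test_empty_sequence(self, motifs):
        assert scan_utr("", motifs) == []

    def test_trailing_non_a_gives_7mer_m8(self, motifs):
        sites = scan_utr("AGCAUUAG", motifs, "tx")
        assert sites == [SeedSite("tx", 0, 7, "7mer-m8")]

    def test_7mer_a1_alone(self, motifs):
        # GCAUUAA without a preceding A-G context that would complete an 8mer
        sites = scan_utr("CCGCAUUAACC", motifs, "tx")
        assert sites == [SeedSite("tx", 2, 9, "7mer-A1")]

    def test_n_never_matches(self, motifs):
        assert scan_utr("AAGCAUUNAGG", motifs) == []

    def test_t_u_normalization(self, motifs):
        rna = "AAGCAUUAAGGCAGCAUUAG"
        dna = rna.replace("U", "T")
        assert scan_utr(rna, motifs, "x") == scan_utr(dna, motifs, "x")

    def test_invalid_character_rejected(self, motifs):
        with pytest.raises(ValueError, match="tx7"):
            scan_utr("ACGTQ", motifs, "tx7")

    def test_overlapping_sites_both_reported(self, motifs):
        # two 8mers sharing sequence context on a tandem repeat
        seq = "AGCAUUAAGCAUUAA"
        types = [(s.start, s.site_type) for s in scan_utr(seq, motifs)]
        assert (0, "8mer") in types and (7, "8mer") in types

    def test_every_8mer_site_starts_with_m8_motif(self, motifs, small_screen):
        for gene, seq in small_screen.utrs.items():
            norm = seq.replace("T", "U")
            for site in scan_utr(seq, motifs, gene):
                if site.site_type == "8mer":
                    assert norm[site.start : site.start + 7] == motifs.motif_7mer_m8


def test_scan_matches_brute_force_on_random_sequences(motifs):
    rng = np.random.default_rng(55)
    bases = np.array(list("ACGU"))
    for _ in range(300):
        seq = "".join(rng.choice(bases, size=rng.integers(0, 400)))
        got = [(s.start, s.end, s.site_type) for s in scan_utr(seq, motifs)]
        assert got == brute_force_scan(seq, motifs)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGUN", max_size=120), st.text(alphabet="ACGU", min_size=8, max_size=24))
def test_scan_brute_force_property(utr, guide):
    motifs = derive_seed_motifs(MatureMiRNA("g", guide))
    got = [(s.start, s.end, s.site_type) for s in scan_utr(utr, motifs)]
    assert got == brute_force_scan(utr, motifs)


def test_planted_sites_recovered_exactly(motifs, small_screen):
    """The generator's truth table is exactly what the scanner sees."""
    for row in small_screen.truth.itertuples(index=False):
        expected = set()
        if row.sites:
            expected = {
                (item.split(":")[0], int(item.split(":")[1]))
                for item in row.sites.split(";")
            }
        found = {
            (s.site_type, s.start)
            for s in scan_utr(small_screen.utrs[row.gene], motifs)
        }
        assert found == expected, row.gene


class TestCountSites:
    def test_single_8mer(self):
        recs = count_sites({"g": [SeedSite("g", 10, 18, "8mer")]})
        assert (recs[0].n_7mer, recs[0].n_8mer) == (0, 1)

    def test_mixed_classes(self):
        sites = [
            SeedSite("g", 3, 10, "7mer-m8"),
            SeedSite("g", 40, 47, "7mer-A1"),
            SeedSite("g", 100, 108, "8mer"),
        ]
        recs = count_sites({"g": sites})
        assert (recs[0].n_7mer, recs[0].n_8mer) == (2, 1)

    def test_no_sites(self):
        recs = count_sites({"g": []})
        assert (recs[0].n_7mer, recs[0].n_8mer) == (0, 0)

    def test_isoform_union_deduplicated(self):
        # same position seen from two isoforms counts once
        sites = [SeedSite("iso1", 5, 13, "8mer"), SeedSite("iso2", 5, 13, "8mer")]
        recs = count_sites({"g": sites})
        assert recs[0].n_8mer == 1

    def test_7mer_a1_can_be_excluded(self):
        sites = [
            SeedSite("g", 3, 10, "7mer-m8"),
            SeedSite("g", 40, 47, "7mer-A1"),
        ]
        recs = count_sites({"g": sites}, include_7mer_a1=False)
        assert recs[0].n_7mer == 1
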