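"""Changepoint fitting, distal usage, shortening calls, isoform escape."""

import numpy as np
import pytest

from mirescape.apa import (
    ApaParams,
    CoverageTrack,
    IsoformRecord,
    call_shortening,
    distal_usage_index,
    fit_breakpoint,
    seed_escape_fraction,
)
from mirescape.seedscan import SeedSite
from oracles import exhaustive_breakpoint


class TestFitBreakpoint:
    def test_clean_step(self):
        fit = fit_breakpoint([5, 5, 5, 1, 1, 1], minseg=1)
        assert fit.breakpoint == 3
        assert fit.proximal_mean == pytest.approx(5.0)
        assert fit.distal_mean == pytest.approx(1.0)
        assert not fit.flat

    def test_flat_track_flagged(self):
        fit = fit_breakpoint([4, 4, 4, 4, 4, 4], minseg=1)
        assert fit.flat and fit.breakpoint == 1

    def test_minseg_respected(self):
        fit = fit_breakpoint([10, 10, 2, 2, 2, 2], minseg=2)
        assert fit.breakpoint == 2

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            fit_breakpoint([1, 2, 3], minseg=2)

    def test_matches_exhaustive_rss_minimisation(self):
        rng = np.random.default_rng(17)
        for _ in range(120):
            n = int(rng.integers(4, 200))
            minseg = int(rng.integers(1, max(2, n // 4)))
            cov = rng.poisson(5.0, size=n).astype(float)
            if rng.random() < 0.5:  # plant a step in half the tracks
                k = int(rng.integers(minseg, n - minseg + 1))
                cov[k:] = rng.poisson(1.0, size=n - k)
            fit = fit_breakpoint(cov, minseg=minseg)
            k_oracle, rss_oracle, rss_all = exhaustive_breakpoint(cov, minseg)
            impl_rss = rss_all[fit.breakpoint - minseg]
            assert impl_rss <= rss_oracle + 1e-9 * max(1.0, rss_oracle)

    def test_tie_breaks_to_smallest_k(self):
        # symmetric two-level track: both boundary splits minimise RSS
        fit = fit_breakpoint([3, 3, 9, 3, 3], minseg=1)
        _, _, rss_all = exhaustive_breakpoint([3, 3, 9, 3, 3], 1)
        ties = [i + 1 for i, r in enumerate(rss_all) if r <= min(rss_all) + 1e-12]
        assert len(ties) > 1  # the symmetric track really is tied
        assert fit.breakpoint == min(ties)

    def test_raw_detector_scale_invariant(self):
        rng = np.random.default_rng(4)
        cov = rng.poisson(20.0, size=80).astype(float)
        cov[50:] = rng.poisson(3.0, size=30)
        k1 = fit_breakpoint(cov, minseg=5, transform="raw").breakpoint
        k2 = fit_breakpoint(cov * 7.5, minseg=5, transform="raw").breakpoint
        assert k1 == k2


class TestDistalUsageIndex:
    def test_step_track(self):
        assert distal_usage_index([5, 5, 5, 1, 1, 1], 3, 0.0) == pytest.approx(0.2)

    def test_uniform_track_is_one(self):
        assert distal_usage_index([7.0] * 10, 4, 0.0) == pytest.approx(1.0)

    def test_pseudocount_guards_zero_distal(self):
        assert distal_usage_index([2, 2, 0, 0], 2, 0.5) == pytest.approx(0.2)

    def test_breakpoint_out_of_range(self):
        with pytest.raises(ValueError):
            distal_usage_index([1, 2, 3], 3)


def _tracks(gene, vec, mir):
    return (
        CoverageTrack(gene, "vector", np.asarray(vec, dtype=float)),
        CoverageTrack(gene, "mir155", np.asarray(mir, dtype=float)),
    )


class TestCallShortening:
    params = ApaParams(minseg=10, min_track_mean=0.5)

    def test_identical_tracks_not_shortened(self):
        track = np.full(300, 20.0)
        v, m = _tracks("g", track, track)
        call = call_shortening(v, m, [], self.params)
        assert not call.shortened and not call.seed_lost
        assert call.dui_ratio == pytest.approx(1.0)

    def test_step_beyond_seed_loses_site(self):
        vec = np.full(300, 20.0)
        mir = np.full(300, 20.0)
        mir[100:] = 2.0
        v, m = _tracks("g", vec, mir)
        site = SeedSite("g", 150, 158, "8mer")
        call = call_shortening(v, m, [site], self.params)
        assert call.shortened and call.seed_lost
        assert call.breakpoint == 100
        assert call.dui_ratio <= 0.5

    def test_proximal_seed_survives_shortening(self):
        vec = np.full(300, 20.0)
        mir = np.full(300, 20.0)
        mir[100:] = 2.0
        v, m = _tracks("g", vec, mir)
        call = call_shortening(v, m, [SeedSite("g", 10, 18, "8mer")], self.params)
        assert call.shortened and not call.seed_lost

    def test_seed_lost_implies_shortened(self, small_screen, motifs):
        from mirescape.seedscan import scan_utr

        for row in small_screen.truth.itertuples(index=False):
            v, m = _tracks(
                row.gene,
                small_screen.coverage_vector[row.gene],
                small_screen.coverage_mir155[row.gene],
            )
            sites = scan_utr(small_screen.utrs[row.gene], motifs, row.gene)
            call = call_shortening(v, m, sites)
            assert not (call.seed_lost and not call.shortened)

    def test_loss_in_both_lines_annotated(self):
        vec = np.full(300, 20.0)
        vec[100:] = 0.0
        mir = vec.copy()
        v, m = _tracks("g", vec, mir)
        call = call_shortening(v, m, [], self.params)
        assert call.lost_in_both
        assert not call.shortened  # ratio is ~1: loss present in both lines

    def test_low_coverage_is_qc_failure(self):
        v, m = _tracks("g", np.full(300, 0.1), np.full(300, 20.0))
        call = call_shortening(v, m, [], ApaParams(min_track_mean=1.0))
        assert call.qc_fail and call.breakpoint is None and not call.shortened

    def test_length_mismatch_names_transcript(self):
        v, m = _tracks("tx99", np.ones(100), np.ones(101))
        with pytest.raises(ValueError, match="tx99"):
            call_shortening(v, m, [])

    def test_min_proximal_mean_vetoes_noise_calls(self):
        vec = np.full(300, 1.0)
        mir = np.full(300, 1.0)
        mir[100:] = 0.0
        v, m = _tracks("g", vec, mir)
        call = call_shortening(v, m, [], ApaParams(min_proximal_mean=5.0, min_track_mean=0.1))
        assert not call.shortened


class TestSeedEscapeFraction:
    def test_all_isoforms_carry_seed(self):
        isos = [IsoformRecord("i1", "g", 3.0, True), IsoformRecord("i2", "g", 1.0, True)]
        assert seed_escape_fraction(isos) == 0.0

    def test_no_isoform_carries_seed(self):
        isos = [IsoformRecord("i1", "g", 2.0, False)]
        assert seed_escape_fraction(isos) == 1.0

    def test_truncated_variant_share(self):
        isos = [
            IsoformRecord("i1", "g", 3.0, True),
            IsoformRecord("i2", "g", 0.0, True),
            IsoformRecord("i3", "g", 1.0, False),
        ]
        assert seed_escape_fraction(isos) == pytest.approx(0.25)

    def test_zero_total_expression_signalled(self):
        with pytest.raises(ValueError):
            seed_escape_fraction([IsoformRecord("i1", "g", 0.0, True)])
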