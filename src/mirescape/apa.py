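"""3'UTR-shortening detection from per-base coverage, and seed-site loss.

Use of a proximal alternative polyadenylation (APA) site truncates the
3'UTR and can delete miRNA seed sites, letting a target escape
repression.  In a browser, shortening shows up as a step drop in read
pile-up partway along the UTR of the overexpressing condition.  This
module formalises that read-off in the DaPars tradition:

1. fit a two-segment piecewise-constant changepoint (least squares on
   log2(coverage + 1)) to the miRNA-condition track;
2. compute the distal usage index (DUI) -- mean coverage distal to the
   breakpoint over mean coverage proximal -- for both conditions at the
   same split;
3. call the transcript *shortened* when the between-condition DUI ratio
   (miRNA / vector) falls to tau (default 0.5) or below, with adequate
   proximal coverage and a non-degenerate fit;
4. call the *seed site lost* when a shortened transcript has a seed
   site lying entirely at or beyond the breakpoint.

There is one library per condition, so no replicate-based test of DUI
differences is attempted; the thresholds are effect-size cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seedscan import SeedSite

__all__ = [
    "CoverageTrack",
    "BreakpointFit",
    "ShorteningCall",
    "ApaParams",
    "IsoformRecord",
    "fit_breakpoint",
    "distal_usage_index",
    "call_shortening",
    "seed_escape_fraction",
]


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base read coverage over a 3'UTR, oriented 5'->3' of the transcript."""

    transcript_id: str
    condition: str
    coverage: np.ndarray

    def __post_init__(self) -> None:
        cov = np.asarray(self.coverage, dtype=float)
        if cov.ndim != 1:
            raise ValueError("coverage must be one-dimensional")
        if np.any(cov < 0):
            raise ValueError(f"{self.transcript_id}: negative coverage values")
        object.__setattr__(self, "coverage", cov)

    def __len__(self) -> int:
        return len(self.coverage)


@dataclass(frozen=True)
class BreakpointFit:
    """Result of the two-segment changepoint fit.

    ``breakpoint`` is the 0-based offset of the first distal base.
    ``proximal_mean`` / ``distal_mean`` are raw-scale coverage means.
    ``flat`` marks degenerate tracks where every split has equal RSS.
    """

    breakpoint: int
    proximal_mean: float
    distal_mean: float
    rss: float
    flat: bool


@dataclass(frozen=True)
class ApaParams:
    """Tunable thresholds for shortening calls.

    ``tau``: max DUI ratio (miRNA/vector) for a shortened call.
    ``min_proximal_mean``: min raw proximal mean coverage in the miRNA
    track (reads); guards calls made from noise over a dead transcript.
    ``minseg``: min bases in each segment; ``None`` -> min(25, L // 10).
    ``epsilon``: pseudocount in the DUI (guards zero proximal coverage).
    ``min_track_mean``: QC floor on overall mean coverage of each track.
    ``lost_in_both_cutoff``: absolute DUI at or below which the *vector*
    track itself is considered already shortened (distal loss present in
    both lines, so the between-condition ratio is blind to it).
    """

    tau: float = 0.5
    min_proximal_mean: float = 5.0
    minseg: int | None = None
    epsilon: float = 0.5
    min_track_mean: float = 1.0
    lost_in_both_cutoff: float = 0.1

    def resolve_minseg(self, length: int) -> int:
        if self.minseg is not None:
            return self.minseg
        return max(1, min(25, length // 10))


@dataclass(frozen=True)
class ShorteningCall:
    gene: str
    breakpoint: int | None
    proximal_mean_vector: float
    distal_mean_vector: float
    proximal_mean_mir155: float
    distal_mean_mir155: float
    dui_vector: float
    dui_mir155: float
    dui_ratio: float
    shortened: bool
    seed_lost: bool
    lost_in_both: bool
    qc_fail: bool
    qc_reason: str = ""


@dataclass(frozen=True)
class IsoformRecord:
    """One expressed isoform of a gene; ``contains_seed_utr`` flags
    whether its 3'UTR carries the seed site."""

    isoform_id: str
    gene: str
    expression: float
    contains_seed_utr: bool

    def __post_init__(self) -> None:
        if self.expression < 0:
            raise ValueError(f"{self.isoform_id}: expression must be >= 0")


_FLAT_RTOL = 1e-9


def fit_breakpoint(
    coverage: Sequence[float], minseg: int = 1, transform: str = "log2"
) -> BreakpointFit:
    """Two-segment least-squares changepoint on log2(coverage + 1).

    Minimises, over split offsets ``k`` with ``minseg <= k <= L - minseg``,
    the residual sum of squares of a piecewise-constant fit with segments
    ``[0, k)`` and ``[k, L)``.  Ties break to the smallest ``k``; a track
    where every split gives equal RSS (e.g. constant coverage) is
    flagged ``flat`` and reported at ``k = minseg``.  Segment means are
    reported on the raw coverage scale.

    ``transform="log2"`` (default) stabilises the variance of
    high-coverage tracks; ``transform="raw"`` fits the untransformed
    counts, which makes the fitted breakpoint exactly invariant to
    scaling the track by a positive constant.
    """
    cov = np.asarray(coverage, dtype=float)
    if minseg < 1:
        raise ValueError("minseg must be >= 1")
    if transform not in ("log2", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    n = len(cov)
    if n < 2 * minseg:
        raise ValueError(
            f"track length {n} is shorter than two segments of {minseg}"
        )
    y = np.log2(cov + 1.0) if transform == "log2" else cov
    # prefix sums give each candidate split's RSS in O(1):
    # RSS(k) = sum(y^2) - S1(k)^2/k - (S1(n)-S1(k))^2/(n-k)
    c1 = np.cumsum(y)
    c2 = np.cumsum(y * y)
    ks = np.arange(minseg, n - minseg + 1)
    left_sum = c1[ks - 1]
    left_sq = c2[ks - 1]
    right_sum = c1[-1] - left_sum
    right_sq = c2[-1] - left_sq
    rss = (left_sq - left_sum**2 / ks) + (right_sq - right_sum**2 / (n - ks))
    best = int(np.argmin(rss))  # argmin takes the first minimum: smallest k
    k = int(ks[best])
    spread = float(rss.max() - rss.min())
    flat = spread <= _FLAT_RTOL * max(1.0, float(np.abs(rss).max()))
    if flat:
        k = minseg
        best = 0
    return BreakpointFit(
        breakpoint=k,
        proximal_mean=float(cov[:k].mean()),
        distal_mean=float(cov[k:].mean()),
        rss=float(max(rss[best], 0.0)),
        flat=flat,
    )


def distal_usage_index(
    coverage: Sequence[float], breakpoint: int, epsilon: float = 0.5
) -> float:
    """(mean distal coverage + eps) / (mean proximal coverage + eps)."""
    cov = np.asarray(coverage, dtype=float)
    if not 0 < breakpoint < len(cov):
        raise ValueError(f"breakpoint {breakpoint} outside (0, {len(cov)})")
    return (cov[breakpoint:].mean() + epsilon) / (cov[:breakpoint].mean() + epsilon)


def call_shortening(
    track_vector: CoverageTrack,
    track_mir155: CoverageTrack,
    seed_sites: Sequence[SeedSite],
    params: ApaParams = ApaParams(),
) -> ShorteningCall:
    """Call 3'UTR shortening and seed-site loss for one transcript.

    The breakpoint is fitted on the miRNA-condition track (the condition
    expected to exhibit shortening) and the same split is applied to the
    vector track.  QC failure (too-short or too-shallow tracks) yields a
    no-call row with ``qc_fail=True``.
    """
    gene = track_mir155.transcript_id
    if len(track_vector) != len(track_mir155):
        raise ValueError(
            f"{gene}: track lengths differ "
            f"({len(track_vector)} vs {len(track_mir155)})"
        )
    n = len(track_mir155)
    minseg = params.resolve_minseg(n)

    def _no_call(reason: str) -> ShorteningCall:
        return ShorteningCall(
            gene=gene, breakpoint=None,
            proximal_mean_vector=float("nan"), distal_mean_vector=float("nan"),
            proximal_mean_mir155=float("nan"), distal_mean_mir155=float("nan"),
            dui_vector=float("nan"), dui_mir155=float("nan"),
            dui_ratio=float("nan"),
            shortened=False, seed_lost=False, lost_in_both=False,
            qc_fail=True, qc_reason=reason,
        )

    if n < 2 * minseg:
        return _no_call(f"track length {n} < 2 x minseg {minseg}")
    mean_v = float(track_vector.coverage.mean())
    mean_m = float(track_mir155.coverage.mean())
    if mean_v < params.min_track_mean or mean_m < params.min_track_mean:
        return _no_call(
            f"mean coverage below floor {params.min_track_mean} "
            f"(vector {mean_v:.2f}, miR {mean_m:.2f})"
        )

    fit = fit_breakpoint(track_mir155.coverage, minseg=minseg)
    k = fit.breakpoint
    dui_m = distal_usage_index(track_mir155.coverage, k, params.epsilon)
    dui_v = distal_usage_index(track_vector.coverage, k, params.epsilon)
    dui_ratio = dui_m / dui_v
    shortened = (
        dui_ratio <= params.tau
        and fit.proximal_mean >= params.min_proximal_mean
        and not fit.flat
    )
    seed_lost = shortened and any(site.start >= k for site in seed_sites)
    lost_in_both = dui_v <= params.lost_in_both_cutoff
    cov_v = track_vector.coverage
    return ShorteningCall(
        gene=gene,
        breakpoint=k,
        proximal_mean_vector=float(cov_v[:k].mean()),
        distal_mean_vector=float(cov_v[k:].mean()),
        proximal_mean_mir155=fit.proximal_mean,
        distal_mean_mir155=fit.distal_mean,
        dui_vector=dui_v,
        dui_mir155=dui_m,
        dui_ratio=dui_ratio,
        shortened=shortened,
        seed_lost=seed_lost,
        lost_in_both=lost_in_both,
        qc_fail=False,
    )


def seed_escape_fraction(isoforms: Sequence[IsoformRecord]) -> float:
    """Fraction of a gene's expression on isoforms whose 3'UTR lacks the seed.

    Truncated isoform variants that do not carry the targeted 3'UTR
    escape repression; this is their expression share.  Raises when
    total expression is zero (the fraction is undefined).
    """
    total = sum(iso.expression for iso in isoforms)
    if total <= 0:
        raise ValueError("total isoform expression is 0; escape fraction undefined")
    escaped = sum(iso.expression for iso in isoforms if not iso.contains_seed_utr)
    return escaped / total
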