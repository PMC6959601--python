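"""Enrichment of peak sets in genomic contexts (repeats, enhancers, open chromatin).

The counting unit is the peak: a 2x2 table cross-classifies a focus set and an
explicit background/universe set by >=1 bp overlap with an annotation track.
Odds ratios use the Haldane-Anscombe +0.5 correction only when a cell is zero,
with Woolf's standard error on the (corrected) log odds ratio, and a two-sided
Fisher exact p-value computed by tail-probability summation. A chi-squared
test (no continuity correction) compares two cistrome-shift site sets over a
shared universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, PeakSet, overlap_membership

__all__ = [
    "AnnotationTrack",
    "OddsRatioResult",
    "OverlapFraction",
    "cistrome_overlap_test",
    "fisher_exact_two_sided",
    "fraction_overlapping",
    "odds_ratio_overlap",
    "odds_ratio_from_table",
    "windowed_profile",
]


@dataclass(frozen=True)
class AnnotationTrack:
    """A labeled interval track (e.g. MIR, enhancer, super_enhancer, HOT, DNase_open)."""

    label: str
    intervals: PeakSet

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("annotation label must be non-empty")


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 overlap table with odds ratio, Woolf SE, 95% CI, and exact p."""

    label: str
    a: int  # focus peaks overlapping the annotation
    b: int  # focus peaks not overlapping
    c: int  # background peaks overlapping
    d: int  # background peaks not overlapping
    odds_ratio: float
    log_or_se: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool  # True when the Haldane-Anscombe +0.5 was applied
    window: int | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "window": self.window,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "odds_ratio": self.odds_ratio,
            "log_or_se": self.log_or_se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "corrected": self.corrected,
        }


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric tail probabilities <= P(obs)."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def odds_ratio_from_table(
    a: int, b: int, c: int, d: int, label: str = "", window: int | None = None
) -> OddsRatioResult:
    """Build an :class:`OddsRatioResult` from raw 2x2 counts.

    The exact p always uses the raw counts; OR, SE, and CI use +0.5-corrected
    cells iff any raw cell is zero.
    """
    corrected = 0 in (a, b, c, d)
    shift = 0.5 if corrected else 0.0
    ca, cb, cc, cd = (x + shift for x in (a, b, c, d))
    odds = (ca * cd) / (cb * cc)
    se = math.sqrt(1 / ca + 1 / cb + 1 / cc + 1 / cd)
    z = stats.norm.ppf(0.975)
    ci_low = odds * math.exp(-z * se)
    ci_high = odds * math.exp(z * se)
    p = fisher_exact_two_sided(a, b, c, d)
    return OddsRatioResult(
        label, a, b, c, d, odds, se, ci_low, ci_high, p, corrected, window
    )


def odds_ratio_overlap(
    focus: PeakSet,
    annotation: AnnotationTrack,
    background: PeakSet,
    window: int | None = None,
) -> OddsRatioResult:
    """Per-peak enrichment of ``focus`` in an annotation against a background set."""
    if len(focus) == 0 or len(background) == 0:
        raise ValueError("focus and background must be non-empty")
    hit_f = overlap_membership(focus, [annotation.intervals])[:, 0]
    hit_b = overlap_membership(background, [annotation.intervals])[:, 0]
    a = int(hit_f.sum())
    b = len(focus) - a
    c = int(hit_b.sum())
    d = len(background) - c
    return odds_ratio_from_table(a, b, c, d, label=annotation.label, window=window)


def _expand_to_window(peaks: PeakSet, window: int) -> PeakSet:
    half = window // 2
    ivs = []
    for iv in peaks:
        summit = iv.summit_pos
        start = max(0, summit - half)
        end = summit + window - half
        if peaks.layout is not None:
            end = min(end, peaks.layout.length(iv.chrom))
        ivs.append(GenomicInterval(iv.chrom, start, end, name=iv.name))
    return PeakSet(peaks.name, ivs, peaks.layout)


def windowed_profile(
    peaks: PeakSet,
    annotation: AnnotationTrack,
    windows: Sequence[int],
    background: PeakSet,
) -> list[OddsRatioResult]:
    """Odds ratios after expanding every peak (focus and background alike) to
    summit +- window/2, one result per window size.

    Expanding both sets keeps the null calibrated: a uniformly placed
    annotation yields OR ~ 1 at every window, while proximity planted around
    focus summits shows enrichment that decays as the window grows.
    """
    if any(w <= 0 for w in windows):
        raise ValueError("window sizes must be positive")
    if list(windows) != sorted(windows):
        raise ValueError("windows must be sorted ascending")
    return [
        odds_ratio_overlap(
            _expand_to_window(peaks, w),
            annotation,
            _expand_to_window(background, w),
            window=w,
        )
        for w in windows
    ]


class OverlapFraction(NamedTuple):
    numerator: int
    denominator: int
    percent: float
    percent_rounded: int


def fraction_overlapping(peaks: PeakSet, annotation: AnnotationTrack) -> OverlapFraction:
    """Fraction of peaks overlapping an annotation, with round-half-up percent."""
    if len(peaks) == 0:
        raise ValueError("empty PeakSet")
    hits = overlap_membership(peaks, [annotation.intervals])[:, 0]
    num = int(hits.sum())
    den = len(peaks)
    percent = 100.0 * num / den
    return OverlapFraction(num, den, percent, int(math.floor(percent + 0.5)))


def cistrome_overlap_test(
    gained_a: PeakSet, gained_b: PeakSet, universe: PeakSet
) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) for association of
    two gained-site sets over a shared universe of regions.

    Every member of both gained sets must overlap some universe region; the
    universe regions are cross-classified by membership in A and B.
    """
    member = overlap_membership(universe, [gained_a, gained_b])
    in_a, in_b = member[:, 0], member[:, 1]
    for peaks, hit_count, tag in (
        (gained_a, in_a, "A"),
        (gained_b, in_b, "B"),
    ):
        covered = overlap_membership(peaks, [universe])[:, 0]
        if not covered.all():
            raise ValueError(
                f"{int((~covered).sum())} peaks of set {tag} overlap no universe region"
            )
    n = len(universe)
    a = int((in_a & in_b).sum())
    b = int((in_a & ~in_b).sum())
    c = int((~in_a & in_b).sum())
    d = n - a - b - c
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise ValueError("degenerate margins: a set is empty or covers the universe")
    statistic = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def results_to_frame(results: Sequence[OddsRatioResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
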