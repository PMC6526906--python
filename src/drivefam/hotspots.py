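"""Enrichment of meiotic DSB hotspots near family loci.

Because nonallelic gene conversion is initiated by double-strand breaks,
proximity of family loci to mapped meiotic DSB hotspots is a candidate
mechanism for their elevated conversion rates.  This module measures the
distance from each end of a locus coding span to the nearest hotspot
interval, builds distance-threshold contingency tables against a
genome-wide background (all coding sequences), and tests enrichment with
Pearson chi-square, Yates-corrected chi-square, and a two-sided exact
Fisher test computed by direct hypergeometric summation (the printed
analyses do not name their test, so all three are reported).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import Interval


@dataclass
class HotspotSet:
    """Sorted hotspot intervals per chromosome."""

    intervals: list[Interval]
    _by_chrom: dict[str, tuple[list[int], list[int]]] = field(init=False)

    def __post_init__(self) -> None:
        by: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by.setdefault(iv.chrom, []).append(iv)
        self._by_chrom = {}
        for chrom, ivs in by.items():
            ivs.sort(key=lambda v: v.start)
            self._by_chrom[chrom] = ([v.start for v in ivs],
                                     [v.end for v in ivs])

    def __len__(self) -> int:
        return len(self.intervals)


def nearest_hotspot_distance(chrom: str, pos: int,
                             hotspots: HotspotSet) -> float:
    """Distance (bp) from a point to the nearest hotspot interval.

    Zero if the point lies inside a hotspot; +inf when the chromosome has
    no hotspot (the point is then excludable from downstream counts).
    Distance to an interval is measured to its nearest covered base.
    """
    entry = hotspots._by_chrom.get(chrom)
    if entry is None:
        return math.inf
    starts, ends = entry
    i = bisect_right(starts, pos) - 1
    best = math.inf
    if i >= 0:
        if pos < ends[i]:
            return 0.0
        best = pos - (ends[i] - 1)
    if i + 1 < len(starts):
        best = min(best, starts[i + 1] - pos)
    return float(best)


@dataclass(frozen=True)
class CdsEndPoint:
    chrom: str
    pos: int
    locus_id: str
    side: str  # '5prime' | '3prime'
    excluded: bool = False


def locus_end_points(cds_spans: Sequence[Interval]) -> list[CdsEndPoint]:
    """Both ends of each locus coding span as candidate data points."""
    pts = []
    for iv in cds_spans:
        pts.append(CdsEndPoint(iv.chrom, iv.start, iv.name, "5prime"))
        pts.append(CdsEndPoint(iv.chrom, iv.end - 1, iv.name, "3prime"))
    return pts


def end_distances(cds_spans: Sequence[Interval], hotspots: HotspotSet
                  ) -> list[tuple[CdsEndPoint, float]]:
    """Nearest-hotspot distance per CDS end; infinite distances are flagged
    excluded (no hotspot available on that chromosome side)."""
    out = []
    for pt in locus_end_points(cds_spans):
        d = nearest_hotspot_distance(pt.chrom, pt.pos, hotspots)
        if math.isinf(d):
            pt = CdsEndPoint(pt.chrom, pt.pos, pt.locus_id, pt.side, True)
        out.append((pt, d))
    return out


# --- contingency tables and tests --------------------------------------------

@dataclass
class ContingencyTable:
    """2x2 threshold table: rows are groups, columns <=t vs >t."""

    a: int  # group1 <= threshold
    b: int  # group1 > threshold
    c: int  # group2 <= threshold
    d: int  # group2 > threshold
    threshold: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def proportions(self) -> tuple[float, float]:
        return (self.a / (self.a + self.b), self.c / (self.c + self.d))


def make_contingency(distances_group1: Sequence[float],
                     distances_group2: Sequence[float],
                     threshold: float) -> ContingencyTable:
    """Count distances <= / > threshold per group (infinite excluded)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    g1 = [d for d in distances_group1 if math.isfinite(d)]
    g2 = [d for d in distances_group2 if math.isfinite(d)]
    if not g1 or not g2:
        raise ValueError("empty distance group after exclusions")
    a = sum(d <= threshold for d in g1)
    c = sum(d <= threshold for d in g2)
    return ContingencyTable(a, len(g1) - a, c, len(g2) - c, threshold)


@dataclass
class EnrichmentResult:
    method: str
    statistic: Optional[float]
    p_value: float
    proportions: tuple[float, float]
    warning: Optional[str] = None


def fisher_exact_pvalue(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by hypergeometric summation.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table (with a small
    relative tolerance against floating-point ties).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    M = a + b + c + d
    n_row1 = a + b
    n_col1 = a + c
    rv = stats.hypergeom(M, n_row1, n_col1)
    kmin = max(0, n_row1 + n_col1 - M)
    kmax = min(n_row1, n_col1)
    ks = np.arange(kmin, kmax + 1)
    pmf = rv.pmf(ks)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def enrichment_test(table: ContingencyTable, method: str = "all"
                    ) -> list[EnrichmentResult]:
    """Association tests on a 2x2 table; method in {chi2, chi2_yates,
    fisher, all}.  A warning is attached when any expected count is < 5."""
    arr = np.array([[table.a, table.b], [table.c, table.d]])
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = stats.contingency.expected_freq(arr)
    warn = "expected count < 5" if (expected < 5).any() else None
    props = table.proportions
    out = []
    wanted = ("chi2", "chi2_yates", "fisher") if method == "all" else (method,)
    for m in wanted:
        if m == "chi2":
            if arr.min() == arr.max():
                stat, p = 0.0, 1.0
            else:
                res = stats.chi2_contingency(arr, correction=False)
                stat, p = float(res.statistic), float(res.pvalue)
            out.append(EnrichmentResult("chi2", stat, p, props, warn))
        elif m == "chi2_yates":
            res = stats.chi2_contingency(arr, correction=True)
            out.append(EnrichmentResult("chi2_yates", float(res.statistic),
                                        float(res.pvalue), props, warn))
        elif m == "fisher":
            out.append(EnrichmentResult("fisher", None,
                                        fisher_exact_pvalue(table), props,
                                        warn))
        else:
            raise ValueError(f"unknown method {m!r}")
    return out


def locus_hotspot_summary(cds_spans: Sequence[Interval], hotspots: HotspotSet,
                          threshold: float = 2500) -> int:
    """Number of loci with >= 1 hotspot within ``threshold`` of a CDS end
    (a hotspot overlapping the span itself also counts)."""
    if not cds_spans:
        raise ValueError("no loci supplied")
    count = 0
    for iv in cds_spans:
        d5 = nearest_hotspot_distance(iv.chrom, iv.start, hotspots)
        d3 = nearest_hotspot_distance(iv.chrom, iv.end - 1, hotspots)
        overlap = any(
            math.isfinite(d) and d == 0 for d in (d5, d3)) or _span_overlap(
            iv, hotspots)
        if overlap or min(d5, d3) <= threshold:
            count += 1
    return count


def _span_overlap(iv: Interval, hotspots: HotspotSet) -> bool:
    entry = hotspots._by_chrom.get(iv.chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = bisect_right(starts, iv.end - 1) - 1
    return i >= 0 and ends[i] > iv.start
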