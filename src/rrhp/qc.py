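"""Replicate and cross-sample statistics on site counts.

Covers the standard QC views of a positive-display 5hmC library: the per-site read
coverage distribution, Pearson correlation and site-set overlap between replicate
libraries, the forward/reverse strand asymmetry screen, and a paired differential
ranking for tumor/normal style comparisons.

Depth caveat: read totals are themselves a function of 5hmC abundance in a positive
display, so libraries compared here should be sequenced to comparable depth; no
depth normalization is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .profiler import SiteCounts

__all__ = [
    "CoverageHistogram",
    "ComparisonReport",
    "AsymmetryParams",
    "coverage_histogram",
    "correlate",
    "overlap",
    "compare_report",
    "strand_asymmetry",
    "compare_paired",
]


@dataclass
class CoverageHistogram:
    """Read-count frequency distribution over detected sites."""

    counts: dict[int, int]  # total reads at a site -> number of such sites

    @property
    def n_sites(self) -> int:
        return sum(self.counts.values())

    def fraction_below(self, k: int) -> float:
        below = sum(n for total, n in self.counts.items() if total < k)
        return below / self.n_sites

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items())
        return pd.DataFrame(rows, columns=["reads", "n_sites"])


def coverage_histogram(counts: SiteCounts) -> CoverageHistogram:
    """Histogram of total per-site read counts over sites with at least one read."""
    totals = [t for t in counts.totals().values() if t >= 1]
    if not totals:
        raise ValueError("no detected sites: cannot build a coverage histogram")
    hist: dict[int, int] = {}
    for t in totals:
        hist[t] = hist.get(t, 0) + 1
    return CoverageHistogram(hist)


def _universe(a: SiteCounts, b: SiteCounts, universe: str) -> list[tuple[str, int]]:
    if universe == "union":
        keys = a.sites() | b.sites()
    elif universe == "intersection":
        keys = a.sites() & b.sites()
    else:
        raise ValueError(f"universe must be 'union' or 'intersection', got {universe!r}")
    return sorted(keys)


def correlate(
    a: SiteCounts,
    b: SiteCounts,
    universe: str = "union",
    min_count: int = 0,
    binary: bool = False,
) -> float:
    """Pearson correlation of per-site totals between two libraries.

    Absent sites count 0 under the union universe.  When ``min_count > 0``, sites
    where both libraries fall below it are excluded.  ``binary`` correlates
    presence/absence instead of counts.  Returns NaN when fewer than two sites
    remain or either vector has zero variance.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both libraries must contain at least one site")
    ta, tb = a.totals(), b.totals()
    keys = _universe(a, b, universe)
    if min_count > 0:
        keys = [k for k in keys if ta.get(k, 0) >= min_count or tb.get(k, 0) >= min_count]
    x = np.array([ta.get(k, 0) for k in keys], dtype=float)
    y = np.array([tb.get(k, 0) for k in keys], dtype=float)
    if binary:
        x = (x > 0).astype(float)
        y = (y > 0).astype(float)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _quartiles(values: list[int]) -> dict[str, float]:
    if not values:
        return {"n": 0, "q1": math.nan, "median": math.nan, "q3": math.nan}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"n": len(values), "q1": float(q1), "median": float(med), "q3": float(q3)}


@dataclass
class OverlapResult:
    n_common: int
    n_unique_a: int
    n_unique_b: int
    common_a_summary: dict = field(default_factory=dict)
    common_b_summary: dict = field(default_factory=dict)
    unique_a_summary: dict = field(default_factory=dict)
    unique_b_summary: dict = field(default_factory=dict)


def overlap(a: SiteCounts, b: SiteCounts, min_count: int = 0) -> OverlapResult:
    """Site-set Venn between two libraries at threshold ``total >= max(1, min_count)``.

    Also summarizes (quartiles) the read counts of overlapping versus
    library-unique sites, the diagnostic that shows non-reproducible sites sit in
    the low-count tail.
    """
    thr = max(1, min_count)
    ta = {k: t for k, t in a.totals().items() if t >= thr}
    tb = {k: t for k, t in b.totals().items() if t >= thr}
    common = set(ta) & set(tb)
    only_a = set(ta) - set(tb)
    only_b = set(tb) - set(ta)
    return OverlapResult(
        n_common=len(common),
        n_unique_a=len(only_a),
        n_unique_b=len(only_b),
        common_a_summary=_quartiles([ta[k] for k in common]),
        common_b_summary=_quartiles([tb[k] for k in common]),
        unique_a_summary=_quartiles([ta[k] for k in only_a]),
        unique_b_summary=_quartiles([tb[k] for k in only_b]),
    )


@dataclass
class ComparisonReport:
    """Replicate comparison: correlation, overlap, and low-count diagnostics."""

    pearson_r: float
    n_common: int
    n_unique_a: int
    n_unique_b: int
    common_a_summary: dict
    common_b_summary: dict
    unique_a_summary: dict
    unique_b_summary: dict
    unique_below_threshold_fraction: float
    low_count_threshold: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, allow_nan=True)
            fh.write("\n")


def compare_report(
    a: SiteCounts,
    b: SiteCounts,
    universe: str = "union",
    min_count: int = 0,
    low_count_threshold: int = 3,
) -> ComparisonReport:
    """Full replicate comparison combining :func:`correlate` and :func:`overlap`."""
    r = correlate(a, b, universe=universe, min_count=min_count)
    ov = overlap(a, b, min_count=min_count)
    ta, tb = a.totals(), b.totals()
    thr = max(1, min_count)
    uniq_counts = [t for k, t in ta.items() if t >= thr and tb.get(k, 0) < thr]
    uniq_counts += [t for k, t in tb.items() if t >= thr and ta.get(k, 0) < thr]
    below = (
        sum(1 for t in uniq_counts if t < low_count_threshold) / len(uniq_counts)
        if uniq_counts
        else float("nan")
    )
    return ComparisonReport(
        pearson_r=r,
        n_common=ov.n_common,
        n_unique_a=ov.n_unique_a,
        n_unique_b=ov.n_unique_b,
        common_a_summary=ov.common_a_summary,
        common_b_summary=ov.common_b_summary,
        unique_a_summary=ov.unique_a_summary,
        unique_b_summary=ov.unique_b_summary,
        unique_below_threshold_fraction=below,
        low_count_threshold=low_count_threshold,
    )


@dataclass
class AsymmetryParams:
    """Strand-asymmetry screen settings.

    ``fold_threshold`` flags sites where the stronger strand carries at least that
    multiple of the weaker strand's raw count (a zero weaker strand flags whenever
    the stronger reaches the threshold); ``pseudocount`` only stabilizes the
    reported log2 ratio.
    """

    fold_threshold: float = 2.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def strand_asymmetry(
    counts: SiteCounts, params: AsymmetryParams | None = None
) -> pd.DataFrame:
    """Per-site forward/reverse log2 ratio and two-fold-style asymmetry flag.

    Returns a DataFrame with columns contig, pos, fwd_reads, rev_reads,
    log2_ratio = log2((fwd + pc) / (rev + pc)), and ``flagged`` computed on raw
    counts: max(fwd, rev) >= fold_threshold * min(fwd, rev), with a zero minimum
    flagging iff max >= fold_threshold.
    """
    params = params or AsymmetryParams()
    rows = []
    for (contig, pos), (fwd, rev) in counts.items():
        ratio = math.log2((fwd + params.pseudocount) / (rev + params.pseudocount))
        lo, hi = min(fwd, rev), max(fwd, rev)
        flagged = hi >= params.fold_threshold * lo if lo > 0 else hi >= params.fold_threshold
        rows.append(
            {"contig": contig, "pos": pos, "fwd_reads": fwd, "rev_reads": rev,
             "log2_ratio": ratio, "flagged": bool(flagged)}
        )
    return pd.DataFrame(
        rows, columns=["contig", "pos", "fwd_reads", "rev_reads", "log2_ratio", "flagged"]
    )


def compare_paired(a: SiteCounts, b: SiteCounts, top_n: int) -> pd.DataFrame:
    """Rank sites by absolute read-count difference between two paired libraries.

    Sites absent from one library count 0 there.  Ties break by (contig, pos).
    The ranking is a plain difference of raw counts — callers are responsible for
    comparable sequencing depth, and no significance test is implied.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    ta, tb = a.totals(), b.totals()
    rows = []
    for key in set(ta) | set(tb):
        xa, xb = ta.get(key, 0), tb.get(key, 0)
        rows.append(
            {"contig": key[0], "pos": key[1], "count_a": xa, "count_b": xb,
             "difference": xa - xb}
        )
    rows.sort(key=lambda r: (-abs(r["difference"]), r["contig"], r["pos"]))
    return pd.DataFrame(
        rows[:top_n], columns=["contig", "pos", "count_a", "count_b", "difference"]
    )
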