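"""False-call calibration against bisulfite data, and locus-level 5hmC quantitation.

RRBS and the 5hmC display assay both fragment with MspI, so they interrogate the
same CpG sites.  A CpG that RRBS shows deeply covered and completely unmethylated
cannot carry 5hmC; any display reads at such a site are false calls.  Counting, over
the N qualifying sites, how many show at least i reads gives the per-cutoff error
rate E_i = N_i / N and hence the minimal read cutoff for a desired error rate.

Also here: the glucMS-qPCR percentage (locus-specific 5hmC from the Ct values of
intact, mock-digested and beta-GT-protected digested DNA) and annotation-category
summaries of the profiled sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .digest import SiteCatalog
from .profiler import SiteCounts

__all__ = [
    "RRBSCall",
    "ErrorTable",
    "QpcrMeasurement",
    "read_rrbs_tsv",
    "false_call_table",
    "min_cutoff",
    "NO_CUTOFF",
    "glucms_percent",
    "annotate",
]


@dataclass(frozen=True)
class RRBSCall:
    """One bisulfite methylation call: CpG cytosine position (0-based), coverage,
    methylated fraction."""

    contig: str
    pos: int
    coverage: int
    meth_fraction: float

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")
        if not 0.0 <= self.meth_fraction <= 1.0:
            raise ValueError("meth_fraction must be in [0, 1]")


def read_rrbs_tsv(path) -> list[RRBSCall]:
    """Read calls from a minimal TSV dialect: contig, pos, coverage, meth_fraction."""
    df = pd.read_csv(path, sep="\t")
    required = ["contig", "pos", "coverage", "meth_fraction"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"expected columns {required}, got {list(df.columns)}")
    return [
        RRBSCall(str(r.contig), int(r.pos), int(r.coverage), float(r.meth_fraction))
        for r in df.itertuples()
    ]


@dataclass
class ErrorTable:
    """False-call rates per read cutoff: E_i = N_i / N, N_i = qualifying sites with
    at least i display reads."""

    n_qualifying: int
    n_false: dict[int, int]  # cutoff i -> N_i

    @property
    def error_rates(self) -> dict[int, float]:
        return {i: n / self.n_qualifying for i, n in self.n_false.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_cutoff": list(self.n_false),
                "error_count": list(self.n_false.values()),
                "error_rate": [n / self.n_qualifying for n in self.n_false.values()],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _site_for_cpg(contig: str, pos: int, site_positions: set[tuple[str, int]]):
    """Map a CpG cytosine position to the CCGG site containing it, if any.

    In a CCGG 4-mer at site position p the forward-strand CpG cytosine sits at
    p + 1 and the reverse-strand cytosine at p + 2.
    """
    if (contig, pos - 1) in site_positions:
        return contig, pos - 1
    if (contig, pos - 2) in site_positions:
        return contig, pos - 2
    return None


def false_call_table(
    rrhp: SiteCounts,
    rrbs: list[RRBSCall],
    sites: SiteCatalog | None = None,
    min_coverage: int = 50,
    max_meth: float = 0.0,
    max_cutoff: int = 10,
) -> ErrorTable:
    """Cross-check display counts against RRBS-verified unmethylated CpGs.

    A bisulfite call qualifies when its coverage is strictly greater than
    ``min_coverage``, its methylated fraction is at most ``max_meth``, and its CpG
    lies within a potential display site (a CCGG junction).  The potential-site
    universe is the detectable-site catalog when given, else the sites present in
    the count table.  E_i is the fraction of qualifying sites with display total
    >= i, for i = 1..max_cutoff.
    """
    site_positions = sites.positions() if sites is not None else rrhp.sites()
    qualifying: set[tuple[str, int]] = set()
    for call in rrbs:
        if call.coverage <= min_coverage or call.meth_fraction > max_meth:
            continue
        hit = _site_for_cpg(call.contig, call.pos, site_positions)
        if hit is not None:
            qualifying.add(hit)
    if not qualifying:
        raise ValueError("no qualifying sites: calibration impossible")
    totals = [rrhp.total(contig, pos) for contig, pos in qualifying]
    n_false = {i: sum(1 for t in totals if t >= i) for i in range(1, max_cutoff + 1)}
    return ErrorTable(n_qualifying=len(qualifying), n_false=n_false)


NO_CUTOFF = -1


def min_cutoff(table: ErrorTable, threshold: float = 0.05) -> int:
    """Smallest read cutoff whose error rate is below ``threshold``.

    Returns :data:`NO_CUTOFF` when no tabulated cutoff achieves it.
    """
    for i, e in sorted(table.error_rates.items()):
        if e < threshold:
            return i
    return NO_CUTOFF


@dataclass
class QpcrMeasurement:
    """Ct triple for one locus: undigested input, mock-treated digested, and
    beta-GT-treated digested DNA (means of technical replicates)."""

    ct_intact: float
    ct_digested_minus: float
    ct_digested_plus: float

    def digestion_sane(self) -> bool:
        """Digestion should remove template: mock-digested Ct >= intact Ct."""
        return self.ct_digested_minus >= self.ct_intact


def glucms_percent(m: QpcrMeasurement) -> tuple[float, float]:
    """Locus 5hmC percentage from glucMS-qPCR Ct values.

    percent = 100 * (Ct_digested_minus - Ct_digested_plus)
                  / (Ct_digested_minus - Ct_intact)

    Returns (clamped, raw): the raw ratio can leave [0, 100] through Ct noise, so
    the clamped value is reported alongside it.  A zero denominator (no digestion
    effect at all) is an error.
    """
    denom = m.ct_digested_minus - m.ct_intact
    if denom == 0:
        raise ValueError("Ct(digested -) equals Ct(intact): no digestion signal")
    raw = 100.0 * (m.ct_digested_minus - m.ct_digested_plus) / denom
    return min(100.0, max(0.0, raw)), raw


def annotate(
    sites: SiteCounts,
    intervals: list[tuple[str, int, int, str]],
) -> pd.DataFrame:
    """Overlap detected sites with category-labelled annotation intervals.

    ``intervals`` are (contig, start, end, category) in 0-based half-open
    coordinates (as read by :func:`rrhp.io.read_bed_intervals`).  Per category the
    table reports how many detected sites fall in at least one interval (and the
    fraction of all detected sites), plus the fraction of the category's intervals
    covered by at least one site.  A site may count toward several categories.
    """
    if not intervals:
        raise ValueError("no annotation intervals supplied")
    trees: dict[str, dict[str, IntervalTree]] = {}
    n_intervals: dict[str, int] = {}
    for contig, start, end, category in intervals:
        trees.setdefault(category, {}).setdefault(contig, IntervalTree()).addi(
            start, end, (contig, start, end)
        )
        n_intervals[category] = n_intervals.get(category, 0) + 1

    detected = [key for key, total in sites.totals().items() if total >= 1]
    n_sites = len(detected)
    rows = []
    for category in sorted(trees):
        hit_sites = 0
        covered: set[tuple[str, int, int]] = set()
        for contig, pos in detected:
            tree = trees[category].get(contig)
            if tree is None:
                continue
            # a site occupies the CCGG 4-mer [pos, pos + 4)
            hits = tree.overlap(pos, pos + 4)
            if hits:
                hit_sites += 1
                covered.update(iv.data for iv in hits)
        rows.append(
            {
                "category": category,
                "n_sites": hit_sites,
                "site_fraction": hit_sites / n_sites if n_sites else math.nan,
                "n_intervals": n_intervals[category],
                "interval_coverage": len(covered) / n_intervals[category],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["category", "n_sites", "site_fraction", "n_intervals", "interval_coverage"],
    )
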