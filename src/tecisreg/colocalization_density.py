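"""Factor colocalization within TE copies and genome-wide density scans.

Colocalization asks whether a TE copy bound by one factor is more likely
than average to also be bound by another, within each TE category
(superfamily/clade level).  The density scan slides a fixed window across
the genome counting bound TE copies per kilobase, to locate loci where
factor-bound TEs cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2

from .formats_io import GenomeIndex, TECopy
from .te_enrichment import BindingEvent

logger = logging.getLogger(__name__)


@dataclass
class CopyBindingTable:
    """Which factors bind each TE copy, with the copy's category label."""

    factors_of: dict[str, set[str]]  # copy_id -> factors with >=1 summit
    category_of: dict[str, str]  # copy_id -> superfamily/clade label
    factor_set: frozenset[str]

    @classmethod
    def from_events(
        cls,
        events: Sequence[BindingEvent],
        copies: Sequence[TECopy],
        factors: Sequence[str],
        grouping: str = "family",
    ) -> "CopyBindingTable":
        cat = {c.copy_id: getattr(c, grouping) for c in copies}
        fac: dict[str, set[str]] = {}
        fset = frozenset(factors)
        for ev in events:
            if not ev.in_te or ev.copy_id not in cat:
                continue
            f = ev.summit.factor
            if f not in fset:
                raise ValueError(f"factor {f!r} outside configured set")
            fac.setdefault(ev.copy_id, set()).add(f)
        return cls(fac, cat, fset)

    def bound_copies(self, factor: str, category: Optional[str] = None) -> list[str]:
        return [
            cid
            for cid, fs in self.factors_of.items()
            if factor in fs
            and (category is None or self.category_of.get(cid) == category)
        ]

    def n_copies(self, category: Optional[str] = None) -> int:
        if category is None:
            return len(self.category_of)
        return sum(1 for c in self.category_of.values() if c == category)

    def binding_probability(self, factor: str, category: Optional[str] = None) -> float:
        """Average probability that a copy (of the category) is bound by
        the factor."""
        n = self.n_copies(category)
        return len(self.bound_copies(factor, category)) / n if n else 0.0


@dataclass
class ColocResult:
    factor_a: str
    factor_b: str
    category: str
    n_a_bound: int  # copies in category bound by a
    n_both: int  # of those, copies also bound by b
    observed: float  # P(b | a-bound)
    baseline: float  # average P(b) in the category
    fold: Optional[float]
    chi2_stat: Optional[float]
    p_value: Optional[float]
    testable: bool


def coloc_test(
    table: CopyBindingTable,
    factor_a: str,
    factor_b: str,
    category: str,
    baseline: Optional[float] = None,
    min_events: int = 10,
) -> ColocResult:
    """Conditional enrichment of factor-b binding among a-bound copies.

    Within the category, the a-bound copies are split into b-bound vs not,
    and a one-sample chi-squared test (df = 1, no continuity correction)
    compares the split against the category's average b-binding
    probability.  Categories with ``<= min_events`` a-bound copies, or a
    zero baseline, are reported not-testable.
    """
    a_bound = table.bound_copies(factor_a, category)
    n_a = len(a_bound)
    n_both = sum(1 for cid in a_bound if factor_b in table.factors_of.get(cid, ()))
    if baseline is None:
        baseline = table.binding_probability(factor_b, category)
    observed = n_both / n_a if n_a else 0.0
    if n_a <= min_events or baseline <= 0 or baseline >= 1:
        return ColocResult(
            factor_a, factor_b, category, n_a, n_both, observed, baseline,
            observed / baseline if baseline > 0 else None, None, None, False,
        )
    expected = np.array([n_a * baseline, n_a * (1 - baseline)])
    obs = np.array([n_both, n_a - n_both])
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(chi2.sf(stat, df=1))
    return ColocResult(
        factor_a, factor_b, category, n_a, n_both, observed, baseline,
        observed / baseline, stat, p, True,
    )


def coloc_all_pairs(
    table: CopyBindingTable,
    categories: Optional[Sequence[str]] = None,
    min_events: int = 10,
) -> list[ColocResult]:
    """Every ordered factor pair in every category with enough events."""
    cats = (
        sorted(set(table.category_of.values())) if categories is None else categories
    )
    results = []
    for a in sorted(table.factor_set):
        for b in sorted(table.factor_set):
            if a == b:
                continue
            for cat in cats:
                res = coloc_test(table, a, b, cat, min_events=min_events)
                if res.n_a_bound > 0:
                    results.append(res)
    return results


@dataclass
class DensityTrack:
    """Sliding-window density of bound TE copies (copies per kilobase)."""

    windows: list[tuple[str, int, int]]
    values: np.ndarray
    width: int
    step: int

    def argmax_window(self) -> tuple[str, int, int]:
        return self.windows[int(np.argmax(self.values))]


def density_scan(
    bound_copies: Sequence[TECopy],
    genome: GenomeIndex,
    width: int = 100_000,
    step: int = 50_000,
    chroms: Optional[Sequence[str]] = None,
) -> DensityTrack:
    """Count bound copies per kilobase in sliding windows.

    A copy belongs to the window containing its midpoint, so each copy is
    counted in exactly width/step overlapping windows and totals over a
    non-overlapping tiling conserve the copy count.  The last window of a
    chromosome is truncated at the chromosome end and its density uses the
    truncated width.
    """
    if width % step != 0:
        logger.warning("window width %d is not a multiple of step %d", width, step)
    mids: dict[str, np.ndarray] = {}
    for c in bound_copies:
        mids.setdefault(c.chrom, [])
    for c in bound_copies:
        mids[c.chrom].append(c.midpoint)
    mids = {ch: np.sort(np.asarray(v)) for ch, v in mids.items()}
    windows: list[tuple[str, int, int]] = []
    values: list[float] = []
    chrom_list = list(chroms) if chroms is not None else genome.included_chroms
    for chrom in chrom_list:
        length = genome.chrom_lengths[chrom]
        m = mids.get(chrom, np.array([]))
        for start in range(0, max(1, length - step + 1), step):
            end = min(start + width, length)
            count = int(np.searchsorted(m, end) - np.searchsorted(m, start))
            windows.append((chrom, start, end))
            values.append(count / ((end - start) / 1000.0))
            if end >= length:
                break
    return DensityTrack(windows, np.asarray(values), width, step)


@dataclass
class HotLocus:
    chrom: str
    start: int
    end: int
    peak_density: float
    n_windows: int


def top_locus(track: DensityTrack, top_quantile: float = 0.99) -> HotLocus:
    """Merge the contiguous run of top-quantile windows around the argmax
    into one locus — the densest cluster of factor-bound TEs."""
    vals = track.values
    threshold = np.quantile(vals, top_quantile)
    imax = int(np.argmax(vals))
    chrom = track.windows[imax][0]
    lo = imax
    while (
        lo > 0
        and track.windows[lo - 1][0] == chrom
        and vals[lo - 1] >= threshold
    ):
        lo -= 1
    hi = imax
    while (
        hi + 1 < len(vals)
        and track.windows[hi + 1][0] == chrom
        and vals[hi + 1] >= threshold
    ):
        hi += 1
    return HotLocus(
        chrom,
        track.windows[lo][1],
        track.windows[hi][2],
        float(vals[imax]),
        hi - lo + 1,
    )
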