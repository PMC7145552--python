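"""Family-level enrichment of ChIP-seq summits inside TE copies.

The core statistic: for each TE group (subfamily, family or class) and each
transcription factor, the number ``k`` of the factor's ``n`` peak summits
that fall inside a copy of the group is compared against the fraction ``p``
of the genome occupied by the group, with a two-tailed binomial test and
Bonferroni correction over all (group x factor) tests.  Genomic fractions
exclude configured chromosomes (chrY for female-derived cell lines) and use
per-base union semantics, so overlapping copies of one group count once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import binom

from .formats_io import BedInterval, GenomeIndex, PeakSummit, TECopy, lod_of

logger = logging.getLogger(__name__)

GROUPINGS = ("subfamily", "family", "te_class")


@dataclass(frozen=True)
class BindingEvent:
    """One peak summit, annotated with its host TE copy if it has one."""

    summit: PeakSummit
    copy_id: Optional[str] = None

    @property
    def in_te(self) -> bool:
        return self.copy_id is not None


@dataclass
class EnrichmentResult:
    group: str
    factor: str
    observed: int  # k: summits of this factor inside the group
    total: int  # n: all summits of this factor
    fraction: float  # p: genomic fraction of the group
    p_raw: float
    p_bonf: float
    n_tests: int
    direction: str  # "enriched" | "depleted"

    @property
    def fold(self) -> float:
        """Fold enrichment (k/n)/p."""
        return (self.observed / self.total) / self.fraction if self.total else np.nan

    @property
    def significant(self) -> bool:
        return self.p_bonf < 0.05


def _group_key(copy: TECopy, grouping: str) -> str:
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    return getattr(copy, grouping)


def _union_lengths(intervals: Iterable[tuple[int, int]]) -> int:
    """Total covered bases of a set of (start, end) intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def genome_fraction(
    copies: Sequence[TECopy], genome: GenomeIndex, grouping: str = "subfamily"
) -> dict[str, float]:
    """Fraction of the non-excluded genome covered by each TE group.

    Bases are counted once per group even when copies of the group overlap;
    copies on excluded chromosomes are ignored.
    """
    denom = genome.total_length
    if denom <= 0:
        raise ValueError("genome has no non-excluded bases")
    excluded = genome.excluded_chroms
    per_group: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for c in copies:
        if c.chrom in excluded or c.chrom not in genome:
            continue
        per_group.setdefault(_group_key(c, grouping), {}).setdefault(
            c.chrom, []
        ).append((c.start, c.end))
    return {
        g: sum(_union_lengths(ivs) for ivs in per_chrom.values()) / denom
        for g, per_chrom in per_group.items()
    }


def intersect_summits(
    summits: Sequence[PeakSummit],
    copies: Sequence[TECopy],
    genome: Optional[GenomeIndex] = None,
) -> list[BindingEvent]:
    """Assign each summit to the TE copy containing it, if any.

    Intervals are half-open, so a summit at a copy's ``end`` coordinate is
    outside it.  A summit inside several overlapping copies goes to the one
    with the smallest start (ties broken by lexicographically smallest
    ``copy_id``) — a deterministic rule the upstream annotation does not
    prescribe.  Summits on excluded chromosomes are dropped with a log line.
    """
    trees: dict[str, IntervalTree] = {}
    by_id = {c.copy_id: c for c in copies}
    for c in copies:
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, c.copy_id)
    events: list[BindingEvent] = []
    n_excluded = 0
    excluded = genome.excluded_chroms if genome is not None else set()
    for s in summits:
        if s.chrom in excluded:
            n_excluded += 1
            continue
        tree = trees.get(s.chrom)
        hits = tree[s.pos] if tree is not None else set()
        if hits:
            best = min(hits, key=lambda iv: (by_id[iv.data].start, iv.data))
            events.append(BindingEvent(s, best.data))
        else:
            events.append(BindingEvent(s))
    if n_excluded:
        logger.info("dropped %d summits on excluded chromosomes", n_excluded)
    return events


def binom_two_tailed(k: int, n: int, p: float) -> float:
    """Two-tailed binomial p-value, minimum-likelihood convention.

    Sums P(X = i) over every outcome whose point probability does not
    exceed P(X = k) by more than a relative tolerance of 1e-7 — the
    convention of standard statistical environments for ``binom.test``.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0,1), got {p}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0,n], got k={k}, n={n}")
    pmf = binom.pmf(np.arange(n + 1), n, p)
    cutoff = pmf[k] * (1 + 1e-7)
    return float(min(1.0, pmf[pmf <= cutoff].sum()))


def family_enrichment(
    events: Sequence[BindingEvent],
    copies: Sequence[TECopy],
    fractions: dict[str, float],
    factors: Sequence[str],
    grouping: str = "subfamily",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Two-tailed binomial enrichment of every (TE group x factor) pair.

    ``n`` for each factor counts all of its summits, TE-resident or not;
    ``k`` counts those inside copies of the group.  The Bonferroni
    multiplier is the number of tests actually performed, i.e.
    (#groups with a genomic fraction) x (#factors).
    """
    group_of = {c.copy_id: _group_key(c, grouping) for c in copies}
    totals = {f: 0 for f in factors}
    observed: dict[tuple[str, str], int] = {}
    for ev in events:
        f = ev.summit.factor
        if f not in totals:
            raise ValueError(f"event factor {f!r} not in declared factors")
        totals[f] += 1
        if ev.in_te:
            g = group_of.get(ev.copy_id)
            if g is not None:
                observed[(g, f)] = observed.get((g, f), 0) + 1
    groups = sorted(fractions)
    n_tests = len(groups) * len(factors)
    results: list[EnrichmentResult] = []
    for g in groups:
        p = fractions[g]
        for f in factors:
            k, n = observed.get((g, f), 0), totals[f]
            if p <= 0:
                if k > 0:
                    raise ValueError(
                        f"group {g!r} has zero genomic fraction but {k} observed "
                        "summits: annotation/summit mismatch"
                    )
                continue
            if n == 0:
                continue
            p_raw = binom_two_tailed(k, n, p)
            results.append(
                EnrichmentResult(
                    group=g,
                    factor=f,
                    observed=k,
                    total=n,
                    fraction=p,
                    p_raw=p_raw,
                    p_bonf=min(1.0, p_raw * n_tests),
                    n_tests=n_tests,
                    direction="enriched" if k / n > p else "depleted",
                )
            )
    orphan = {(g, f) for (g, f) in observed if g not in fractions}
    for g, f in sorted(orphan):
        raise ValueError(
            f"group {g!r} has observed summits but no genomic fraction"
        )
    return results


def _subtract_intervals(
    intervals: list[tuple[int, int]], cuts: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set-subtract sorted cut intervals from sorted intervals."""
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        pieces = [(s, e)]
        for cs, ce in cuts:
            if ce <= s or cs >= e:
                continue
            new_pieces = []
            for ps, pe in pieces:
                if ce <= ps or cs >= pe:
                    new_pieces.append((ps, pe))
                    continue
                if ps < cs:
                    new_pieces.append((ps, cs))
                if ce < pe:
                    new_pieces.append((ce, pe))
            pieces = new_pieces
        out.extend(pieces)
    return out


def conserved_noncoding_elements(
    elements: Sequence[BedInterval],
    cds: Sequence[BedInterval],
    min_length: int = 20,
    min_lod: float = 60.0,
) -> list[BedInterval]:
    """Conserved non-coding elements: phastCons elements strictly longer
    than ``min_length`` with lod strictly above ``min_lod``, minus CDS."""
    kept = [
        e
        for e in elements
        if (e.end - e.start) > min_length and lod_of(e) > min_lod
    ]
    cds_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in cds:
        cds_by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    for ivs in cds_by_chrom.values():
        ivs.sort()
    out: list[BedInterval] = []
    for e in kept:
        for s, z in _subtract_intervals(
            [(e.start, e.end)], cds_by_chrom.get(e.chrom, [])
        ):
            out.append(BedInterval(e.chrom, s, z, e.name, e.score))
    return out


def annotation_fraction(
    copies: Sequence[TECopy],
    regions: Sequence[BedInterval],
    grouping: str = "te_class",
) -> dict[str, float]:
    """Fraction of region bases covered by each TE group (union per group).

    Regions may be CDS intervals or CNEs from
    :func:`conserved_noncoding_elements`; unsorted input is sorted with a
    warning.
    """
    region_ivs: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        region_ivs.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom, ivs in region_ivs.items():
        if ivs != sorted(ivs):
            logger.warning("regions on %s were unsorted; sorting", chrom)
            ivs.sort()
    denom = sum(_union_lengths(ivs) for ivs in region_ivs.values())
    if denom == 0:
        return {}
    region_trees = {
        chrom: IntervalTree.from_tuples(ivs) for chrom, ivs in region_ivs.items()
    }
    for t in region_trees.values():
        t.merge_overlaps()
    covered: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for c in copies:
        tree = region_trees.get(c.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(c.start, c.end):
            s, e = max(c.start, iv.begin), min(c.end, iv.end)
            covered.setdefault(_group_key(c, grouping), {}).setdefault(
                c.chrom, []
            ).append((s, e))
    return {
        g: sum(_union_lengths(ivs) for ivs in per_chrom.values()) / denom
        for g, per_chrom in covered.items()
    }
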