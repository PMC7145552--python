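"""Conservation/accessibility meta-profiles and chromatin-state assignment.

Per-base conservation (phyloP-like) and windowed DNase accessibility signal
are averaged over aligned flanks around TE-embedded summits, with matched
random in-TE sites as the control; TSS distances, read-coverage matrices
(normalized to a fixed subsampled read count) and chromatin-state
proportions complete the functional characterization of the bound TEs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .formats_io import BedInterval, GenomeIndex, PeakSummit, SignalTrack, TECopy

logger = logging.getLogger(__name__)


@dataclass
class MetaProfile:
    """Mean signal per offset around a set of single-base sites."""

    offsets: np.ndarray  # -flank .. +flank
    mean: np.ndarray  # smoothed per-offset mean over sites with data
    n_sites: int
    smooth: int
    per_site_mean: np.ndarray  # mean signal per site over the window


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated at the edges (the window shrinks
    rather than padding with zeros)."""
    if window <= 1:
        return values.copy()
    n = len(values)
    out = np.empty(n)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    for i in range(n):
        lo, hi = max(0, i - half_lo), min(n, i + half_hi + 1)
        seg = values[lo:hi]
        out[i] = np.nanmean(seg) if np.any(~np.isnan(seg)) else np.nan
    return out


def meta_profile(
    sites: Sequence[tuple[str, int]],
    track: SignalTrack,
    flank: int = 400,
    smooth: int = 10,
) -> MetaProfile:
    """Average signal over ``site ± flank`` across sites.

    Offsets a site cannot reach (chromosome edge, missing track data) are
    NaN for that site and excluded from the per-offset mean.  The mean
    profile is then smoothed with a centered ``smooth``-bp moving average.
    """
    offsets = np.arange(-flank, flank + 1)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets))
    per_site = np.full(len(sites), np.nan)
    for si, (chrom, pos) in enumerate(sites):
        vals = track.values_at(chrom, pos + offsets)
        ok = ~np.isnan(vals)
        sums[ok] += vals[ok]
        counts[ok] += 1
        if ok.any():
            per_site[si] = vals[ok].mean()
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetaProfile(offsets, moving_average(mean, smooth), len(sites), smooth, per_site)


def random_te_sites(
    genome: GenomeIndex,
    copies: Sequence[TECopy],
    n_draw: int,
    seed: int | np.random.Generator,
) -> list[tuple[str, int]]:
    """Draw ``n_draw`` uniform positions over the non-excluded genome and
    keep those falling inside a TE copy — the control site set matched to
    the TE-embedded binding sites."""
    if n_draw < 1:
        raise ValueError("n_draw must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chroms = genome.included_chroms
    lengths = np.array([genome.chrom_lengths[c] for c in chroms])
    bitmaps = {c: np.zeros(genome.chrom_lengths[c], dtype=bool) for c in chroms}
    any_te = False
    for cp in copies:
        if cp.chrom in bitmaps:
            bitmaps[cp.chrom][cp.start : cp.end] = True
            any_te = True
    if not any_te:
        raise ValueError("no TE bases on non-excluded chromosomes")
    cum = np.cumsum(lengths)
    draws = rng.integers(0, cum[-1], size=n_draw)
    chrom_idx = np.searchsorted(cum, draws, side="right")
    out: list[tuple[str, int]] = []
    for d, ci in zip(draws, chrom_idx):
        pos = int(d - (cum[ci - 1] if ci > 0 else 0))
        chrom = chroms[ci]
        if bitmaps[chrom][pos]:
            out.append((chrom, pos))
    return out


@dataclass
class ProfileComparison:
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    degenerate: bool = False


def compare_profiles(
    a_sites: Sequence[tuple[str, int]],
    b_sites: Sequence[tuple[str, int]],
    track: SignalTrack,
    flank: int = 400,
) -> ProfileComparison:
    """Welch two-sample two-tailed t-test on per-site mean signal.

    Each site contributes the mean of its ``± flank`` window; the test
    compares the two groups of per-site means (e.g. bound TE sites vs
    random TE sites).
    """
    if len(a_sites) < 2 or len(b_sites) < 2:
        raise ValueError("both groups need at least 2 sites")
    a = meta_profile(a_sites, track, flank, smooth=1).per_site_mean
    b = meta_profile(b_sites, track, flank, smooth=1).per_site_mean
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = np.isclose(a.mean(), b.mean())
        logger.warning("degenerate comparison: zero variance in both groups")
        return ProfileComparison(
            0.0 if equal else np.inf,
            1.0 if equal else 0.0,
            float(a.mean()),
            float(b.mean()),
            degenerate=True,
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ProfileComparison(float(t), float(p), float(a.mean()), float(b.mean()))


def tss_distances(
    sites: Sequence[tuple[str, int]],
    tss: dict[str, np.ndarray],
    groups: Optional[Sequence[str]] = None,
) -> dict[str, float]:
    """Mean absolute distance to the nearest TSS, per group of sites.

    ``groups[i]`` labels site ``i`` (e.g. the TE class of the host copy);
    with no labels a single "all" group is reported.  Sites on chromosomes
    without any TSS are excluded with a log line.
    """
    if not tss:
        raise ValueError("TSS list is empty")
    labels = list(groups) if groups is not None else ["all"] * len(sites)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    n_skipped = 0
    for (chrom, pos), lab in zip(sites, labels):
        positions = tss.get(chrom)
        if positions is None or len(positions) == 0:
            n_skipped += 1
            continue
        i = np.searchsorted(positions, pos)
        cands = []
        if i < len(positions):
            cands.append(abs(int(positions[i]) - pos))
        if i > 0:
            cands.append(abs(pos - int(positions[i - 1])))
        d = min(cands)
        sums[lab] = sums.get(lab, 0.0) + d
        counts[lab] = counts.get(lab, 0) + 1
    if n_skipped:
        logger.info("excluded %d sites on chromosomes without TSS", n_skipped)
    return {lab: sums[lab] / counts[lab] for lab in sums}


def signal_matrix(
    sites: Sequence[tuple[str, int]],
    read_intervals: Sequence[BedInterval],
    flank: int = 4000,
    target_reads: Optional[int] = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-site x per-offset read coverage matrix over ``± flank``.

    Reads are subsampled without replacement to ``target_reads`` before
    coverage accumulation, emulating normalization of heterogeneous
    libraries to a fixed read count; when fewer reads are available all are
    used with a warning.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    reads = list(read_intervals)
    if target_reads is not None:
        if target_reads < len(reads):
            idx = rng.choice(len(reads), size=target_reads, replace=False)
            reads = [reads[i] for i in sorted(idx)]
        elif target_reads > len(reads):
            logger.warning(
                "only %d reads available for target %d; using all",
                len(reads),
                target_reads,
            )
    by_chrom: dict[str, list[BedInterval]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    width = 2 * flank + 1
    mat = np.zeros((len(sites), width))
    for si, (chrom, pos) in enumerate(sites):
        lo, hi = pos - flank, pos + flank + 1
        for r in by_chrom.get(chrom, []):
            s, e = max(r.start, lo), min(r.end, hi)
            if s < e:
                mat[si, s - lo : e - lo] += 1
    return mat


@dataclass
class StateAssignment:
    summit: PeakSummit
    state: str  # segmentation state label, or "unannotated"
    rollup: str  # promoter / enhancer / other per the rollup map


def assign_states(
    summits: Sequence[PeakSummit],
    segmentation: Sequence[BedInterval],
    rollup_map: dict[str, str],
) -> list[StateAssignment]:
    """Assign each summit the chromatin state of the segment containing it.

    The segmentation must partition each chromosome (overlapping segments
    raise); rollup labels (promoter/enhancer/other) come from the supplied
    state -> rollup map, defaulting to "other" for unmapped states.
    """
    by_chrom: dict[str, list[BedInterval]] = {}
    for seg in segmentation:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    starts: dict[str, np.ndarray] = {}
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"segmentation does not partition {chrom}: "
                    f"{a.start}-{a.end} overlaps {b.start}-{b.end}"
                )
        starts[chrom] = np.array([s.start for s in segs])
    out: list[StateAssignment] = []
    for s in summits:
        segs = by_chrom.get(s.chrom)
        state = "unannotated"
        if segs:
            i = int(np.searchsorted(starts[s.chrom], s.pos, side="right")) - 1
            if i >= 0 and segs[i].start <= s.pos < segs[i].end:
                state = segs[i].name
        out.append(StateAssignment(s, state, rollup_map.get(state, "other")))
    return out


def state_proportions(
    assignments: Sequence[StateAssignment], by: str = "rollup"
) -> dict[str, float]:
    """Proportion of summits per state (or rollup) label; sums to 1."""
    if not assignments:
        return {}
    counts: dict[str, int] = {}
    for a in assignments:
        key = getattr(a, by)
        counts[key] = counts.get(key, 0) + 1
    total = len(assignments)
    return {k: v / total for k, v in counts.items()}
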