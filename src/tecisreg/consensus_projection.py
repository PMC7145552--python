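"""Projection of bound sites onto TE consensus coordinates.

Each summit inside a TE copy is mapped through the copy's alignment to the
subfamily consensus, giving a consensus position that is comparable across
copies regardless of where in the genome they inserted.  Positions are
aggregated into 100 bins; because many copies (LINEs especially) are
5'-truncated, raw counts rise toward the 3' end even under uniform binding,
so each consensus site's count is normalized by the number of copies that
actually align over that site.  A 10-segment goodness-of-fit test flags
subfamilies whose binding concentrates at particular consensus positions,
and those peak regions are scanned for transcription-factor motifs with an
exact PWM p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2

from .formats_io import ALPHABET, CopyAlignment, MotifPWM
from .te_enrichment import BindingEvent

logger = logging.getLogger(__name__)

N_BINS = 100
N_SEGMENTS = 10
NORMALIZED_SCALE = 1e5  # display scale: events per copy per bin x 1e5


@dataclass
class ProjectedEvent:
    event: BindingEvent
    consensus_pos: int
    gap_flagged: bool  # summit fell in a genomic insertion; nearest-edge rule


@dataclass
class ConsensusProfile:
    """100-bin profile of binding events along one subfamily consensus."""

    consensus_name: str
    length: int
    raw_counts: np.ndarray  # events per bin
    coverage: np.ndarray  # mean copy coverage per bin
    normalized: np.ndarray  # raw / coverage * 1e5; NaN where coverage == 0
    n_events: int
    n_unmappable: int = 0
    projected: list[ProjectedEvent] = field(default_factory=list)

    @property
    def peak_bin(self) -> int:
        return int(np.nanargmax(self.normalized))


def project_to_consensus(
    event: BindingEvent, aln: CopyAlignment
) -> Optional[ProjectedEvent]:
    """Map one in-TE summit to its consensus coordinate.

    A summit inside a gapless alignment block maps exactly.  A summit in a
    genomic insertion (no consensus base under it) is assigned the nearest
    downstream consensus coordinate — the consensus position immediately
    after the last aligned base before the gap, in consensus-forward
    orientation — and flagged.  A summit outside the aligned span entirely
    is unmappable (returns None).
    """
    if event.copy_id != aln.copy_id:
        raise ValueError(
            f"event copy {event.copy_id!r} does not match alignment "
            f"{aln.copy_id!r}"
        )
    pos = event.summit.pos
    exact = aln.map_base(pos)
    if exact is not None:
        return ProjectedEvent(event, exact, gap_flagged=False)
    if not (aln.genome_start <= pos < aln.genome_end):
        return None
    # between blocks: find the flanking blocks in genome order
    for i in range(len(aln.blocks) - 1):
        gs, cs, ln = aln.blocks[i]
        ngs, ncs, nln = aln.blocks[i + 1]
        if gs + ln <= pos < ngs:
            # first consensus-forward coordinate after the last aligned
            # base below the gap: cs + ln for '+' copies, cs for '-' copies
            cons = cs + ln if aln.strand == "+" else cs
            return ProjectedEvent(event, min(cons, aln.consensus_length - 1), True)
    return None


def site_coverage(alignments: Sequence[CopyAlignment], length: int) -> np.ndarray:
    """Number of copies aligning over each consensus site.

    All copies of the subfamily count, bound or not: this is the
    denominator that corrects for 5' truncation.
    """
    cov = np.zeros(length, dtype=float)
    for aln in alignments:
        for _, cs, ln in aln.blocks:
            cov[cs : cs + ln] += 1
    return cov


def bin_index(pos: int, length: int, n_bins: int = N_BINS) -> int:
    """floor(pos * n_bins / length), clipped to the last bin."""
    return min(pos * n_bins // length, n_bins - 1)


def build_profile(
    events: Sequence[BindingEvent],
    alignments: Sequence[CopyAlignment],
    consensus_length: int,
    consensus_name: str = "",
) -> ConsensusProfile:
    """Project all events of one subfamily and bin them into 100 bins.

    ``alignments`` must contain every copy of the subfamily (for the
    coverage denominator); events whose copy has no alignment, or that fall
    outside the aligned span, are counted as unmappable.
    """
    if consensus_length <= 0:
        raise ValueError("consensus length must be positive")
    aln_by_copy = {a.copy_id: a for a in alignments}
    raw = np.zeros(N_BINS)
    projected: list[ProjectedEvent] = []
    n_unmappable = 0
    for ev in events:
        aln = aln_by_copy.get(ev.copy_id)
        proj = project_to_consensus(ev, aln) if aln is not None else None
        if proj is None:
            n_unmappable += 1
            continue
        projected.append(proj)
        raw[bin_index(proj.consensus_pos, consensus_length)] += 1
    cov_sites = site_coverage(alignments, consensus_length)
    site_bins = np.minimum(
        np.arange(consensus_length) * N_BINS // consensus_length, N_BINS - 1
    )
    coverage = np.array(
        [
            cov_sites[site_bins == b].mean() if np.any(site_bins == b) else 0.0
            for b in range(N_BINS)
        ]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(coverage > 0, raw / coverage * NORMALIZED_SCALE, np.nan)
    return ConsensusProfile(
        consensus_name=consensus_name,
        length=consensus_length,
        raw_counts=raw,
        coverage=coverage,
        normalized=normalized,
        n_events=len(projected),
        n_unmappable=n_unmappable,
        projected=projected,
    )


@dataclass
class UniformityTest:
    p_value: Optional[float]
    method: str  # "chi2" | "exact_mc" | "not_tested"
    statistic: Optional[float] = None
    n_events: int = 0


def segment_counts(raw_counts: np.ndarray) -> np.ndarray:
    """Collapse 100 bins into 10 equal segments of 10 bins."""
    return raw_counts.reshape(N_SEGMENTS, N_BINS // N_SEGMENTS).sum(axis=1)


def multinomial_uniform_p_mc(
    counts: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    n_resamples: int = 100_000,
) -> tuple[float, float]:
    """Exact Monte-Carlo multinomial goodness-of-fit against uniformity.

    Resamples the Pearson statistic under an equiprobable multinomial and
    returns ``(T_obs, p)`` with ``p = (1 + #{T_sim >= T_obs}) / (R + 1)``.
    """
    counts = np.asarray(counts)
    k = len(counts)
    n = int(counts.sum())
    expected = n / k
    t_obs = float(((counts - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(0) if rng is None else rng
    sims = rng.multinomial(n, np.full(k, 1 / k), size=n_resamples)
    t_sim = ((sims - expected) ** 2 / expected).sum(axis=1)
    p = (1 + int((t_sim >= t_obs - 1e-9).sum())) / (n_resamples + 1)
    return t_obs, p


def uniformity_test(
    profile: ConsensusProfile,
    rng: Optional[np.random.Generator] = None,
    n_resamples: int = 100_000,
) -> UniformityTest:
    """Goodness-of-fit of the 10-segment event counts against uniformity.

    Profiles with fewer than 30 events are not tested.  With 30-100 events
    an exact Monte-Carlo multinomial test is used (Pearson statistic,
    ``p = (1 + #{T_sim >= T_obs}) / (R + 1)``); above 100 events the
    chi-squared approximation with 9 degrees of freedom.
    """
    counts = segment_counts(profile.raw_counts)
    n = int(counts.sum())
    if n < 30:
        return UniformityTest(None, "not_tested", None, n)
    expected = n / N_SEGMENTS
    t_obs = float(((counts - expected) ** 2 / expected).sum())
    if n > 100:
        p = float(chi2.sf(t_obs, df=N_SEGMENTS - 1))
        return UniformityTest(max(p, np.finfo(float).tiny), "chi2", t_obs, n)
    t_obs, p = multinomial_uniform_p_mc(counts, rng, n_resamples)
    return UniformityTest(p, "exact_mc", t_obs, n)


def bonferroni(p_values: Sequence[Optional[float]]) -> tuple[list[Optional[float]], int]:
    """Bonferroni-correct the tested profiles; the multiplier is the number
    of profiles actually tested (None entries were below the event floor)."""
    n_tests = sum(p is not None for p in p_values)
    return (
        [min(1.0, p * n_tests) if p is not None else None for p in p_values],
        n_tests,
    )


# ---------------------------------------------------------------------------
# PWM scanning with exact p-values
# ---------------------------------------------------------------------------

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int  # consensus coordinate of the match start
    strand: str
    score: float  # log2 likelihood ratio, bits
    p_value: float


def pwm_score_distribution(
    pwm: MotifPWM, lattice: float = 1e-3
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Exact distribution of log-odds scores over background k-mers.

    Dynamic programming on a discretized score lattice (default step 1e-3
    bits): positions are folded in one at a time, convolving the integer
    score offsets of the four bases weighted by their background
    probabilities.  Query scores must be computed with the same quantized
    matrix so boundary ties resolve identically.

    Returns ``(scores, tail_prob, q_matrix, offset)``: ``tail_prob[i]`` is
    the probability that a background k-mer scores >= ``scores[i]``;
    ``q_matrix`` is the per-position score matrix in integer lattice units
    and ``offset`` the lattice index origin (the minimal achievable score
    in units).
    """
    lo = pwm.log_odds
    q = np.rint(lo / lattice).astype(np.int64)  # quantized per-position scores
    bg = pwm.background
    offset = 0  # running minimum of the accumulated score
    dist = np.array([1.0])
    for i in range(q.shape[0]):
        row = q[i]
        row_min, row_max = row.min(), row.max()
        new = np.zeros(len(dist) + row_max - row_min)
        for j in range(4):
            shift = row[j] - row_min
            new[shift : shift + len(dist)] += bg[j] * dist
        dist = new
        offset += row_min
    scores = (offset + np.arange(len(dist))) * lattice
    tail = np.cumsum(dist[::-1])[::-1]
    return scores, tail, q, int(offset)


def _scores_along(seq_idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Sliding log-odds score at every start position; NaN where the window
    contains a non-ACGT base."""
    k = lo.shape[0]
    n = len(seq_idx) - k + 1
    if n <= 0:
        return np.zeros(0)
    out = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        idx = seq_idx[i : i + n]
        ok = idx >= 0
        valid &= ok
        out += np.where(ok, lo[i, np.clip(idx, 0, 3)], 0.0)
    out[~valid] = np.nan
    return out


def scan_motif(
    sequence: str,
    pwm: MotifPWM,
    region: Optional[tuple[int, int]] = None,
    alpha: float = 1e-4,
    lattice: float = 1e-3,
) -> list[MotifHit]:
    """Scan both strands of ``sequence[region]`` for PWM matches.

    The p-value of a score is the exact probability that a background
    k-mer scores at least as high, computed by the lattice DP of
    :func:`pwm_score_distribution`.  Hits with ``p < alpha`` are returned
    sorted by position.  Windows containing non-ACGT bases are skipped.
    """
    start, end = region if region is not None else (0, len(sequence))
    if not (0 <= start <= end <= len(sequence)):
        raise ValueError("region outside sequence")
    sub = sequence[start:end].upper()
    k = len(pwm)
    if end - start < k:
        return []
    seq_idx = np.array([_BASE_INDEX.get(b, -1) for b in sub], dtype=np.int64)

    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        _, tail, q, offset = pwm_score_distribution(mat, lattice)
        # query scores in the same lattice units as the DP distribution
        units = _scores_along(seq_idx, q.astype(float))
        for i in np.flatnonzero(~np.isnan(units)):
            idx = min(max(int(units[i]) - offset, 0), len(tail) - 1)
            p = float(tail[idx])
            if p < alpha:
                hits.append(
                    MotifHit(
                        pwm.name, start + int(i), strand,
                        float(units[i]) * lattice, p,
                    )
                )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def peak_regions(
    profile: ConsensusProfile, fold_over_median: float = 3.0
) -> list[tuple[int, int]]:
    """Consensus intervals of contiguous bins whose normalized value
    exceeds ``fold_over_median`` times the profile median (the regions the
    study marks as binding peaks before motif scanning)."""
    vals = profile.normalized
    med = np.nanmedian(vals)
    threshold = fold_over_median * med if med > 0 else fold_over_median
    hot = np.where(np.nan_to_num(vals, nan=0.0) > threshold)[0]
    if len(hot) == 0:
        return []
    regions: list[tuple[int, int]] = []
    run_start = prev = hot[0]
    for b in hot[1:]:
        if b != prev + 1:
            regions.append((run_start, prev))
            run_start = b
        prev = b
    regions.append((run_start, prev))
    L = profile.length
    return [
        (b0 * L // N_BINS, min((b1 + 1) * L // N_BINS, L)) for b0, b1 in regions
    ]
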