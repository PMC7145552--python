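"""Cross-species dating of binding-site origins.

A short window (10 bp by default) around each summit is mapped into every
available species through UCSC-style alignment chains.  The most distantly
related species (on a reference phylogeny) in which the window still maps
gives the minimal clade in which the site was already present — its clade
of origin.  The known phylogenetic range of the host TE subfamily caps the
call: a site inside a lineage-restricted subfamily cannot genuinely predate
the subfamily, so an older apparent mapping is flagged inconsistent.
Divergence-based age distributions per TE group complement the dating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .formats_io import ChainSet, TECopy
from .te_enrichment import BindingEvent

logger = logging.getLogger(__name__)

MAPPED, UNMAPPED, NO_DATA = "mapped", "unmapped", "no_data"


@dataclass
class LiftoverResult:
    ok: bool
    target_interval: Optional[tuple[int, int]] = None  # forward-strand coords
    target_chrom: Optional[str] = None
    mapped_fraction: float = 0.0
    reason: Optional[str] = None  # "no_chain" | "split" | "gap"


def liftover(
    chrom: str,
    start: int,
    end: int,
    chains: ChainSet,
    min_ratio: float = 0.95,
) -> LiftoverResult:
    """Map one source interval through the best overlapping chain.

    The highest-scoring chain overlapping the interval is chosen; each base
    is walked through its gapless blocks, and the mapping succeeds iff at
    least ``min_ratio`` of the bases land inside that single chain (the
    image is then the spanning target interval, normalized to the forward
    strand).  Failure reasons: ``no_chain`` (nothing overlaps), ``split``
    (no single chain reaches the ratio but several overlap), ``gap``
    (one chain overlaps but too many bases fall in its gaps).
    """
    if end <= start:
        raise ValueError("interval must have length >= 1")
    overlapping = chains.overlapping(chrom, start, end)
    if not overlapping:
        return LiftoverResult(False, reason="no_chain")
    best = max(overlapping, key=lambda c: c.score)
    images = [best.map_base(p) for p in range(start, end)]
    mapped = [q for q in images if q is not None]
    frac = len(mapped) / (end - start)
    if frac >= min_ratio:
        return LiftoverResult(
            True,
            (min(mapped), max(mapped) + 1),
            best.q_name,
            frac,
        )
    reason = "split" if len(overlapping) > 1 else "gap"
    return LiftoverResult(False, mapped_fraction=frac, reason=reason)


def presence_matrix(
    events: Sequence[BindingEvent],
    chain_sets: dict[str, Optional[ChainSet]],
    flank: int = 5,
    min_ratio: float = 0.95,
) -> list[dict[str, str]]:
    """Per-event, per-species presence of the summit's orthologous window.

    The query is ``summit ± flank`` (10 bp for the default flank of 5).
    Species whose entry is None (no chain data) are ``no_data`` and never
    influence origin calls.
    """
    rows: list[dict[str, str]] = []
    for ev in events:
        s = ev.summit
        row: dict[str, str] = {}
        for species, chains in chain_sets.items():
            if chains is None:
                row[species] = NO_DATA
                continue
            res = liftover(
                s.chrom, max(0, s.pos - flank), s.pos + flank, chains, min_ratio
            )
            row[species] = MAPPED if res.ok else UNMAPPED
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# clade assignment on the reference tree
# ---------------------------------------------------------------------------


class SpeciesTree:
    """Reference phylogeny with labeled internal clades.

    Wraps a Bio.Phylo tree; clade depth is counted in nodes from the root,
    so "most distantly related from the reference" means the mapped species
    whose MRCA with the reference is closest to the root.
    """

    def __init__(self, tree, reference: str):
        self.tree = tree
        self.reference = reference
        self._path_to = {}
        root = tree.root
        for leaf in tree.get_terminals():
            self._path_to[leaf.name] = [root] + tree.get_path(leaf)
        if reference not in self._path_to:
            raise ValueError(f"reference species {reference!r} not in tree")

    def leaves(self) -> list[str]:
        return sorted(self._path_to)

    def mrca(self, a: str, b: str):
        if a not in self._path_to or b not in self._path_to:
            missing = a if a not in self._path_to else b
            raise ValueError(f"species {missing!r} not in tree")
        pa, pb = self._path_to[a], self._path_to[b]
        mrca = pa[0]
        for x, y in zip(pa, pb):
            if x is y:
                mrca = x
            else:
                break
        return mrca

    def mrca_depth(self, a: str, b: str) -> int:
        """Node depth (from root) of the MRCA; smaller = more distant pair."""
        return self._path_to[a].index(self.mrca(a, b))

    def clade_label(self, clade) -> str:
        if clade.name:
            return clade.name
        leaves = sorted(t.name for t in clade.get_terminals())
        return "+".join(leaves)

    def clade_of(self, label: str):
        for clade in self.tree.find_clades():
            if self.clade_label(clade) == label:
                return clade
        raise ValueError(f"no clade labeled {label!r}")

    def is_within(self, inner_label: str, outer_label: str) -> bool:
        """True iff the clade ``inner_label`` is ``outer_label`` itself or
        nested inside it."""
        outer = self.clade_of(outer_label)
        if self.clade_label(outer) == inner_label:
            return True
        return any(
            self.clade_label(c) == inner_label for c in outer.find_clades()
        )


@dataclass
class OriginCall:
    event: BindingEvent
    most_distant_species: Optional[str]
    origin_clade: str
    te_category: str  # host grouping label, or "non-TE"
    inconsistent: bool = False  # apparent mapping older than the subfamily range


def assign_origin(
    event: BindingEvent,
    presence: dict[str, str],
    tree: SpeciesTree,
    te_category: str = "non-TE",
    subfamily_max_clade: Optional[str] = None,
) -> OriginCall:
    """Clade-of-origin call for one binding event.

    The origin clade is the MRCA of the reference species and the mapped
    species most distant from it (deepest split toward the root); species
    with no chain data are skipped.  With no mapped species at all the site
    is reference-specific.  If the host TE subfamily is known to be
    restricted to a clade and the apparent origin is older, the call is
    flagged inconsistent and capped at the subfamily's maximal clade.
    """
    mapped = [
        sp for sp, state in presence.items() if state == MAPPED and sp != tree.reference
    ]
    if not mapped:
        return OriginCall(event, None, tree.reference, te_category)
    depths = {sp: tree.mrca_depth(tree.reference, sp) for sp in mapped}
    most_distant = min(sorted(mapped), key=lambda sp: depths[sp])
    clade = tree.clade_label(tree.mrca(tree.reference, most_distant))
    inconsistent = False
    if subfamily_max_clade is not None and not tree.is_within(
        clade, subfamily_max_clade
    ):
        inconsistent = True
        clade = subfamily_max_clade
        within = [
            sp
            for sp in mapped
            if tree.is_within(
                tree.clade_label(tree.mrca(tree.reference, sp)), subfamily_max_clade
            )
        ]
        most_distant = (
            min(sorted(within), key=lambda sp: depths[sp]) if within else None
        )
    return OriginCall(event, most_distant, clade, te_category, inconsistent)


def call_origins(
    events: Sequence[BindingEvent],
    presence_rows: Sequence[dict[str, str]],
    tree: SpeciesTree,
    copies: Sequence[TECopy],
    subfamily_ranges: Optional[dict[str, str]] = None,
    grouping: str = "family",
) -> list[OriginCall]:
    by_id = {c.copy_id: c for c in copies}
    calls = []
    for ev, row in zip(events, presence_rows):
        host = by_id.get(ev.copy_id) if ev.in_te else None
        category = getattr(host, grouping) if host is not None else "non-TE"
        max_clade = (
            subfamily_ranges.get(host.subfamily)
            if host is not None and subfamily_ranges
            else None
        )
        calls.append(assign_origin(ev, row, tree, category, max_clade))
    return calls


def clade_composition(
    calls: Sequence[OriginCall], by: str = "te_category"
) -> dict[str, dict[str, float]]:
    """Per group, the proportion of calls per origin clade (rows sum to 1)."""
    if not calls:
        raise ValueError("no origin calls")
    counts: dict[str, dict[str, int]] = {}
    for c in calls:
        g = getattr(c, by) if by != "factor" else c.event.summit.factor
        counts.setdefault(g, {})
        counts[g][c.origin_clade] = counts[g].get(c.origin_clade, 0) + 1
    out: dict[str, dict[str, float]] = {}
    for g, clade_counts in counts.items():
        total = sum(clade_counts.values())
        out[g] = {cl: n / total for cl, n in clade_counts.items()}
    return out


@dataclass
class AgeDistribution:
    """Histogram of divergence-from-consensus (1% bins) per TE group."""

    group: str
    bin_edges: np.ndarray  # 0, 1, ..., ceil(max)+1
    counts: np.ndarray
    n: int


def age_distribution(
    copies: Sequence[TECopy],
    grouping: str = "family",
    events: Optional[Sequence[BindingEvent]] = None,
) -> dict[str, AgeDistribution]:
    """Divergence histograms per group, over all copies or (when ``events``
    is given) over bound events weighted by their host copy's divergence."""
    if events is not None:
        by_id = {c.copy_id: c for c in copies}
        items = [
            by_id[ev.copy_id] for ev in events if ev.in_te and ev.copy_id in by_id
        ]
    else:
        items = list(copies)
    per_group: dict[str, list[float]] = {}
    for c in items:
        per_group.setdefault(getattr(c, grouping), []).append(c.divergence_pct)
    out: dict[str, AgeDistribution] = {}
    for g, divs in per_group.items():
        top = int(np.floor(max(divs))) + 1
        edges = np.arange(top + 1)
        counts, _ = np.histogram(divs, bins=edges)
        out[g] = AgeDistribution(g, edges, counts, len(divs))
    return out
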