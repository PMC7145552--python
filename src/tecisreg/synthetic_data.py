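"""Self-consistent synthetic genome bundle with ground truth.

The generator emulates the statistical structure the analysis assumes:

* TE copies derive from subfamily consensus sequences by per-base
  substitution at a subfamily-specific rate (divergence tracks insertion
  age), with LINE-like 5' truncation;
* each subfamily inserted in a named clade of the species tree, so a copy
  is present exactly in the species descending from that clade — the
  per-species chain files are built from this coordinate bookkeeping, not
  from sequence alignment, and are therefore exact by construction;
* transcription-factor binding motifs are planted at fixed consensus
  intervals of selected subfamilies and retained by a configured fraction
  of copies; summits are placed preferentially at retained motif instances,
  the remainder uniformly over the genome;
* conservation is elevated around bound sites; one genomic region holds a
  surplus of bound copies (the planted hot locus).

Every emitted file uses the standard external format so the whole pipeline
can be exercised end to end, and a :class:`TruthManifest` records what was
planted for verification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import formats_io as fio
from .formats_io import (
    BedInterval,
    CopyAlignment,
    MotifPWM,
    PeakSummit,
    TECopy,
    Taxonomy,
    revcomp,
)

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: estrogen-response-element-like palindrome used as the default planted motif
ERE_MOTIF = "AGGTCACAGTGACCT"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class MotifPlanting:
    """A binding motif written into a subfamily consensus.

    ``start`` is the consensus coordinate of the motif; copies retain the
    motif intact with probability ``retain_frac`` (substitutions skip the
    motif window), otherwise the window is scrambled at a high rate so the
    site is destroyed.
    """

    sequence: str = ERE_MOTIF
    start: int = 100
    retain_frac: float = 0.7

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SubfamilySim:
    name: str
    family: str
    te_class: str
    consensus_length: int
    n_copies: int
    insertion_clade: str
    divergence_mean_pct: float
    divergence_sd_pct: float = 2.0
    truncation_prob: float = 0.0  # probability a copy is 5'-truncated
    truncation_max_frac: float = 0.7  # uniform truncation up to this fraction
    motif: Optional[MotifPlanting] = None
    hot_frac: float = 0.0  # fraction of copies placed inside the hot locus


@dataclass
class FactorSim:
    name: str
    n_summits: int
    planted_frac: float  # fraction of summits placed at planted motifs
    target_subfamilies: tuple[str, ...] = ()
    summit_jitter: int = 2  # uniform jitter (bp) around the motif center


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    tree_newick: str = (
        "((((((human,chimp)Hominini,marmoset)Simiiformes,(mouse,rat)Murinae)"
        "Euarchontoglires,dog)Boreoeutheria,elephant)Eutheria,opossum)Theria;"
    )
    reference: str = "human"
    subfamilies: list[SubfamilySim] = field(default_factory=list)
    factors: list[FactorSim] = field(default_factory=list)
    hot_locus: tuple[str, int, int] = ("chr1", 1_500_000, 1_700_000)
    conservation_baseline: float = 0.017
    conservation_sd: float = 0.15
    conservation_uplift: float = 0.25
    uplift_halfwidth: int = 50
    dhs_baseline: float = 1.0
    dhs_uplift: float = 6.0
    dhs_window: int = 20
    n_genes_per_chrom: int = 40
    segmentation_states: tuple[str, ...] = (
        "E1_repressed",
        "E2_quiescent",
        "E3_weak_enh",
        "E4_promoter",
        "E5_strong_enh",
        "E6_insulator",
        "E7_txn",
        "E8_heterochr",
    )
    segment_mean_length: int = 2_000
    copy_margin: int = 12  # minimum gap between placed copies
    indel_prob: float = 0.0  # per-copy probability of one short genomic insertion
    #: co-binding structure: a shared subset of motif-retaining copies is
    #: "active" and attracts planted summits of every factor, so different
    #: factors co-occupy the same copies (the colocalization signal)
    active_copy_frac: float = 0.3
    active_copy_weight: float = 0.7

    def __post_init__(self) -> None:
        for sub in self.subfamilies:
            if sub.motif is not None and not (
                0 <= sub.motif.start and sub.motif.end <= sub.consensus_length
            ):
                raise ValueError(
                    f"{sub.name}: planted motif outside consensus length"
                )
        for fac in self.factors:
            if not 0 <= fac.planted_frac <= 1:
                raise ValueError(f"{fac.name}: planted_frac outside [0,1]")


def default_config(seed: int = 0) -> SimConfig:
    """The standard study-like toy conditions: two 2-Mb chromosomes, an
    ancient high-divergence MIR/L2 wave at the eutherian root, a younger
    ERV1 wave in simians, lineage-specific Alu/L1 background families,
    four factors with half their summits at planted motifs."""
    subfamilies = [
        SubfamilySim(
            "MIR_toy", "MIR", "SINE", 260, 600, "Eutheria", 25.0, 3.0,
            motif=MotifPlanting(ERE_MOTIF, 130, 0.7),
        ),
        SubfamilySim(
            "L2_toy", "L2", "LINE", 600, 600, "Eutheria", 25.0, 3.0,
            truncation_prob=0.8, truncation_max_frac=0.7,
            motif=MotifPlanting(ERE_MOTIF, 480, 0.7),
        ),
        SubfamilySim(
            "ERV1_toy", "ERV1", "LTR", 400, 400, "Simiiformes", 8.0, 1.5,
            motif=MotifPlanting(ERE_MOTIF, 180, 0.8), hot_frac=0.5,
        ),
        SubfamilySim("AluY_toy", "Alu", "SINE", 300, 700, "Hominini", 2.0, 0.8),
        SubfamilySim(
            "L1_toy", "L1", "LINE", 800, 700, "Boreoeutheria", 15.0, 2.0,
            truncation_prob=0.7, truncation_max_frac=0.8,
        ),
    ]
    factors = [
        FactorSim("ERa", 500, 0.5, ("MIR_toy", "L2_toy", "ERV1_toy")),
        FactorSim("FoxA1", 500, 0.4, ("L2_toy", "ERV1_toy")),
        FactorSim("GATA3", 500, 0.4, ("MIR_toy", "ERV1_toy")),
        FactorSim("AP2g", 500, 0.3, ("ERV1_toy",)),
    ]
    return SimConfig(seed=seed, subfamilies=subfamilies, factors=factors)


def small_config(seed: int = 0) -> SimConfig:
    """Reduced-scale preset for quick tests: same structure, one 300-kb
    chromosome plus one 200-kb chromosome, ~500 copies, ~400 summits."""
    cfg = default_config(seed)
    cfg.chrom_lengths = {"chr1": 300_000, "chr2": 200_000}
    cfg.hot_locus = ("chr1", 200_000, 260_000)
    for sub in cfg.subfamilies:
        sub.n_copies = max(40, sub.n_copies // 8)
    for fac in cfg.factors:
        fac.n_summits = 100
    cfg.n_genes_per_chrom = 15
    return cfg


def null_config(seed: int = 0) -> SimConfig:
    """No-signal conditions: same TE landscape but summits placed uniformly
    at random (no motif targeting, no hot locus, no conservation uplift)."""
    cfg = small_config(seed)
    for sub in cfg.subfamilies:
        sub.motif = None
        sub.hot_frac = 0.0
    for fac in cfg.factors:
        fac.planted_frac = 0.0
        fac.target_subfamilies = ()
    cfg.conservation_uplift = 0.0
    cfg.dhs_uplift = 0.0
    return cfg


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class CopyTruth:
    copy_id: str
    subfamily: str
    chrom: str
    start: int
    end: int
    strand: str
    insertion_clade: str
    divergence_pct: float  # realized substitution percentage
    truncation_start: int  # first consensus coordinate covered by the copy
    retains_motif: bool


@dataclass
class SummitTruth:
    factor: str
    chrom: str
    pos: int
    host_copy_id: Optional[str]
    planted: bool
    origin_clade: str


@dataclass
class TruthManifest:
    copies: list[CopyTruth]
    summits: list[SummitTruth]
    planted_subfamilies: dict[str, list[str]]  # factor -> targeted subfamilies
    motif_intervals: dict[str, tuple[int, int]]  # subfamily -> consensus interval
    hot_locus: tuple[str, int, int]
    root_clade: str

    def copy_by_id(self) -> dict[str, CopyTruth]:
        return {c.copy_id: c for c in self.copies}


@dataclass
class SimBundle:
    """Paths of every emitted file plus the in-memory ground truth."""

    outdir: Path
    genome_fasta: Path
    sizes: Path
    rmsk_out: Path
    rmsk_align: Path
    consensus_fasta: Path
    summit_files: dict[str, Path]
    conservation_wig: Path
    dhs_wig: Path
    chain_dir: Path
    tree_file: Path
    taxonomy_file: Path
    ranges_file: Path
    genes_file: Path
    segmentation_file: Path
    motifs_file: Path
    manifest: TruthManifest
    config: SimConfig


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(
    rng: np.random.Generator,
    seq: np.ndarray,
    rate: float,
    protect: Optional[tuple[int, int]] = None,
    scramble: Optional[tuple[int, int]] = None,
) -> tuple[np.ndarray, int]:
    """Substitute bases at ``rate``; return (sequence, n_substitutions).

    ``protect`` shields a window from substitution (retained motif);
    ``scramble`` forces heavy substitution there instead (destroyed motif).
    """
    seq = seq.copy()
    hit = rng.random(len(seq)) < rate
    if protect is not None:
        hit[protect[0] : protect[1]] = False
    if scramble is not None:
        s, e = scramble
        hit[s:e] = rng.random(e - s) < 0.4
    idx = np.flatnonzero(hit)
    if len(idx):
        # substitute with one of the three other bases
        cur = np.searchsorted(BASES, seq[idx])
        shift = rng.integers(1, 4, size=len(idx))
        seq[idx] = BASES[(cur + shift) % 4]
    return seq, int(len(idx))


def _clade_species(tree_newick: str, label: str, reference: str) -> set[str]:
    import io as _io

    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(tree_newick), "newick")
    for clade in tree.find_clades():
        if clade.name == label:
            return {t.name for t in clade.get_terminals()}
    raise ValueError(f"clade {label!r} not found in tree")


def simulate(config: SimConfig, outdir: str | Path) -> SimBundle:
    """Generate the full file bundle and its ground-truth manifest.

    Deterministic: the same config (including seed) produces a
    byte-identical bundle.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms = list(config.chrom_lengths)
    genome = {c: _random_seq(rng, L) for c, L in config.chrom_lengths.items()}
    occupied = {c: np.zeros(L, dtype=bool) for c, L in config.chrom_lengths.items()}

    import io as _io

    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(config.tree_newick), "newick")
    root_label = tree.root.name or "root"
    all_species = sorted(t.name for t in tree.get_terminals())
    clade_members = {
        clade.name: {t.name for t in clade.get_terminals()}
        for clade in tree.find_clades()
        if clade.name
    }
    for sub in config.subfamilies:
        if sub.insertion_clade not in clade_members:
            raise ValueError(
                f"{sub.name}: insertion clade {sub.insertion_clade!r} not a "
                "labeled clade of the tree"
            )
        if config.reference not in clade_members[sub.insertion_clade]:
            raise ValueError(
                f"{sub.name}: insertion clade must contain the reference species"
            )

    # --- consensus sequences with planted motifs -------------------------
    consensus: dict[str, str] = {}
    for sub in config.subfamilies:
        seq = _random_seq(rng, sub.consensus_length)
        if sub.motif is not None:
            motif = np.frombuffer(sub.motif.sequence.encode(), dtype=np.uint8)
            seq[sub.motif.start : sub.motif.end] = motif
        consensus[sub.name] = seq.tobytes().decode()

    # --- copy placement ---------------------------------------------------
    chrom_lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()
    hot_chrom, hot_start, hot_end = config.hot_locus
    margin = config.copy_margin

    copies_truth: list[CopyTruth] = []
    copy_records: list[TECopy] = []
    alignments: list[CopyAlignment] = []
    chrom_of_copy: dict[str, str] = {}
    copy_seq_cache: dict[str, tuple[int, int]] = {}
    copy_counter = 0

    def place(length: int, in_hot: bool) -> Optional[tuple[str, int]]:
        for _ in range(2000):
            if in_hot:
                chrom = hot_chrom
                pos = int(rng.integers(hot_start, max(hot_start + 1, hot_end - length)))
            else:
                chrom = chroms[rng.choice(len(chroms), p=chrom_probs)]
                pos = int(
                    rng.integers(margin, config.chrom_lengths[chrom] - length - margin)
                )
            window = occupied[chrom][pos - margin : pos + length + margin]
            if not window.any():
                occupied[chrom][pos - margin : pos + length + margin] = True
                return chrom, pos
        return None

    for sub in config.subfamilies:
        cons_arr = np.frombuffer(consensus[sub.name].encode(), dtype=np.uint8)
        for _ in range(sub.n_copies):
            truncated = rng.random() < sub.truncation_prob
            if truncated:
                t_start = int(
                    rng.integers(1, int(sub.consensus_length * sub.truncation_max_frac))
                )
            else:
                t_start = 0
            if sub.motif is not None and t_start > sub.motif.start - 8:
                # keep planted motifs interior to the copy so summit windows
                # never straddle a copy boundary
                t_start = max(0, sub.motif.start - 8)
            length = sub.consensus_length - t_start
            retains = sub.motif is not None and rng.random() < sub.motif.retain_frac
            rate = max(
                0.0,
                rng.normal(sub.divergence_mean_pct, sub.divergence_sd_pct) / 100.0,
            )
            protect = scramble = None
            if sub.motif is not None:
                window = (sub.motif.start - t_start, sub.motif.end - t_start)
                if retains:
                    protect = window
                else:
                    scramble = window
            seq, n_sub = _mutate(rng, cons_arr[t_start:], rate, protect, scramble)
            strand = "+" if rng.random() < 0.5 else "-"
            in_hot = rng.random() < sub.hot_frac
            spot = place(length, in_hot)
            if spot is None:
                raise RuntimeError(
                    f"could not place copy of {sub.name} (len {length}); "
                    f"genome too small — need roughly "
                    f"{sum(s.n_copies * s.consensus_length for s in config.subfamilies)}"
                    " placeable bases"
                )
            chrom, pos = spot
            emitted = seq if strand == "+" else np.frombuffer(
                revcomp(seq.tobytes().decode()).encode(), dtype=np.uint8
            )
            genome[chrom][pos : pos + length] = emitted
            copy_id = f"cp{copy_counter:05d}"
            copy_counter += 1
            div = 100.0 * n_sub / length
            copies_truth.append(
                CopyTruth(
                    copy_id, sub.name, chrom, pos, pos + length, strand,
                    sub.insertion_clade, div, t_start, retains,
                )
            )
            copy_records.append(
                TECopy(
                    chrom, pos, pos + length, strand, sub.name, sub.family,
                    sub.te_class, round(div, 2), copy_id,
                )
            )
            alignments.append(
                CopyAlignment(
                    copy_id, sub.name, [(pos, t_start, length)], strand,
                    sub.consensus_length,
                )
            )
            chrom_of_copy[copy_id] = chrom
            copy_seq_cache[copy_id] = (pos, pos + length)

    # sort copies by position for tidy files
    order = sorted(range(len(copy_records)), key=lambda i: (
        copy_records[i].chrom, copy_records[i].start))
    copy_records = [copy_records[i] for i in order]
    copies_truth = [copies_truth[i] for i in order]
    alignments = [alignments[i] for i in order]

    truth_by_id = {c.copy_id: c for c in copies_truth}
    sub_by_name = {s.name: s for s in config.subfamilies}

    # --- summits ----------------------------------------------------------
    copy_interval_arrays = {
        c: (
            np.array([x.start for x in copy_records if x.chrom == c]),
            np.array([x.end for x in copy_records if x.chrom == c]),
            [x.copy_id for x in copy_records if x.chrom == c],
        )
        for c in chroms
    }

    def host_of(chrom: str, pos: int) -> Optional[str]:
        starts, ends, ids = copy_interval_arrays[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return ids[i]
        return None

    def clean_background(chrom: str, pos: int, flank: int = 6) -> bool:
        """Window must not straddle a copy boundary (keeps ortholog truth
        unambiguous for the 10-bp liftover queries)."""
        hosts = {host_of(chrom, p) for p in (pos - flank, pos, pos + flank)}
        return len(hosts) == 1

    retaining: dict[str, list[CopyTruth]] = {}
    for ct in copies_truth:
        if ct.retains_motif:
            retaining.setdefault(ct.subfamily, []).append(ct)
    def _in_hot(ct: CopyTruth) -> bool:
        return ct.chrom == hot_chrom and hot_start <= ct.start < hot_end

    active: dict[str, list[CopyTruth]] = {}
    for sub_name, cts in retaining.items():
        n_active = max(1, int(round(config.active_copy_frac * len(cts))))
        # hot-locus copies are preferentially the active ones: the locus is
        # dense in bound copies precisely because its copies attract summits
        hot = [c for c in cts if _in_hot(c)]
        cold = [c for c in cts if not _in_hot(c)]
        pool = [hot[i] for i in rng.permutation(len(hot))] + [
            cold[i] for i in rng.permutation(len(cold))
        ]
        active[sub_name] = pool[:n_active]

    summits_truth: list[SummitTruth] = []
    planted_map: dict[str, list[str]] = {}
    for fac in config.factors:
        planted_map[fac.name] = list(fac.target_subfamilies)
        n_planted = int(round(fac.n_summits * fac.planted_frac))
        targets = [s for s in fac.target_subfamilies if retaining.get(s)]
        if not targets:
            n_planted = 0
        for _ in range(n_planted):
            sub_name = targets[int(rng.integers(0, len(targets)))]
            sub = sub_by_name[sub_name]
            pool = (
                active[sub_name]
                if rng.random() < config.active_copy_weight
                else retaining[sub_name]
            )
            ct = pool[int(rng.integers(0, len(pool)))]
            motif_center_cons = sub.motif.center
            off = motif_center_cons - ct.truncation_start
            if ct.strand == "+":
                pos = ct.start + off
            else:
                pos = ct.end - 1 - off
            pos += int(rng.integers(-fac.summit_jitter, fac.summit_jitter + 1))
            pos = min(max(pos, ct.start + 1), ct.end - 2)
            summits_truth.append(
                SummitTruth(
                    fac.name, ct.chrom, pos, ct.copy_id, True, ct.insertion_clade
                )
            )
        for _ in range(fac.n_summits - n_planted):
            for _try in range(1000):
                ci = rng.choice(len(chroms), p=chrom_probs)
                chrom = chroms[ci]
                pos = int(rng.integers(10, config.chrom_lengths[chrom] - 10))
                if clean_background(chrom, pos):
                    break
            host = host_of(chrom, pos)
            origin = truth_by_id[host].insertion_clade if host else root_label
            summits_truth.append(
                SummitTruth(fac.name, chrom, pos, host, False, origin)
            )

    # --- tracks -----------------------------------------------------------
    bound_positions: dict[str, list[int]] = {c: [] for c in chroms}
    for st in summits_truth:
        bound_positions[st.chrom].append(st.pos)

    cons_track: dict[str, list[tuple[int, int, np.ndarray]]] = {}
    dhs_track: dict[str, list[tuple[int, int, np.ndarray]]] = {}
    for chrom in chroms:
        L = config.chrom_lengths[chrom]
        vals = rng.normal(config.conservation_baseline, config.conservation_sd, L)
        for pos in bound_positions[chrom]:
            lo = max(0, pos - config.uplift_halfwidth)
            hi = min(L, pos + config.uplift_halfwidth + 1)
            vals[lo:hi] += config.conservation_uplift
        cons_track[chrom] = [(0, 1, np.round(vals, 4))]
        n_win = L // config.dhs_window
        wvals = np.abs(rng.normal(config.dhs_baseline, 0.5, n_win))
        for pos in bound_positions[chrom]:
            w = pos // config.dhs_window
            lo, hi = max(0, w - 3), min(n_win, w + 4)
            wvals[lo:hi] += config.dhs_uplift
        dhs_track[chrom] = [(0, config.dhs_window, np.round(wvals, 3))]

    # --- chains -----------------------------------------------------------
    chain_dir = outdir / "chains"
    chain_dir.mkdir(exist_ok=True)
    absent_by_species: dict[str, dict[str, list[tuple[int, int]]]] = {
        sp: {c: [] for c in chroms} for sp in all_species if sp != config.reference
    }
    for ct in copies_truth:
        present = clade_members[ct.insertion_clade]
        for sp in absent_by_species:
            if sp not in present:
                absent_by_species[sp][ct.chrom].append((ct.start, ct.end))

    for sp, per_chrom in absent_by_species.items():
        chains = []
        for ci, chrom in enumerate(chroms):
            L = config.chrom_lengths[chrom]
            gaps = sorted(per_chrom[chrom])
            blocks = []
            t_cursor, q_cursor = 0, 0
            for gs, ge in gaps:
                if gs > t_cursor:
                    blocks.append((t_cursor, q_cursor, gs - t_cursor))
                    q_cursor += gs - t_cursor
                t_cursor = ge
            if t_cursor < L:
                blocks.append((t_cursor, q_cursor, L - t_cursor))
                q_cursor += L - t_cursor
            chains.append(
                fio.Chain(
                    chain_id=f"{sp}_{chrom}",
                    score=1_000_000.0,
                    t_name=chrom,
                    t_size=L,
                    t_start=blocks[0][0],
                    t_end=blocks[-1][0] + blocks[-1][2],
                    q_name=chrom,
                    q_size=q_cursor,
                    q_strand="+",
                    q_start=blocks[0][1],
                    q_end=blocks[-1][1] + blocks[-1][2],
                    blocks=blocks,
                )
            )
        fio.write_chain(fio.ChainSet(sp, chains), chain_dir / f"{sp}.chain")

    # --- annotation sidecars ----------------------------------------------
    taxonomy = Taxonomy(
        {s.name: (s.family, s.te_class) for s in config.subfamilies}
    )
    genes_lines = []
    for chrom in chroms:
        L = config.chrom_lengths[chrom]
        starts = np.sort(rng.integers(0, L - 5000, size=config.n_genes_per_chrom))
        for gi, s in enumerate(starts):
            strand = "+" if rng.random() < 0.5 else "-"
            genes_lines.append(
                f"GENE_{chrom}_{gi}\tNM_{chrom}_{gi}\t{chrom}\t{strand}\t{s}\t"
                f"{s + 3000}\t{s}\t{s + 3000}\t1\t{s},\t{s + 3000},\n"
            )

    seg_intervals: list[BedInterval] = []
    states = config.segmentation_states
    for chrom in chroms:
        L = config.chrom_lengths[chrom]
        pos = 0
        while pos < L:
            seg_len = int(rng.exponential(config.segment_mean_length)) + 200
            end = min(pos + seg_len, L)
            state = states[int(rng.integers(0, len(states)))]
            seg_intervals.append(BedInterval(chrom, pos, end, state))
            pos = end

    # --- write bundle -------------------------------------------------------
    genome_str = {c: genome[c].tobytes().decode() for c in chroms}
    paths = SimBundle(
        outdir=outdir,
        genome_fasta=outdir / "genome.fa",
        sizes=outdir / "sizes.tsv",
        rmsk_out=outdir / "rmsk.out",
        rmsk_align=outdir / "rmsk.align",
        consensus_fasta=outdir / "consensus.fa",
        summit_files={
            fac.name: outdir / f"summits_{fac.name}.narrowPeak"
            for fac in config.factors
        },
        conservation_wig=outdir / "conservation.wig",
        dhs_wig=outdir / "dhs.wig",
        chain_dir=chain_dir,
        tree_file=outdir / "tree.nwk",
        taxonomy_file=outdir / "taxonomy.tsv",
        ranges_file=outdir / "subfamily_ranges.tsv",
        genes_file=outdir / "genes.tsv",
        segmentation_file=outdir / "segmentation.bed",
        motifs_file=outdir / "motifs.pfm",
        manifest=TruthManifest(
            copies=copies_truth,
            summits=summits_truth,
            planted_subfamilies=planted_map,
            motif_intervals={
                s.name: (s.motif.start, s.motif.end)
                for s in config.subfamilies
                if s.motif is not None
            },
            hot_locus=config.hot_locus,
            root_clade=root_label,
        ),
        config=config,
    )
    fio.write_fasta(genome_str, paths.genome_fasta)
    with open(paths.sizes, "w") as fh:
        for c in chroms:
            fh.write(f"{c}\t{config.chrom_lengths[c]}\n")
    fio.write_repeatmasker_out(copy_records, paths.rmsk_out)
    fio.write_repeatmasker_align(
        alignments, consensus, genome_str, chrom_of_copy, paths.rmsk_align
    )
    fio.write_fasta(consensus, paths.consensus_fasta)
    for fac in config.factors:
        summits = [
            PeakSummit(st.chrom, st.pos, fac.name, 100.0, f"peak_{i}")
            for i, st in enumerate(summits_truth)
            if st.factor == fac.name
        ]
        summits.sort(key=lambda s: (s.chrom, s.pos))
        fio.write_narrowpeak(summits, paths.summit_files[fac.name])
    fio.write_wig(fio.SignalTrack(cons_track, "per_base"), paths.conservation_wig)
    fio.write_wig(fio.SignalTrack(dhs_track, "windowed"), paths.dhs_wig)
    with open(paths.tree_file, "w") as fh:
        fh.write(config.tree_newick + "\n")
    fio.write_taxonomy(taxonomy, paths.taxonomy_file)
    with open(paths.ranges_file, "w") as fh:
        fh.write("#subfamily\tmax_clade\n")
        for s in config.subfamilies:
            fh.write(f"{s.name}\t{s.insertion_clade}\n")
    with open(paths.genes_file, "w") as fh:
        fh.writelines(genes_lines)
    fio.write_bed(seg_intervals, paths.segmentation_file)
    motifs = [
        motif_pwm(s.motif.sequence, name=f"{s.name}_motif")
        for s in config.subfamilies
        if s.motif is not None
    ]
    fio.write_pfm(motifs, paths.motifs_file)
    _write_manifest(paths)
    return paths


def motif_pwm(sequence: str, name: str = "motif", match_prob: float = 0.97) -> MotifPWM:
    """Near-deterministic PWM for a planted consensus motif sequence."""
    idx = {b: i for i, b in enumerate("ACGT")}
    mat = np.full((len(sequence), 4), (1 - match_prob) / 3)
    for i, b in enumerate(sequence):
        mat[i, idx[b]] = match_prob
    return MotifPWM(name, mat)


def _write_manifest(bundle: SimBundle) -> None:
    man = bundle.manifest
    with open(bundle.outdir / "manifest_copies.tsv", "w") as fh:
        fh.write(
            "copy_id\tsubfamily\tchrom\tstart\tend\tstrand\tinsertion_clade\t"
            "divergence_pct\ttruncation_start\tretains_motif\n"
        )
        for c in man.copies:
            fh.write(
                f"{c.copy_id}\t{c.subfamily}\t{c.chrom}\t{c.start}\t{c.end}\t"
                f"{c.strand}\t{c.insertion_clade}\t{c.divergence_pct:.4f}\t"
                f"{c.truncation_start}\t{int(c.retains_motif)}\n"
            )
    with open(bundle.outdir / "manifest_summits.tsv", "w") as fh:
        fh.write("factor\tchrom\tpos\thost_copy_id\tplanted\torigin_clade\n")
        for s in man.summits:
            fh.write(
                f"{s.factor}\t{s.chrom}\t{s.pos}\t{s.host_copy_id or '-'}\t"
                f"{int(s.planted)}\t{s.origin_clade}\n"
            )
    meta = {
        "planted_subfamilies": man.planted_subfamilies,
        "motif_intervals": {k: list(v) for k, v in man.motif_intervals.items()},
        "hot_locus": list(man.hot_locus),
        "root_clade": man.root_clade,
        "seed": bundle.config.seed,
    }
    with open(bundle.outdir / "manifest.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------


@dataclass
class AuditReport:
    passed: bool
    failures: list[str]


def audit(bundle: SimBundle, sample: int = 200) -> AuditReport:
    """Re-parse the emitted bundle and verify it against the manifest.

    Checks copy intervals and divergences in the .out, block structure of
    the .align (per-base consistency of a sample of copies against the
    genome and consensus FASTA), summit positions in the narrowPeak files,
    and the species-presence pattern of a sample of copies in the chain
    files.
    """
    failures: list[str] = []
    man = bundle.manifest
    tax = fio.read_taxonomy(bundle.taxonomy_file)
    copies = fio.read_repeatmasker_out(bundle.rmsk_out, tax)
    truth = man.copy_by_id()
    if len(copies) != len(man.copies):
        failures.append(
            f".out has {len(copies)} copies, manifest has {len(man.copies)}"
        )
    for c in copies:
        t = truth.get(c.copy_id)
        if t is None:
            failures.append(f"copy {c.copy_id} not in manifest")
            continue
        if (c.chrom, c.start, c.end, c.strand) != (t.chrom, t.start, t.end, t.strand):
            failures.append(f"copy {c.copy_id}: interval mismatch")

    genome = fio.read_fasta(bundle.genome_fasta)
    consensus = fio.read_fasta(bundle.consensus_fasta)
    alignments = fio.read_repeatmasker_align(bundle.rmsk_align)
    if len(alignments) != len(man.copies):
        failures.append(
            f".align has {len(alignments)} records, manifest {len(man.copies)}"
        )
    rng = np.random.default_rng(0)
    take = min(sample, len(alignments))
    for i in rng.choice(len(alignments), size=take, replace=False):
        aln = alignments[i]
        t = truth.get(aln.copy_id)
        if t is None:
            failures.append(f".align {aln.copy_id} not in manifest")
            continue
        if aln.genome_start != t.start or aln.genome_end != t.end:
            failures.append(f".align {aln.copy_id}: span mismatch")
        lo_cons = min(b[1] for b in aln.blocks)
        if lo_cons != t.truncation_start:
            failures.append(
                f".align {aln.copy_id}: truncation start {lo_cons} != "
                f"{t.truncation_start}"
            )

    for factor, path in bundle.summit_files.items():
        parsed = fio.read_narrowpeak(path, factor)
        expect = sorted(
            (s.chrom, s.pos) for s in man.summits if s.factor == factor
        )
        got = sorted((s.chrom, s.pos) for s in parsed)
        if expect != got:
            failures.append(f"summits for {factor} differ from manifest")

    # chain mappability pattern on a sample of copies
    chain_sets = {}
    for path in sorted(bundle.chain_dir.glob("*.chain*")):
        sp = path.name.split(".chain")[0]
        chain_sets[sp] = fio.read_chain(path, sp)
    import io as _io

    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(bundle.config.tree_newick), "newick")
    clade_members = {
        c.name: {t.name for t in c.get_terminals()}
        for c in tree.find_clades()
        if c.name
    }
    take = min(50, len(man.copies))
    for i in rng.choice(len(man.copies), size=take, replace=False):
        t = man.copies[i]
        probe = (t.start + t.end) // 2
        for sp, cs in chain_sets.items():
            mapped = any(
                ch.map_base(probe) is not None
                for ch in cs.overlapping(t.chrom, probe, probe + 1)
            )
            should = sp in clade_members[t.insertion_clade]
            if mapped != should:
                failures.append(
                    f"copy {t.copy_id} mappability in {sp} is {mapped}, "
                    f"expected {should} (chain {sp}_{t.chrom})"
                )
                break
    return AuditReport(not failures, failures)
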