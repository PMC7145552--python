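"""End-to-end orchestration of the analysis stages.

``run_all`` executes enrichment -> consensus profiling -> signal profiling
-> origin dating -> colocalization -> density scanning in dependency order
over one input bundle (the synthetic generator's layout or equivalently
named real files), writing one TSV per stage plus a machine-readable run
record with every seed and parameter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import (
    colocalization_density as cd,
    consensus_projection as cp,
    formats_io as fio,
    liftover_dating as ld,
    signal_profiles as sp,
    te_enrichment as te,
)

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised before any compute when the configuration is unusable."""


@dataclass
class RunConfig:
    """Input paths and parameters for a full pipeline run.

    Paths follow the bundle layout of the synthetic generator; any stage
    whose inputs are absent is skipped with a log line.
    """

    bundle_dir: Path
    out_dir: Path
    factors: list[str]
    exclude_chroms: list[str] = field(default_factory=list)
    reference_species: str = "human"
    alpha: float = 0.05
    grouping: str = "subfamily"
    flank_conservation: int = 400
    smooth: int = 10
    liftover_flank: int = 5
    min_ratio: float = 0.95
    density_width: int = 100_000
    density_step: int = 50_000
    n_random_sites: int = 20_000
    seed: int = 0
    min_profile_events: int = 30
    rollup_map: dict[str, str] = field(
        default_factory=lambda: {
            "E4_promoter": "promoter",
            "E5_strong_enh": "enhancer",
            "E3_weak_enh": "enhancer",
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["bundle_dir"] = Path(raw["bundle_dir"])
        raw["out_dir"] = Path(raw["out_dir"])
        return cls(**raw)

    def validate(self) -> None:
        required = ["sizes.tsv", "rmsk.out", "taxonomy.tsv"]
        missing = [
            f for f in required if not (self.bundle_dir / f).exists()
        ]
        for factor in self.factors:
            f = f"summits_{factor}.narrowPeak"
            if not (self.bundle_dir / f).exists():
                missing.append(f)
        if missing:
            raise ValidationError(
                f"missing inputs in {self.bundle_dir}: {', '.join(missing)}"
            )


@dataclass
class RunResult:
    enrichment: list[te.EnrichmentResult]
    profiles: dict[tuple[str, str], cp.ConsensusProfile]  # (subfamily, factor)
    uniformity: dict[tuple[str, str], cp.UniformityTest]
    motif_hits: dict[tuple[str, str], list[cp.MotifHit]]
    conservation: Optional[sp.ProfileComparison]
    origin_calls: list[ld.OriginCall]
    clade_composition: dict[str, dict[str, float]]
    coloc: list[cd.ColocResult]
    density: cd.DensityTrack
    hot_locus: cd.HotLocus
    state_proportions: dict[str, dict[str, float]]


def run_all(config: RunConfig) -> RunResult:
    config.validate()
    b = config.bundle_dir
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genome = fio.read_genome_index(b / "sizes.tsv", config.exclude_chroms)
    taxonomy = fio.read_taxonomy(b / "taxonomy.tsv")
    copies = fio.read_repeatmasker_out(b / "rmsk.out", taxonomy)
    summits: list[fio.PeakSummit] = []
    for factor in config.factors:
        summits.extend(
            fio.read_narrowpeak(b / f"summits_{factor}.narrowPeak", factor)
        )

    # --- stage: enrichment -------------------------------------------------
    logger.info("stage enrich: %d copies, %d summits", len(copies), len(summits))
    fractions = te.genome_fraction(copies, genome, config.grouping)
    events = te.intersect_summits(summits, copies, genome)
    enrichment = te.family_enrichment(
        events, copies, fractions, config.factors, config.grouping, config.alpha
    )
    _write_enrichment(enrichment, out / "enrichment.tsv")

    # --- stage: consensus profiles ------------------------------------------
    profiles: dict[tuple[str, str], cp.ConsensusProfile] = {}
    uniformity: dict[tuple[str, str], cp.UniformityTest] = {}
    motif_hits: dict[tuple[str, str], list[cp.MotifHit]] = {}
    align_path = b / "rmsk.align"
    if align_path.exists():
        alignments = fio.read_repeatmasker_align(align_path)
        consensus = fio.read_fasta(b / "consensus.fa")
        motifs = (
            fio.read_pfm(b / "motifs.pfm") if (b / "motifs.pfm").exists() else []
        )
        by_sub: dict[str, list[fio.CopyAlignment]] = {}
        for aln in alignments:
            by_sub.setdefault(aln.consensus_name, []).append(aln)
        sub_of = {c.copy_id: c.subfamily for c in copies}
        for sub_name, sub_alns in sorted(by_sub.items()):
            for factor in config.factors:
                evs = [
                    ev
                    for ev in events
                    if ev.in_te
                    and ev.summit.factor == factor
                    and sub_of.get(ev.copy_id) == sub_name
                ]
                if not evs:
                    continue
                profile = cp.build_profile(
                    evs, sub_alns, len(consensus[sub_name]), sub_name
                )
                key = (sub_name, factor)
                profiles[key] = profile
                uniformity[key] = cp.uniformity_test(
                    profile, np.random.default_rng(config.seed + 1)
                )
                ut = uniformity[key]
                if ut.p_value is not None and ut.p_value < config.alpha:
                    hits: list[cp.MotifHit] = []
                    for region in cp.peak_regions(profile):
                        for pwm in motifs:
                            hits.extend(
                                cp.scan_motif(consensus[sub_name], pwm, region)
                            )
                    motif_hits[key] = hits
        _write_profiles(profiles, uniformity, out / "profiles.tsv")
        _write_motif_hits(motif_hits, out / "motif_hits.tsv")
    else:
        logger.info("stage profile skipped: no rmsk.align")

    # --- stage: signal -------------------------------------------------------
    conservation_cmp: Optional[sp.ProfileComparison] = None
    cons_path = b / "conservation.wig"
    if cons_path.exists():
        track = fio.read_wig(cons_path)
        te_sites = [
            (ev.summit.chrom, ev.summit.pos) for ev in events if ev.in_te
        ]
        control = sp.random_te_sites(genome, copies, config.n_random_sites, rng)
        if len(te_sites) >= 2 and len(control) >= 2:
            conservation_cmp = sp.compare_profiles(
                te_sites, control, track, config.flank_conservation
            )
            with open(out / "conservation.tsv", "w") as fh:
                fh.write("mean_bound\tmean_control\tt\tp\n")
                fh.write(
                    f"{conservation_cmp.mean_a:.5f}\t{conservation_cmp.mean_b:.5f}"
                    f"\t{conservation_cmp.t_statistic:.3f}"
                    f"\t{conservation_cmp.p_value:.3e}\n"
                )

    state_props: dict[str, dict[str, float]] = {}
    seg_path = b / "segmentation.bed"
    if seg_path.exists():
        segmentation = fio.read_bed(seg_path)
        for label, subset in (
            ("TE", [ev.summit for ev in events if ev.in_te]),
            ("non-TE", [ev.summit for ev in events if not ev.in_te]),
        ):
            if subset:
                assigns = sp.assign_states(subset, segmentation, config.rollup_map)
                state_props[label] = sp.state_proportions(assigns)
        _write_state_props(state_props, out / "states.tsv")

    # --- stage: dating -------------------------------------------------------
    origin_calls: list[ld.OriginCall] = []
    composition: dict[str, dict[str, float]] = {}
    chain_dir = b / "chains"
    tree_path = b / "tree.nwk"
    if chain_dir.is_dir() and tree_path.exists():
        chain_sets = {
            p.name.split(".chain")[0]: fio.read_chain(p, p.name.split(".chain")[0])
            for p in sorted(chain_dir.glob("*.chain*"))
        }
        tree = ld.SpeciesTree(fio.read_tree(tree_path), config.reference_species)
        ranges = _read_ranges(b / "subfamily_ranges.tsv")
        presence = ld.presence_matrix(
            events, chain_sets, config.liftover_flank, config.min_ratio
        )
        origin_calls = ld.call_origins(
            events, presence, tree, copies, ranges, grouping="family"
        )
        composition = ld.clade_composition(origin_calls)
        _write_origins(origin_calls, out / "origins.tsv")
        _write_composition(composition, out / "clade_composition.tsv")

    # --- stage: colocalization & density -------------------------------------
    table = cd.CopyBindingTable.from_events(events, copies, config.factors, "family")
    coloc = cd.coloc_all_pairs(table)
    _write_coloc(coloc, out / "colocalization.tsv")
    bound_ids = set(table.factors_of)
    bound_copies = [c for c in copies if c.copy_id in bound_ids]
    density = cd.density_scan(
        bound_copies, genome, config.density_width, config.density_step
    )
    hot = cd.top_locus(density)
    with open(out / "density.bedGraph", "w") as fh:
        for (chrom, s, e), v in zip(density.windows, density.values):
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
    with open(out / "hot_locus.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tpeak_density\tn_windows\n")
        fh.write(
            f"{hot.chrom}\t{hot.start}\t{hot.end}\t{hot.peak_density:.6g}\t"
            f"{hot.n_windows}\n"
        )

    _write_run_record(config, out)
    return RunResult(
        enrichment=enrichment,
        profiles=profiles,
        uniformity=uniformity,
        motif_hits=motif_hits,
        conservation=conservation_cmp,
        origin_calls=origin_calls,
        clade_composition=composition,
        coloc=coloc,
        density=density,
        hot_locus=hot,
        state_proportions=state_props,
    )


def _read_ranges(path: Path) -> dict[str, str]:
    if not path.exists():
        return {}
    out = {}
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        sub, clade = line.split("\t")[:2]
        out[sub] = clade
    return out


def _write_enrichment(results, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "group\tfactor\tobserved\ttotal\tfraction\tfold\tp_raw\tp_bonf\t"
            "n_tests\tdirection\tsignificant\n"
        )
        for r in sorted(results, key=lambda r: (r.p_bonf, r.group, r.factor)):
            fh.write(
                f"{r.group}\t{r.factor}\t{r.observed}\t{r.total}\t"
                f"{r.fraction:.6g}\t{r.fold:.4g}\t{r.p_raw:.4g}\t{r.p_bonf:.4g}\t"
                f"{r.n_tests}\t{r.direction}\t{int(r.significant)}\n"
            )


def _write_profiles(profiles, uniformity, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "subfamily\tfactor\tn_events\tpeak_bin\tuniformity_p\tmethod\n"
        )
        for (sub, factor), prof in sorted(profiles.items()):
            ut = uniformity[(sub, factor)]
            p = f"{ut.p_value:.4g}" if ut.p_value is not None else "NA"
            fh.write(
                f"{sub}\t{factor}\t{prof.n_events}\t{prof.peak_bin}\t{p}\t"
                f"{ut.method}\n"
            )


def _write_motif_hits(motif_hits, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("subfamily\tfactor\tmotif\tposition\tstrand\tscore\tp\n")
        for (sub, factor), hits in sorted(motif_hits.items()):
            for h in hits:
                fh.write(
                    f"{sub}\t{factor}\t{h.motif}\t{h.position}\t{h.strand}\t"
                    f"{h.score:.3f}\t{h.p_value:.3g}\n"
                )


def _write_state_props(props, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("subset\trollup\tproportion\n")
        for subset, table in props.items():
            for rollup, p in sorted(table.items()):
                fh.write(f"{subset}\t{rollup}\t{p:.6g}\n")


def _write_origins(calls, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tfactor\tte_category\torigin_clade\t"
            "most_distant_species\tinconsistent\n"
        )
        for c in calls:
            s = c.event.summit
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.factor}\t{c.te_category}\t"
                f"{c.origin_clade}\t{c.most_distant_species or '-'}\t"
                f"{int(c.inconsistent)}\n"
            )


def _write_composition(composition, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tclade\tproportion\n")
        for group, table in sorted(composition.items()):
            for clade, p in sorted(table.items()):
                fh.write(f"{group}\t{clade}\t{p:.6g}\n")


def _write_coloc(coloc, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "factor_a\tfactor_b\tcategory\tn_a\tn_both\tobserved\tbaseline\t"
            "fold\tchi2\tp\ttestable\n"
        )
        for r in coloc:
            fold = f"{r.fold:.4g}" if r.fold is not None else "NA"
            stat = f"{r.chi2_stat:.4g}" if r.chi2_stat is not None else "NA"
            p = f"{r.p_value:.4g}" if r.p_value is not None else "NA"
            fh.write(
                f"{r.factor_a}\t{r.factor_b}\t{r.category}\t{r.n_a_bound}\t"
                f"{r.n_both}\t{r.observed:.4g}\t{r.baseline:.4g}\t{fold}\t"
                f"{stat}\t{p}\t{int(r.testable)}\n"
            )


def _write_run_record(config: RunConfig, out: Path) -> None:
    from . import __version__

    params = {
        k: str(v) if isinstance(v, Path) else v
        for k, v in vars(config).items()
    }
    blob = json.dumps(params, sort_keys=True).encode()
    record = {
        "version": __version__,
        "parameters": params,
        "parameter_hash": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
    }
    with open(out / "run_record.json", "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
        fh.write("\n")
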