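"""Genomic fractions, summit/copy intersection, the two-tailed binomial,
and family-level enrichment, each against an independent oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from tecisreg import te_enrichment as te
from tecisreg.formats_io import BedInterval, GenomeIndex, PeakSummit, TECopy


def _copy(chrom, start, end, sub="S1", fam="F1", cls="SINE", cid=None, div=10.0):
    return TECopy(chrom, start, end, "+", sub, fam, cls, div, cid or f"{chrom}:{start}")


def _genome(**lengths):
    return GenomeIndex(list(lengths), dict(lengths))


class TestGenomeFraction:
    def test_single_copy(self):
        g = _genome(chr1=1000)
        frac = te.genome_fraction([_copy("chr1", 100, 200, fam="X")], g, "family")
        assert frac == {"X": pytest.approx(0.1)}

    def test_overlapping_copies_union_semantics(self):
        g = _genome(chr1=1000)
        copies = [
            _copy("chr1", 100, 200, fam="X", cid="a"),
            _copy("chr1", 150, 250, fam="X", cid="b"),
        ]
        assert te.genome_fraction(copies, g, "family")["X"] == pytest.approx(0.15)

    def test_excluded_chromosome_out_of_numerator_and_denominator(self):
        g = GenomeIndex(["chr1", "chrY"], {"chr1": 1000, "chrY": 500}, {"chrY"})
        copies = [
            _copy("chr1", 0, 100, fam="X", cid="a"),
            _copy("chrY", 0, 400, fam="X", cid="y"),
        ]
        assert te.genome_fraction(copies, g, "family")["X"] == pytest.approx(0.1)

    def test_bitmap_oracle_random(self):
        rng = np.random.default_rng(5)
        g = _genome(chr1=5000, chr2=3000)
        copies = []
        for i in range(120):
            chrom = "chr1" if rng.random() < 0.6 else "chr2"
            start = int(rng.integers(0, g.chrom_lengths[chrom] - 100))
            copies.append(
                _copy(chrom, start, start + int(rng.integers(10, 100)),
                      fam=f"F{i % 4}", cid=f"c{i}")
            )
        fracs = te.genome_fraction(copies, g, "family")
        for fam in {c.family for c in copies}:
            bitmap = {c: np.zeros(L, bool) for c, L in g.chrom_lengths.items()}
            for c in copies:
                if c.family == fam:
                    bitmap[c.chrom][c.start:c.end] = True
            expect = sum(b.sum() for b in bitmap.values()) / g.total_length
            assert fracs[fam] == pytest.approx(expect)


class TestIntersectSummits:
    def test_inside_and_half_open_boundary(self):
        copies = [_copy("chr1", 100, 200, cid="c1")]
        summits = [PeakSummit("chr1", 150, "ERa"), PeakSummit("chr1", 200, "ERa")]
        ev_in, ev_out = te.intersect_summits(summits, copies)
        assert ev_in.in_te and ev_in.copy_id == "c1"
        assert not ev_out.in_te

    def test_start_boundary_inside(self):
        copies = [_copy("chr1", 100, 200, cid="c1")]
        (ev,) = te.intersect_summits([PeakSummit("chr1", 100, "ERa")], copies)
        assert ev.in_te

    def test_tie_break_smallest_start_then_id(self):
        copies = [
            _copy("chr1", 100, 300, cid="zzz"),
            _copy("chr1", 120, 320, cid="aaa"),
        ]
        (ev,) = te.intersect_summits([PeakSummit("chr1", 150, "ERa")], copies)
        assert ev.copy_id == "zzz"  # smaller start wins over smaller id
        same_start = [
            _copy("chr1", 100, 300, cid="zzz"),
            _copy("chr1", 100, 320, cid="aaa"),
        ]
        (ev,) = te.intersect_summits([PeakSummit("chr1", 150, "ERa")], same_start)
        assert ev.copy_id == "aaa"

    def test_exhaustive_overlap_oracle_random(self):
        rng = np.random.default_rng(9)
        copies = [
            _copy("chr1", s, s + int(rng.integers(20, 120)), cid=f"c{i}")
            for i, s in enumerate(rng.integers(0, 2000, 80))
        ]
        summits = [
            PeakSummit("chr1", int(p), "ERa") for p in rng.integers(0, 2100, 300)
        ]
        events = te.intersect_summits(summits, copies)
        for s, ev in zip(summits, events):
            containing = [c for c in copies if c.start <= s.pos < c.end]
            if not containing:
                assert not ev.in_te
            else:
                best = min(containing, key=lambda c: (c.start, c.copy_id))
                assert ev.copy_id == best.copy_id

    def test_excluded_chrom_dropped(self):
        g = GenomeIndex(["chr1", "chrY"], {"chr1": 1000, "chrY": 1000}, {"chrY"})
        events = te.intersect_summits(
            [PeakSummit("chrY", 10, "ERa"), PeakSummit("chr1", 10, "ERa")],
            [], g,
        )
        assert len(events) == 1 and events[0].summit.chrom == "chr1"


class TestBinomTwoTailed:
    def test_degenerate_near_one(self):
        assert te.binom_two_tailed(100, 100, 1 - 1e-12) == pytest.approx(1.0)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            te.binom_two_tailed(1, 10, 0.0)

    def test_symmetry_at_half(self):
        for k in range(11):
            assert te.binom_two_tailed(k, 10, 0.5) == pytest.approx(
                te.binom_two_tailed(10 - k, 10, 0.5)
            )

    def test_enumeration_oracle(self):
        """Minimum-likelihood two-sided rule against explicit enumeration."""
        rng = np.random.default_rng(2)
        for _ in range(60):
            n = int(rng.integers(1, 21))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            pmf = [
                math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)
            ]
            expect = sum(q for q in pmf if q <= pmf[k] * (1 + 1e-7))
            assert te.binom_two_tailed(k, n, p) == pytest.approx(
                min(1.0, expect), rel=1e-9
            )

    def test_agrees_with_r_binom_test_convention(self):
        # scipy's binomtest implements the same environment convention and
        # serves as an independent cross-check of the hand enumeration
        from scipy.stats import binomtest

        for k, n, p in [(3, 10, 0.1), (12, 113, 0.01), (40, 100, 0.3)]:
            assert te.binom_two_tailed(k, n, p) == pytest.approx(
                binomtest(k, n, p).pvalue, rel=1e-9
            )


class TestFamilyEnrichment:
    def _events(self, positions, copies, factor="ERa"):
        summits = [PeakSummit("chr1", p, factor) for p in positions]
        return te.intersect_summits(summits, copies)

    def test_zero_observed_is_depleted(self):
        copies = [_copy("chr1", 0, 100, sub="S1", cid="c1")]
        events = self._events(range(500, 600), copies)
        (res,) = te.family_enrichment(
            events, copies, {"S1": 0.01}, ["ERa"], "subfamily"
        )
        assert res.direction == "depleted" and res.observed == 0
        assert res.p_bonf == pytest.approx(min(1.0, res.p_raw * 1))

    def test_planted_family_flagged_significant(self):
        rng = np.random.default_rng(0)
        copies = [_copy("chr1", 0, 1000, sub="HOT", cid="hot")]
        # 30% of 500 summits inside a family occupying 1% of the genome
        pos = [int(rng.integers(0, 1000)) for _ in range(150)] + [
            int(rng.integers(2000, 100_000)) for _ in range(350)
        ]
        events = self._events(pos, copies)
        (res,) = te.family_enrichment(
            events, copies, {"HOT": 0.01}, ["ERa"], "subfamily"
        )
        assert res.significant and res.direction == "enriched"

    def test_bonferroni_multiplier_counts_groups_times_factors(self):
        copies = [_copy("chr1", 0, 10, sub=f"S{i}", cid=f"c{i}") for i in range(536)]
        fractions = {f"S{i}": 0.0001 for i in range(536)}
        factors = ["ERa", "FoxA1", "GATA3", "AP2g"]
        events = []
        for f in factors:
            events.extend(self._events([5000], copies, f))
        results = te.family_enrichment(events, copies, fractions, factors)
        assert all(r.n_tests == 2144 for r in results)

    def test_zero_fraction_with_observations_raises(self):
        copies = [_copy("chr1", 0, 100, sub="S1", cid="c1")]
        events = self._events([50], copies)
        with pytest.raises(ValueError, match="mismatch"):
            te.family_enrichment(events, copies, {"S1": 0.0}, ["ERa"])

    def test_type_one_error_controlled_under_null(self, small_bundle):
        """Uniform random summits show no Bonferroni-significant group."""
        from tecisreg import formats_io as fio

        genome = fio.read_genome_index(small_bundle.sizes)
        tax = fio.read_taxonomy(small_bundle.taxonomy_file)
        copies = fio.read_repeatmasker_out(small_bundle.rmsk_out, tax)
        fractions = te.genome_fraction(copies, genome, "subfamily")
        n_sig = n_groups = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            chroms = genome.included_chroms
            lens = np.array([genome.chrom_lengths[c] for c in chroms])
            summits = []
            for _ in range(400):
                ci = rng.choice(len(chroms), p=lens / lens.sum())
                summits.append(
                    PeakSummit(chroms[ci], int(rng.integers(0, lens[ci])), "ERa")
                )
            events = te.intersect_summits(summits, copies, genome)
            results = te.family_enrichment(
                events, copies, fractions, ["ERa"], "subfamily"
            )
            n_sig += sum(r.significant for r in results)
            n_groups += len(results)
        assert n_sig / n_groups <= 0.05


def test_planted_enrichment_power_across_seeds(tmp_path):
    """At the generator's planted effect size the motif-bearing
    subfamilies are recovered as Bonferroni-significant in every seed."""
    from tecisreg import formats_io as fio
    from tecisreg.synthetic_data import simulate, small_config

    planted = {"MIR_toy", "L2_toy", "ERV1_toy"}
    n_hit = n_total = 0
    for seed in range(300, 306):
        bundle = simulate(small_config(seed), tmp_path / f"p{seed}")
        genome = fio.read_genome_index(bundle.sizes)
        tax = fio.read_taxonomy(bundle.taxonomy_file)
        copies = fio.read_repeatmasker_out(bundle.rmsk_out, tax)
        summits = []
        for factor, path in bundle.summit_files.items():
            summits.extend(fio.read_narrowpeak(path, factor))
        events = te.intersect_summits(summits, copies, genome)
        fractions = te.genome_fraction(copies, genome, "subfamily")
        results = te.family_enrichment(
            events, copies, fractions, list(bundle.summit_files), "subfamily"
        )
        flagged = {
            r.group for r in results if r.significant and r.direction == "enriched"
        }
        n_hit += len(planted & flagged)
        n_total += len(planted)
    assert n_hit / n_total >= 0.95


class TestAnnotationFraction:
    def test_length_threshold_is_strict(self):
        elements = [
            BedInterval("chr1", 0, 20, "lod=70"),  # length exactly 20: excluded
            BedInterval("chr1", 100, 121, "lod=70"),
        ]
        cnes = te.conserved_noncoding_elements(elements, [])
        assert [(c.start, c.end) for c in cnes] == [(100, 121)]

    def test_lod_threshold_is_strict(self):
        elements = [
            BedInterval("chr1", 0, 50, "lod=60"),
            BedInterval("chr1", 100, 150, "lod=61"),
        ]
        cnes = te.conserved_noncoding_elements(elements, [])
        assert [(c.start, c.end) for c in cnes] == [(100, 150)]

    def test_cds_subtraction_splits_element(self):
        elements = [BedInterval("chr1", 0, 100, "lod=70")]
        cds = [BedInterval("chr1", 40, 60)]
        cnes = te.conserved_noncoding_elements(elements, cds)
        assert [(c.start, c.end) for c in cnes] == [(0, 40), (60, 100)]

    def test_bitmap_oracle_random(self):
        rng = np.random.default_rng(4)
        regions = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(10, 80))
            regions.append(BedInterval("chr1", pos, pos + int(rng.integers(5, 50))))
            pos = regions[-1].end
        copies = [
            _copy("chr1", s, s + int(rng.integers(10, 90)),
                  cls=["SINE", "LINE"][i % 2], cid=f"c{i}")
            for i, s in enumerate(rng.integers(0, pos, 60))
        ]
        fracs = te.annotation_fraction(copies, regions, "te_class")
        total = max(max(r.end for r in regions), max(c.end for c in copies)) + 1
        region_bm = np.zeros(total, bool)
        for r in regions:
            region_bm[r.start:r.end] = True
        for cls in ("SINE", "LINE"):
            te_bm = np.zeros(total, bool)
            for c in copies:
                if c.te_class == cls:
                    te_bm[c.start:c.end] = True
            expect = (region_bm & te_bm).sum() / region_bm.sum()
            assert fracs.get(cls, 0.0) == pytest.approx(expect)

    def test_class_fractions_sum_below_one(self):
        rng = np.random.default_rng(8)
        regions = [BedInterval("chr1", 0, 10_000)]
        copies = [
            _copy("chr1", s, s + 50, cls=["SINE", "LINE", "LTR"][i % 3], cid=f"c{i}")
            for i, s in enumerate(rng.integers(0, 9_950, 40))
        ]
        fracs = te.annotation_fraction(copies, regions, "te_class")
        assert sum(fracs.values()) <= 1.0 + 1e-12
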