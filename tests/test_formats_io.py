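"""Parsers/writers: coordinate conventions, filters, inverse round-trips,
and the alignment column-walk oracle."""

from __future__ import annotations

import io

import numpy as np
import pytest

from tecisreg import formats_io as fio

RM_HEADER = (
    "   SW   perc perc perc  query  position in query  matching repeat ...\n"
    "score   div. del. ins.  sequence begin end (left) repeat class/family "
    "begin end (left) ID\n\n"
)


def _out_line(begin=101, end=200, strand="C", sub="MIR", cls="SINE/MIR", cid="7"):
    return (
        f"  225 25.3  0.0  0.0  chr1 {begin} {end} (0) {strand} {sub} {cls} "
        f"1 100 (0) {cid}\n"
    )


class TestRepeatMaskerOut:
    def test_coordinate_convention_and_strand(self):
        copies = fio.read_repeatmasker_out(io.StringIO(RM_HEADER + _out_line()))
        (c,) = copies
        assert (c.start, c.end, c.strand) == (100, 200, "-")
        assert c.divergence_pct == pytest.approx(25.3)
        assert c.subfamily == "MIR"

    @pytest.mark.parametrize(
        "sub,cls",
        [
            ("(TAACCC)n", "Simple_repeat"),
            ("ALR/Alpha", "Satellite/centr"),
            ("U6", "snRNA"),
        ],
    )
    def test_non_te_rows_dropped(self, sub, cls):
        text = RM_HEADER + _out_line(sub=sub, cls=cls) + _out_line(cid="8")
        copies = fio.read_repeatmasker_out(io.StringIO(text))
        assert [c.copy_id for c in copies] == ["8"]

    def test_malformed_column_count_reports_line(self):
        with pytest.raises(fio.ParseError, match="line 4"):
            fio.read_repeatmasker_out(io.StringIO(RM_HEADER + "chr1 100 200\n"))

    def test_unknown_subfamily_degrades_to_other(self):
        tax = fio.Taxonomy({"MIR": ("MIR", "SINE")})
        text = RM_HEADER + _out_line(sub="XYZ_novel", cls="LTR/ERV1", cid="9")
        (c,) = fio.read_repeatmasker_out(io.StringIO(text), tax)
        assert c.te_class == "other"

    def test_round_trip_50_records(self):
        rng = np.random.default_rng(42)
        copies = []
        for i in range(50):
            start = int(rng.integers(0, 10_000))
            copies.append(
                fio.TECopy(
                    chrom=f"chr{rng.integers(1, 3)}",
                    start=start,
                    end=start + int(rng.integers(50, 500)),
                    strand="+" if rng.random() < 0.5 else "-",
                    subfamily=f"SUB{i % 7}",
                    family=f"FAM{(i % 7) % 3}",
                    te_class=["SINE", "LINE", "LTR", "DNA"][(i % 7) % 4],
                    divergence_pct=round(float(rng.uniform(0, 30)), 1),
                    copy_id=f"cp{i}",
                )
            )
        buf = io.StringIO()
        fio.write_repeatmasker_out(copies, buf)
        buf.seek(0)
        tax = fio.Taxonomy(
            {c.subfamily: (c.family, c.te_class) for c in copies}
        )
        back = fio.read_repeatmasker_out(buf, tax)
        assert back == copies


class TestNarrowPeak:
    def _line(self, start, end, offset):
        return f"chr1\t{start}\t{end}\tpk\t0\t.\t5.0\t-1\t-1\t{offset}\n"

    def test_summit_from_offset(self):
        (s,) = fio.read_narrowpeak(io.StringIO(self._line(100, 200, 25)), "ERa")
        assert s.pos == 125 and s.factor == "ERa"

    def test_missing_offset_falls_back_to_midpoint(self, caplog):
        with caplog.at_level("WARNING"):
            (s,) = fio.read_narrowpeak(io.StringIO(self._line(100, 200, -1)), "ERa")
        assert s.pos == 150
        assert "midpoint" in caplog.text

    def test_round_trip_1000_records(self):
        rng = np.random.default_rng(0)
        summits = [
            fio.PeakSummit("chr1", int(p), "FoxA1", float(s), f"pk{i}")
            for i, (p, s) in enumerate(
                zip(rng.integers(200, 10**6, 1000), rng.uniform(0, 99, 1000).round(2))
            )
        ]
        buf = io.StringIO()
        fio.write_narrowpeak(summits, buf)
        buf.seek(0)
        back = fio.read_narrowpeak(buf, "FoxA1")
        assert [(s.chrom, s.pos, s.score) for s in back] == [
            (s.chrom, s.pos, s.score) for s in summits
        ]


IDENTITY_CHAIN = "chain 1000 chr1 100 + 10 20 chr1 100 + 10 20 1\n10\n\n"


class TestChain:
    def test_identity_chain(self):
        cs = fio.read_chain(io.StringIO(IDENTITY_CHAIN), "sp")
        (ch,) = cs.chains
        assert [ch.map_base(p) for p in range(10, 20)] == list(range(10, 20))
        assert ch.map_base(9) is None

    def test_block_sum_mismatch_raises_with_id(self):
        bad = "chain 1000 chr1 100 + 10 25 chr1 100 + 10 20 c77\n10\n\n"
        with pytest.raises(fio.ParseError, match="c77"):
            fio.read_chain(io.StringIO(bad))

    def test_minus_strand_query_normalized_to_forward(self):
        # query coords strand-relative: q 0..10 on '-' of a 100bp sequence
        text = "chain 5 chr1 50 + 0 10 chrQ 100 - 0 10 2\n10\n\n"
        (ch,) = fio.read_chain(io.StringIO(text)).chains
        # base 0 maps to reverse-strand 0 == forward 99
        assert ch.map_base(0) == 99
        assert ch.map_base(9) == 90

    def test_round_trip(self):
        rng = np.random.default_rng(3)
        chains = []
        for cid in range(5):
            t, q = 0, 0
            blocks = []
            for _ in range(rng.integers(1, 6)):
                size = int(rng.integers(5, 50))
                blocks.append((t, q, size))
                t += size + int(rng.integers(0, 10))
                q += size + int(rng.integers(0, 10))
            last_t = blocks[-1][0] + blocks[-1][2]
            last_q = blocks[-1][1] + blocks[-1][2]
            chains.append(
                fio.Chain(
                    str(cid), 100.0, "chr1", 10_000, blocks[0][0], last_t,
                    "chrQ", 10_000, "+", blocks[0][1], last_q, blocks,
                )
            )
        buf = io.StringIO()
        fio.write_chain(fio.ChainSet("sp", chains), buf)
        buf.seek(0)
        back = fio.read_chain(buf, "sp")
        assert [c.blocks for c in back.chains] == [c.blocks for c in chains]


class TestWig:
    def test_fixed_step_per_base(self):
        text = "fixedStep chrom=chr1 start=11 step=1\n1.0\n2.0\n3.0\n"
        track = fio.read_wig(io.StringIO(text))
        assert track.kind == "per_base"
        np.testing.assert_array_equal(
            track.values_at("chr1", np.array([10, 11, 12])), [1.0, 2.0, 3.0]
        )
        assert np.isnan(track.values_at("chr1", np.array([9]))[0])

    def test_windowed_values_apply_per_base(self):
        text = "fixedStep chrom=chr1 start=1 step=20 span=20\n5.0\n7.0\n"
        track = fio.read_wig(io.StringIO(text))
        assert track.kind == "windowed"
        assert track.values_at("chr1", np.array([0]))[0] == 5.0
        assert track.values_at("chr1", np.array([19]))[0] == 5.0
        assert track.values_at("chr1", np.array([20]))[0] == 7.0

    def test_bedgraph(self):
        track = fio.read_wig(io.StringIO("chr2\t100\t110\t4.5\n"))
        assert track.values_at("chr2", np.array([105]))[0] == 4.5

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(-1, 1, 200).round(4)
        track = fio.SignalTrack({"chr1": [(50, 1, vals)]}, "per_base")
        buf = io.StringIO()
        fio.write_wig(track, buf, precision=6)
        buf.seek(0)
        back = fio.read_wig(buf)
        np.testing.assert_allclose(
            back.values_at("chr1", np.arange(50, 250)), vals, rtol=1e-4
        )


class TestPfmAndTree:
    def test_jaspar_counts_normalize(self):
        text = (
            ">M1\nA [ 10 0 ]\nC [ 0 10 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        )
        (m,) = fio.read_pfm(io.StringIO(text), pseudocount=0.0)
        np.testing.assert_allclose(m.matrix.sum(axis=1), 1.0)
        assert m.matrix[0, 0] == 1.0 and m.matrix[1, 1] == 1.0

    def test_newick_most_distant_leaf(self):
        tree = fio.read_tree(io.StringIO("((A,B),C);"))
        depths = {
            t.name: len(tree.get_path(t)) for t in tree.get_terminals()
        }
        # C attaches at the root: the shallowest split from A
        assert depths["C"] < depths["A"]


def _naive_column_walk(align_text: str, chrom: str, cons_name: str):
    """Independent per-base genome->consensus map from .align text."""
    lines = align_text.splitlines()
    mapping = {}
    g = c = None
    strand = "+"
    for line in lines:
        parts = line.split()
        if parts and parts[0].isdigit() and len(parts) > 8:  # header
            strand = "-" if parts[8] == "C" else "+"
            continue
        if len(parts) >= 4 and parts[0] == chrom:
            if g is None:
                g = int(parts[1]) - 1
            q_chunk = parts[2]
        elif len(parts) >= 4 and parts[0] in ("C", cons_name):
            chunk = parts[3] if parts[0] == "C" else parts[2]
            start = int(parts[2]) - 1 if parts[0] == "C" else int(parts[1]) - 1
            if c is None:
                c = start
            for qb, cb in zip(q_chunk, chunk):
                if qb != "-" and cb != "-":
                    mapping[g] = c
                    g += 1
                    c += 1 if strand == "+" else -1
                elif qb == "-":
                    c += 1 if strand == "+" else -1
                else:
                    g += 1
    return mapping


class TestAlign:
    def _write(self, blocks, strand, cons_len, rng):
        cons = "".join(rng.choice(list("ACGT"), cons_len))
        genome_len = blocks[-1][0] + blocks[-1][2] + 50
        genome = "".join(rng.choice(list("ACGT"), genome_len))
        aln = fio.CopyAlignment("cp1", "CONS1", blocks, strand, cons_len)
        buf = io.StringIO()
        fio.write_repeatmasker_align(
            [aln], {"CONS1": cons}, {"chr1": genome}, {"cp1": "chr1"}, buf
        )
        return aln, buf.getvalue()

    def test_ungapped_plus(self):
        rng = np.random.default_rng(0)
        aln, text = self._write([(1000, 50, 100)], "+", 200, rng)
        (back,) = fio.read_repeatmasker_align(io.StringIO(text))
        assert back.blocks == [(1000, 50, 100)]
        assert back.consensus_length == 200

    def test_genomic_insertion_splits_blocks(self):
        rng = np.random.default_rng(1)
        # 5-bp genomic insertion: consensus contiguous, genome jumps by 5
        blocks = [(1000, 50, 40), (1045, 90, 40)]
        _, text = self._write(blocks, "+", 200, rng)
        (back,) = fio.read_repeatmasker_align(io.StringIO(text))
        assert back.blocks == blocks

    def test_span_exceeding_consensus_length_raises(self):
        with pytest.raises(ValueError, match="cpX"):
            fio.CopyAlignment("cpX", "CONS1", [(0, 150, 100)], "+", 200)

    @staticmethod
    def _random_blocks(rng, strand, cons_len):
        """Random gapless blocks with genomic insertions and consensus
        deletions between them, consistent with the strand convention."""
        n_blocks = int(rng.integers(2, 5))
        lens = [int(rng.integers(10, 40)) for _ in range(n_blocks)]
        g = int(rng.integers(500, 600))
        blocks = []

        def gaps():
            g_gap, c_gap = int(rng.integers(0, 8)), int(rng.integers(0, 8))
            if g_gap == 0 and c_gap == 0:
                g_gap = 1  # contiguous-in-both would merge into one block
            return g_gap, c_gap

        if strand == "+":
            c = int(rng.integers(0, 20))
            for ln in lens:
                blocks.append((g, c, ln))
                g_gap, c_gap = gaps()
                g += ln + g_gap
                c += ln + c_gap
        else:
            c_high = cons_len - int(rng.integers(0, 20))
            for ln in lens:
                c_high -= ln
                blocks.append((g, c_high, ln))
                g_gap, c_gap = gaps()
                g += ln + g_gap
                c_high -= c_gap
        if blocks[-1][1] < 0:
            return None
        return blocks

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_column_walk_oracle_random_gapped(self, strand):
        rng = np.random.default_rng(99)
        n_checked = 0
        while n_checked < 20:
            blocks = self._random_blocks(rng, strand, 300)
            if blocks is None:
                continue
            aln, text = self._write(blocks, strand, 300, rng)
            (back,) = fio.read_repeatmasker_align(io.StringIO(text))
            assert back.blocks == aln.blocks
            oracle = _naive_column_walk(text, "chr1", "CONS1")
            for gpos in range(aln.genome_start, aln.genome_end):
                assert back.map_base(gpos) == oracle.get(gpos)
            n_checked += 1


class TestBundleParsers:
    def test_taxonomy_round_trip(self, tmp_path):
        tax = fio.Taxonomy({"MIR": ("MIR", "SINE"), "L2a": ("L2", "LINE")})
        path = tmp_path / "tax.tsv"
        fio.write_taxonomy(tax, path)
        assert fio.read_taxonomy(path).table == tax.table

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"chr1": "ACGTACGTAC" * 20, "chr2": "TTTTAAAACC"}
        path = tmp_path / "g.fa"
        fio.write_fasta(seqs, path)
        assert fio.read_fasta(path) == seqs

    def test_lod_parsing(self):
        assert fio.lod_of(fio.BedInterval("chr1", 0, 10, "lod=83")) == 83
        assert fio.lod_of(fio.BedInterval("chr1", 0, 10, ".", 42.0)) == 42.0
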