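"""Readers and writers for the external formats the pipeline touches.

Every genomic interval inside the package is 0-based half-open on the
forward strand of the reference.  The conversion from each format's native
convention (RepeatMasker .out is 1-based inclusive, UCSC chain query
coordinates may be reverse-strand-relative, wiggle is 1-based) happens in
this module and nowhere else.

All readers accept a path (``str``/``Path``, transparently gunzipped when it
ends in ``.gz``) or an open text stream.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np
from Bio import Phylo, SeqIO

logger = logging.getLogger(__name__)

PathOrStream = Union[str, Path, TextIO]

TE_CLASSES = ("SINE", "LINE", "LTR", "DNA", "other")

#: RepeatMasker class labels excluded from TE analysis: tandem/satellite
#: repeats and structural small RNAs are not transposable elements.
NON_TE_CLASSES = frozenset(
    {
        "Satellite",
        "Simple_repeat",
        "snRNA",
        "tRNA",
        "rRNA",
        "srpRNA",
        "scRNA",
        "snoRNA",
        "RNA",
    }
)


class ParseError(ValueError):
    """Malformed input with location information."""


def _open_text(source: PathOrStream, mode: str = "rt"):
    """Return (stream, needs_close) for a path or pass-through stream."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, mode), True
    return open(path, mode), True


# ---------------------------------------------------------------------------
# genome index
# ---------------------------------------------------------------------------


@dataclass
class GenomeIndex:
    """Chromosome names/lengths plus the set of chromosomes excluded from
    genome-wide denominators (the study excludes chrY for female-derived
    cell lines)."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    excluded_chroms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            if self.chrom_lengths.get(name, 0) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        unknown = self.excluded_chroms - set(self.chrom_names)
        if unknown:
            raise ValueError(f"excluded chromosomes not in genome: {sorted(unknown)}")

    @property
    def included_chroms(self) -> list[str]:
        return [c for c in self.chrom_names if c not in self.excluded_chroms]

    @property
    def total_length(self) -> int:
        """Total length of non-excluded chromosomes."""
        return sum(self.chrom_lengths[c] for c in self.included_chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


def read_genome_index(
    source: PathOrStream, exclude_chroms: Iterable[str] = ()
) -> GenomeIndex:
    """Read a two-column ``chrom<TAB>length`` sizes file."""
    stream, close = _open_text(source)
    try:
        names, lengths = [], {}
        for lineno, line in enumerate(stream, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"sizes line {lineno}: expected 2 columns")
            names.append(parts[0])
            lengths[parts[0]] = int(parts[1])
    finally:
        if close:
            stream.close()
    return GenomeIndex(names, lengths, set(exclude_chroms) & set(names))


def write_genome_index(genome: GenomeIndex, dest: PathOrStream) -> None:
    stream, close = _open_text(dest, "wt")
    try:
        for name in genome.chrom_names:
            stream.write(f"{name}\t{genome.chrom_lengths[name]}\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


@dataclass
class Taxonomy:
    """Subfamily -> (family, class) lookup.

    Unknown subfamilies degrade to family = subfamily, class = "other"
    with a logged warning instead of failing.
    """

    table: dict[str, tuple[str, str]]

    def family(self, subfamily: str) -> str:
        entry = self.table.get(subfamily)
        return entry[0] if entry else subfamily

    def te_class(self, subfamily: str) -> str:
        entry = self.table.get(subfamily)
        if entry is None:
            return "other"
        return entry[1] if entry[1] in TE_CLASSES else "other"

    def __contains__(self, subfamily: str) -> bool:
        return subfamily in self.table


def read_taxonomy(source: PathOrStream) -> Taxonomy:
    """Read a ``subfamily<TAB>family<TAB>class`` TSV."""
    stream, close = _open_text(source)
    try:
        table = {}
        for line in stream:
            if not line.strip() or line.startswith("#"):
                continue
            sub, fam, cls = line.rstrip("\n").split("\t")[:3]
            table[sub] = (fam, cls)
    finally:
        if close:
            stream.close()
    return Taxonomy(table)


def write_taxonomy(tax: Taxonomy, dest: PathOrStream) -> None:
    stream, close = _open_text(dest, "wt")
    try:
        stream.write("#subfamily\tfamily\tclass\n")
        for sub, (fam, cls) in tax.table.items():
            stream.write(f"{sub}\t{fam}\t{cls}\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# TE copies (RepeatMasker .out)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TECopy:
    """One annotated repeat interval: a single RepeatMasker .out row.

    ``divergence_pct`` is the substitution distance (in percent) of the copy
    from its subfamily consensus, the usual proxy for insertion age.
    """

    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    subfamily: str
    family: str
    te_class: str
    divergence_pct: float
    copy_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.copy_id}: empty interval {self.start}..{self.end}")
        if self.divergence_pct < 0:
            raise ValueError(f"{self.copy_id}: negative divergence")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


_RM_HEADER_RE = re.compile(r"^\s*(SW|score|$)")


def _is_non_te(class_family: str) -> bool:
    top = class_family.split("/")[0]
    return top in NON_TE_CLASSES


def read_repeatmasker_out(
    source: PathOrStream, taxonomy: Optional[Taxonomy] = None
) -> list[TECopy]:
    """Parse RepeatMasker .out annotation into :class:`TECopy` records.

    Native coordinates are 1-based inclusive; strand 'C' means minus.
    Satellite, simple-repeat and small-RNA rows are dropped (and counted in
    a log message); they are not transposable elements.  The class of each
    copy comes from the taxonomy table when given, else from the
    class/family column of the .out row.
    """
    stream, close = _open_text(source)
    copies: list[TECopy] = []
    n_dropped = 0
    unknown_subfamilies: set[str] = set()
    try:
        for lineno, line in enumerate(stream, 1):
            if _RM_HEADER_RE.match(line):
                continue
            parts = line.split()
            if len(parts) < 15:
                raise ParseError(
                    f".out line {lineno}: expected >=15 columns, got {len(parts)}"
                )
            chrom, begin, end = parts[4], int(parts[5]), int(parts[6])
            strand = "-" if parts[8] in ("C", "-") else "+"
            subfamily, class_family = parts[9], parts[10]
            if _is_non_te(class_family):
                n_dropped += 1
                continue
            if taxonomy is not None:
                family = taxonomy.family(subfamily)
                te_class = taxonomy.te_class(subfamily)
                if subfamily not in taxonomy:
                    unknown_subfamilies.add(subfamily)
            else:
                family = class_family.split("/")[-1]
                top = class_family.split("/")[0]
                te_class = top if top in TE_CLASSES else "other"
            copies.append(
                TECopy(
                    chrom=chrom,
                    start=begin - 1,
                    end=end,
                    strand=strand,
                    subfamily=subfamily,
                    family=family,
                    te_class=te_class,
                    divergence_pct=float(parts[1]),
                    copy_id=parts[14],
                )
            )
    finally:
        if close:
            stream.close()
    if n_dropped:
        logger.info("dropped %d satellite/simple-repeat/small-RNA rows", n_dropped)
    for sub in sorted(unknown_subfamilies):
        logger.warning("subfamily %r absent from taxonomy; classified 'other'", sub)
    return copies


def write_repeatmasker_out(copies: Sequence[TECopy], dest: PathOrStream) -> None:
    """Write .out rows (1-based inclusive; minus strand as 'C')."""
    stream, close = _open_text(dest, "wt")
    try:
        stream.write(
            "   SW   perc perc perc  query      position in query           "
            "matching       repeat              position in repeat\n"
            "score   div. del. ins.  sequence    begin    end      (left)   "
            "repeat         class/family      begin  end    (left)   ID\n\n"
        )
        for c in copies:
            strand = "C" if c.strand == "-" else "+"
            stream.write(
                f"  225 {c.divergence_pct:5.1f}  0.0  0.0  {c.chrom} "
                f"{c.start + 1} {c.end} (0) {strand} {c.subfamily} "
                f"{c.te_class}/{c.family} 1 {c.end - c.start} (0) {c.copy_id}\n"
            )
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# per-copy consensus alignments (RepeatMasker .align)
# ---------------------------------------------------------------------------


@dataclass
class CopyAlignment:
    """Gapless-block decomposition of one copy's alignment to its consensus.

    Blocks are ``(genome_start, consensus_start, length)`` with both starts
    0-based and ``consensus_start`` always in consensus-forward orientation.
    For a '+' copy, walking the genome left to right walks the consensus
    forward; for a '-' copy it walks the consensus backward, and within a
    block position ``g`` maps to
    ``consensus_start + length - 1 - (g - genome_start)``.
    """

    copy_id: str
    consensus_name: str
    blocks: list[tuple[int, int, int]]
    strand: str
    consensus_length: int

    def __post_init__(self) -> None:
        prev_g_end = -1
        prev_c = None
        for gs, cs, ln in self.blocks:
            if ln <= 0:
                raise ValueError(f"{self.copy_id}: non-positive block length")
            if gs <= prev_g_end:
                raise ValueError(f"{self.copy_id}: blocks overlap in genome")
            if cs < 0 or cs + ln > self.consensus_length:
                raise ValueError(
                    f"{self.copy_id}: consensus span {cs}..{cs + ln} exceeds "
                    f"stated consensus length {self.consensus_length}"
                )
            if prev_c is not None:
                if self.strand == "+" and cs < prev_c:
                    raise ValueError(f"{self.copy_id}: consensus order not increasing")
                if self.strand == "-" and cs + ln > prev_c:
                    raise ValueError(f"{self.copy_id}: consensus order not decreasing")
            prev_g_end = gs + ln - 1
            prev_c = cs + ln if self.strand == "+" else cs

    @property
    def genome_start(self) -> int:
        return self.blocks[0][0]

    @property
    def genome_end(self) -> int:
        gs, _, ln = self.blocks[-1]
        return gs + ln

    def map_base(self, genome_pos: int) -> Optional[int]:
        """Exact consensus coordinate of one genome base, or None if the
        base falls in an alignment gap (genomic insertion)."""
        for gs, cs, ln in self.blocks:
            if gs <= genome_pos < gs + ln:
                off = genome_pos - gs
                if self.strand == "+":
                    return cs + off
                return cs + ln - 1 - off
        return None


_ALIGN_HEADER_RE = re.compile(
    r"^(\d+)\s+([\d.]+)\s+[\d.]+\s+[\d.]+\s+(\S+)\s+(\d+)\s+(\d+)\s+\(\d+\)\s+"
    r"([+C])\s+(\S+?)(?:#\S+)?\s+\(?(\d+)\)?\s+(\d+)\s+\(?(\d+)\)?\s+(\S+)"
)

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_repeatmasker_align(source: PathOrStream) -> list[CopyAlignment]:
    """Parse .align pairwise alignments into gapless blocks.

    The layout is the RepeatMasker alignment dump: a header row in the .out
    column order followed by wrapped pairs of sequence lines (query first,
    consensus second; consensus lines of minus-strand hits are prefixed
    with 'C' and carry descending coordinates).  Kimura-divergence footer
    lines and gap annotations are ignored.

    Blocks are built by a column walk of the alignment text, so the mapping
    is exact per base.
    """
    stream, close = _open_text(source)
    alignments: list[CopyAlignment] = []
    try:
        lines = stream.read().splitlines()
    finally:
        if close:
            stream.close()

    i = 0
    n = len(lines)
    while i < n:
        m = _ALIGN_HEADER_RE.match(lines[i])
        if not m:
            i += 1
            continue
        chrom = m.group(3)
        g_begin = int(m.group(4))  # 1-based
        strand = "-" if m.group(6) == "C" else "+"
        cons_name = m.group(7)
        copy_id = m.group(11)
        if strand == "+":
            c_begin, c_end, c_left = int(m.group(8)), int(m.group(9)), int(m.group(10))
        else:  # header shows (left) end begin for C hits
            c_left, c_end, c_begin = int(m.group(8)), int(m.group(9)), int(m.group(10))
        consensus_length = max(c_begin, c_end) + c_left
        i += 1
        q_seq_parts: list[str] = []
        c_seq_parts: list[str] = []
        while i < n:
            line = lines[i]
            if _ALIGN_HEADER_RE.match(line):
                break
            parts = line.split()
            if len(parts) >= 4 and parts[0] == chrom and parts[1].isdigit():
                q_seq_parts.append(parts[2])
            elif len(parts) >= 4 and parts[0] == "C" and parts[1] == cons_name:
                c_seq_parts.append(parts[3])
            elif len(parts) >= 4 and parts[0] == cons_name and parts[1].isdigit():
                c_seq_parts.append(parts[2])
            i += 1
        q_seq = "".join(q_seq_parts)
        c_seq = "".join(c_seq_parts)
        if len(q_seq) != len(c_seq):
            raise ParseError(
                f".align copy {copy_id}: query/consensus alignment rows differ "
                f"in length ({len(q_seq)} vs {len(c_seq)})"
            )
        blocks = _column_walk_blocks(
            q_seq, c_seq, g_begin - 1, c_begin - 1, c_end - 1, strand
        )
        try:
            alignments.append(
                CopyAlignment(copy_id, cons_name, blocks, strand, consensus_length)
            )
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
    return alignments


def _column_walk_blocks(
    q_seq: str,
    c_seq: str,
    g_start: int,
    c_begin: int,
    c_end: int,
    strand: str,
) -> list[tuple[int, int, int]]:
    """Walk alignment columns left to right and emit gapless blocks with
    consensus coordinates normalized to consensus-forward orientation."""
    blocks: list[tuple[int, int, int]] = []
    g = g_start
    # consensus cursor walks forward for '+', backward from c_end for '-'
    c = c_begin if strand == "+" else c_end
    run_g = run_c = run_len = 0
    in_run = False

    def flush() -> None:
        nonlocal in_run
        if in_run:
            if strand == "+":
                blocks.append((run_g, run_c, run_len))
            else:
                # run_c is the highest consensus coord of the run
                blocks.append((run_g, run_c - run_len + 1, run_len))
            in_run = False

    for qc, cc in zip(q_seq, c_seq):
        q_gap = qc == "-"
        c_gap = cc == "-"
        if not q_gap and not c_gap:
            if not in_run:
                run_g, run_c, run_len, in_run = g, c, 0, True
            run_len += 1
            g += 1
            c = c + 1 if strand == "+" else c - 1
        elif q_gap and not c_gap:
            flush()
            c = c + 1 if strand == "+" else c - 1
        elif c_gap and not q_gap:
            flush()
            g += 1
    flush()
    return blocks


def write_repeatmasker_align(
    alignments: Sequence[CopyAlignment],
    consensus_seqs: dict[str, str],
    genome_seqs: dict[str, str],
    chrom_of: dict[str, str],
    dest: PathOrStream,
    width: int = 50,
) -> None:
    """Emit .align text reconstructing the pairwise alignment from blocks.

    Bases between blocks on the genome side become consensus-gap columns;
    bases between blocks on the consensus side become genome-gap columns.
    """
    stream, close = _open_text(dest, "wt")
    try:
        for aln in alignments:
            chrom = chrom_of[aln.copy_id]
            cons = consensus_seqs[aln.consensus_name]
            gseq = genome_seqs[chrom]
            q_cols: list[str] = []
            c_cols: list[str] = []
            blocks = aln.blocks
            for bi, (gs, cs, ln) in enumerate(blocks):
                if bi > 0:
                    pgs, pcs, pln = blocks[bi - 1]
                    # genomic insertion between blocks -> consensus gaps
                    for g in range(pgs + pln, gs):
                        q_cols.append(gseq[g])
                        c_cols.append("-")
                    # consensus deletion between blocks -> genome gaps
                    if aln.strand == "+":
                        for c in range(pcs + pln, cs):
                            q_cols.append("-")
                            c_cols.append(cons[c])
                    else:
                        for c in range(pcs - 1, cs + ln - 1, -1):
                            q_cols.append("-")
                            c_cols.append(revcomp(cons[c]))
                for k in range(ln):
                    g = gs + k
                    q_cols.append(gseq[g])
                    if aln.strand == "+":
                        c_cols.append(cons[cs + k])
                    else:
                        c_cols.append(revcomp(cons[cs + ln - 1 - k]))
            q_aln = "".join(q_cols)
            c_aln = "".join(c_cols)
            g_begin = aln.genome_start + 1
            g_end = aln.genome_end
            if aln.strand == "+":
                c_begin = blocks[0][1] + 1
                c_end_ = blocks[-1][1] + blocks[-1][2]
                left = aln.consensus_length - c_end_
                hdr_cons = f"{c_begin} {c_end_} ({left})"
                strand_sym = "+"
            else:
                c_high = blocks[0][1] + blocks[0][2]  # 1-based top coordinate
                c_low = blocks[-1][1] + 1
                left = aln.consensus_length - c_high
                hdr_cons = f"({left}) {c_high} {c_low}"
                strand_sym = "C"
            stream.write(
                f"225 1.00 0.00 0.00 {chrom} {g_begin} {g_end} (0) {strand_sym} "
                f"{aln.consensus_name} {hdr_cons} {aln.copy_id}\n\n"
            )
            g_cursor = aln.genome_start
            c_cursor = (blocks[0][1]) if aln.strand == "+" else (
                blocks[0][1] + blocks[0][2] - 1
            )
            for off in range(0, len(q_aln), width):
                q_chunk = q_aln[off : off + width]
                c_chunk = c_aln[off : off + width]
                nq = sum(ch != "-" for ch in q_chunk)
                nc = sum(ch != "-" for ch in c_chunk)
                q_from = g_cursor + 1
                q_to = g_cursor + nq
                stream.write(f"  {chrom:20s} {q_from:>9d} {q_chunk} {q_to}\n")
                if aln.strand == "+":
                    c_from = c_cursor + 1
                    c_to = c_cursor + nc
                    stream.write(
                        f"  {aln.consensus_name:20s} {c_from:>9d} {c_chunk} {c_to}\n"
                    )
                    c_cursor += nc
                else:
                    c_from = c_cursor + 1
                    c_to = c_cursor - nc + 2
                    stream.write(
                        f"C {aln.consensus_name:20s} {c_from:>9d} {c_chunk} {c_to}\n"
                    )
                    c_cursor -= nc
                g_cursor += nq
            stream.write("\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# peak summits (narrowPeak)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakSummit:
    """Single-base position of maximal ChIP-seq signal within a peak."""

    chrom: str
    pos: int  # 0-based
    factor: str
    score: float = 0.0
    name: str = "."


def read_narrowpeak(source: PathOrStream, factor: str) -> list[PeakSummit]:
    """Read BED6+4 narrowPeak; summit = peak start + offset (column 10).

    An offset of -1 (peak caller did not report a summit) falls back to the
    interval midpoint, with a warning.
    """
    stream, close = _open_text(source)
    summits: list[PeakSummit] = []
    n_fallback = 0
    try:
        for lineno, line in enumerate(stream, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise ParseError(
                    f"narrowPeak line {lineno}: expected 10 columns, got {len(parts)}"
                )
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            offset = int(parts[9])
            if offset < 0:
                pos = (start + end) // 2
                n_fallback += 1
            else:
                pos = start + offset
            summits.append(
                PeakSummit(chrom, pos, factor, float(parts[6]), parts[3])
            )
    finally:
        if close:
            stream.close()
    if n_fallback:
        logger.warning(
            "%d peaks without summit offset; used interval midpoints", n_fallback
        )
    return summits


def write_narrowpeak(
    summits: Sequence[PeakSummit], dest: PathOrStream, half_width: int = 100
) -> None:
    """Write summits as narrowPeak intervals of ``summit ± half_width``."""
    stream, close = _open_text(dest, "wt")
    try:
        for s in summits:
            start = max(0, s.pos - half_width)
            stream.write(
                f"{s.chrom}\t{start}\t{s.pos + half_width}\t{s.name}\t0\t.\t"
                f"{s.score:g}\t-1\t-1\t{s.pos - start}\n"
            )
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# UCSC chains
# ---------------------------------------------------------------------------


@dataclass
class Chain:
    """One UCSC alignment chain from a source (target) to a query genome.

    ``blocks`` are ``(t_start, q_start, size)`` gapless segments; ``q_start``
    is strand-relative when ``q_strand`` is '-', matching the file format.
    """

    chain_id: str
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]]

    def map_base(self, t_pos: int) -> Optional[int]:
        """Map one source base to a forward-strand query coordinate."""
        for ts, qs, size in self.blocks:
            if ts <= t_pos < ts + size:
                q = qs + (t_pos - ts)
                if self.q_strand == "-":
                    return self.q_size - 1 - q
                return q
        return None

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.t_name and start < self.t_end and end > self.t_start


@dataclass
class ChainSet:
    """All chains for one species, indexed by source chromosome."""

    species: str
    chains: list[Chain]

    def overlapping(self, chrom: str, start: int, end: int) -> list[Chain]:
        return [c for c in self.chains if c.overlaps(chrom, start, end)]


def read_chain(source: PathOrStream, species: str = "") -> ChainSet:
    """Parse a UCSC chain file.

    Block sums are validated against the declared source/query interval
    sizes; a mismatch raises naming the chain id.
    """
    stream, close = _open_text(source)
    chains: list[Chain] = []
    try:
        header: Optional[list[str]] = None
        blocks: list[tuple[int, int, int]] = []
        t_cursor = q_cursor = 0

        def finish() -> None:
            nonlocal header, blocks
            if header is None:
                return
            (
                _,
                score,
                t_name,
                t_size,
                _t_strand,
                t_start,
                t_end,
                q_name,
                q_size,
                q_strand,
                q_start,
                q_end,
            ) = header[:12]
            chain_id = header[12] if len(header) > 12 else str(len(chains) + 1)
            ch = Chain(
                chain_id,
                float(score),
                t_name,
                int(t_size),
                int(t_start),
                int(t_end),
                q_name,
                int(q_size),
                q_strand,
                int(q_start),
                int(q_end),
                blocks,
            )
            if t_cursor != ch.t_end or q_cursor != ch.q_end:
                raise ParseError(
                    f"chain {chain_id}: block sums ({t_cursor},{q_cursor}) do not "
                    f"reach declared interval ends ({ch.t_end},{ch.q_end})"
                )
            chains.append(ch)
            header, blocks = None, []

        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish()
                header = line.split()
                t_cursor, q_cursor = int(header[5]), int(header[10])
                blocks = []
                continue
            parts = line.split()
            size = int(parts[0])
            blocks.append((t_cursor, q_cursor, size))
            t_cursor += size
            q_cursor += size
            if len(parts) == 3:
                t_cursor += int(parts[1])
                q_cursor += int(parts[2])
        finish()
    finally:
        if close:
            stream.close()
    return ChainSet(species, chains)


def write_chain(chain_set: ChainSet, dest: PathOrStream) -> None:
    stream, close = _open_text(dest, "wt")
    try:
        for ch in chain_set.chains:
            stream.write(
                f"chain {ch.score:.0f} {ch.t_name} {ch.t_size} + {ch.t_start} "
                f"{ch.t_end} {ch.q_name} {ch.q_size} {ch.q_strand} {ch.q_start} "
                f"{ch.q_end} {ch.chain_id}\n"
            )
            for bi, (ts, qs, size) in enumerate(ch.blocks):
                if bi + 1 < len(ch.blocks):
                    nts, nqs, _ = ch.blocks[bi + 1]
                    stream.write(f"{size}\t{nts - (ts + size)}\t{nqs - (qs + size)}\n")
                else:
                    stream.write(f"{size}\n")
            stream.write("\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# signal tracks (wiggle / bedGraph)
# ---------------------------------------------------------------------------


@dataclass
class SignalTrack:
    """Per-base or windowed numeric signal over chromosomes.

    Stored as ``(start, step, values)`` segments per chromosome; a windowed
    value applies piecewise-constant to every base of its window.  Bases
    not covered by any segment are missing (NaN).
    """

    segments: dict[str, list[tuple[int, int, np.ndarray]]]
    kind: str = "per_base"  # or "windowed"
    _dense: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def chroms(self) -> list[str]:
        return list(self.segments)

    def _densify(self, chrom: str) -> np.ndarray:
        if chrom not in self._dense:
            segs = self.segments.get(chrom, [])
            if not segs:
                self._dense[chrom] = np.full(0, np.nan)
            else:
                length = max(start + step * len(vals) for start, step, vals in segs)
                arr = np.full(length, np.nan)
                for start, step, vals in segs:
                    if step == 1:
                        arr[start : start + len(vals)] = vals
                    else:
                        arr[start : start + step * len(vals)] = np.repeat(vals, step)
                self._dense[chrom] = arr
        return self._dense[chrom]

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Signal values at base positions; NaN outside covered segments."""
        arr = self._densify(chrom)
        positions = np.asarray(positions)
        out = np.full(positions.shape, np.nan)
        ok = (positions >= 0) & (positions < len(arr))
        out[ok] = arr[positions[ok]]
        return out


def read_wig(source: PathOrStream) -> SignalTrack:
    """Read fixedStep/variableStep wiggle or bedGraph into a SignalTrack.

    Wiggle coordinates are 1-based; bedGraph is 0-based half-open.
    """
    stream, close = _open_text(source)
    segments: dict[str, list[tuple[int, int, np.ndarray]]] = {}
    steps: set[int] = set()
    try:
        mode = None  # "fixed" | "variable" | "bedgraph"
        chrom, start, step, span = "", 0, 1, 1
        values: list[float] = []
        var_pairs: list[tuple[int, float]] = []

        def flush() -> None:
            nonlocal values, var_pairs
            if mode == "fixed" and values:
                segments.setdefault(chrom, []).append(
                    (start, step, np.asarray(values, dtype=float))
                )
                steps.add(step)
            elif mode == "variable" and var_pairs:
                for pos, val in var_pairs:
                    segments.setdefault(chrom, []).append(
                        (pos, span, np.asarray([val]))
                    )
                steps.add(span)
            values, var_pairs = [], []

        for line in stream:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                flush()
                mode = "fixed"
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                start = int(fields["start"]) - 1
                step = int(fields.get("step", 1))
                continue
            if line.startswith("variableStep"):
                flush()
                mode = "variable"
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                continue
            parts = line.split()
            if mode == "fixed":
                values.append(float(parts[0]))
            elif mode == "variable":
                var_pairs.append((int(parts[0]) - 1, float(parts[1])))
            else:  # bedGraph
                c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                segments.setdefault(c, []).append((s, e - s, np.asarray([v])))
                steps.add(e - s)
        flush()
    finally:
        if close:
            stream.close()
    kind = "per_base" if steps == {1} else "windowed"
    return SignalTrack(segments, kind)


def write_wig(track: SignalTrack, dest: PathOrStream, precision: int = 4) -> None:
    """Write fixedStep wiggle (one declaration per stored segment)."""
    stream, close = _open_text(dest, "wt")
    try:
        for chrom, segs in track.segments.items():
            for start, step, vals in segs:
                stream.write(
                    f"fixedStep chrom={chrom} start={start + 1} step={step}"
                    + (f" span={step}" if step > 1 else "")
                    + "\n"
                )
                fmt = f"%.{precision}g"
                stream.write("\n".join(fmt % v for v in vals))
                stream.write("\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# motifs (JASPAR / MEME minimal)
# ---------------------------------------------------------------------------

ALPHABET = "ACGT"


@dataclass
class MotifPWM:
    """Position weight matrix over ACGT with an explicit background model.

    ``matrix[i, j]`` is the probability of base ``ACGT[j]`` at motif
    position ``i`` after pseudocount regularization.
    """

    name: str
    matrix: np.ndarray  # (length, 4) probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p_matrix / p_background) score matrix in bits."""
        return np.log2(self.matrix / self.background)

    def reverse_complement(self) -> "MotifPWM":
        return MotifPWM(
            self.name, self.matrix[::-1, ::-1].copy(), self.background[::-1].copy(),
            self.pseudocount,
        )


def pwm_from_counts(
    name: str,
    counts: np.ndarray,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.1,
) -> MotifPWM:
    counts = np.asarray(counts, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    reg = counts + pseudocount * bg[None, :] * 4 / 4  # uniform share of pseudocount
    probs = reg / reg.sum(axis=1, keepdims=True)
    return MotifPWM(name, probs, bg, pseudocount)


def read_pfm(source: PathOrStream, pseudocount: float = 0.1) -> list[MotifPWM]:
    """Read JASPAR PFM text (``>name`` then four count rows, bracketed or
    bare, in A/C/G/T order) into probability PWMs."""
    stream, close = _open_text(source)
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()
    motifs: list[MotifPWM] = []
    name = None
    rows: list[list[float]] = []

    def finish() -> None:
        nonlocal rows
        if name is not None and rows:
            if len(rows) != 4:
                raise ParseError(f"motif {name}: expected 4 rows, got {len(rows)}")
            counts = np.asarray(rows).T  # rows are per-base -> (length, 4)
            motifs.append(pwm_from_counts(name, counts, pseudocount=pseudocount))
        rows = []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            finish()
            name = line[1:].split()[0]
            continue
        cleaned = re.sub(r"^[ACGTacgt]\s*\[?", "", line)
        cleaned = cleaned.rstrip("]").strip()
        if cleaned:
            rows.append([float(x) for x in cleaned.split()])
    finish()
    return motifs


def write_pfm(motifs: Sequence[MotifPWM], dest: PathOrStream, scale: int = 100) -> None:
    """Write probability matrices as JASPAR-style integer count rows."""
    stream, close = _open_text(dest, "wt")
    try:
        for m in motifs:
            stream.write(f">{m.name}\n")
            counts = np.rint(m.matrix * scale).astype(int)
            for j, base in enumerate(ALPHABET):
                row = " ".join(str(x) for x in counts[:, j])
                stream.write(f"{base} [ {row} ]\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# trees, FASTA, genes, BED
# ---------------------------------------------------------------------------


def read_tree(source: PathOrStream):
    """Read a newick species tree (Bio.Phylo Tree)."""
    stream, close = _open_text(source)
    try:
        tree = Phylo.read(stream, "newick")
    finally:
        if close:
            stream.close()
    return tree


def read_fasta(source: PathOrStream) -> dict[str, str]:
    stream, close = _open_text(source)
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(stream, "fasta")}
    finally:
        if close:
            stream.close()


def write_fasta(seqs: dict[str, str], dest: PathOrStream, width: int = 70) -> None:
    stream, close = _open_text(dest, "wt")
    try:
        for name, seq in seqs.items():
            stream.write(f">{name}\n")
            for off in range(0, len(seq), width):
                stream.write(seq[off : off + width] + "\n")
    finally:
        if close:
            stream.close()


def read_tss(source: PathOrStream) -> dict[str, np.ndarray]:
    """Read a refFlat-like gene TSV (geneName, name, chrom, strand,
    txStart, txEnd, ...) and return sorted TSS positions per chromosome."""
    stream, close = _open_text(source)
    per_chrom: dict[str, list[int]] = {}
    try:
        for line in stream:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, strand = parts[2], parts[3]
            tx_start, tx_end = int(parts[4]), int(parts[5])
            tss = tx_start if strand == "+" else tx_end - 1
            per_chrom.setdefault(chrom, []).append(tss)
    finally:
        if close:
            stream.close()
    return {c: np.asarray(sorted(v)) for c, v in per_chrom.items()}


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0


def read_bed(source: PathOrStream) -> list[BedInterval]:
    """Read BED3-6 (name column carries e.g. a chromatin state or a
    ``lod=NN`` tag for conserved elements)."""
    stream, close = _open_text(source)
    out: list[BedInterval] = []
    try:
        for line in stream:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(
                BedInterval(
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    parts[3] if len(parts) > 3 else ".",
                    float(parts[4]) if len(parts) > 4 else 0.0,
                )
            )
    finally:
        if close:
            stream.close()
    return out


def write_bed(intervals: Sequence[BedInterval], dest: PathOrStream) -> None:
    stream, close = _open_text(dest, "wt")
    try:
        for iv in intervals:
            stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\n")
    finally:
        if close:
            stream.close()


def lod_of(interval: BedInterval) -> float:
    """Conservation lod score of a phastCons element (``lod=NN`` name tag,
    falling back to the BED score column)."""
    if interval.name.startswith("lod="):
        return float(interval.name[4:])
    return interval.score
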