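"""Shared genomic data model and plain-text format IO.

Coordinates are 1-based inclusive throughout the data model (GFF/SAM
convention); any half-open arithmetic is internal to a function and noted
where it occurs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

CATEGORIES = ("annotated", "hypothetical", "pseudogene", "ribosomal", "bgc")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class InputError(ValueError):
    """Raised for malformed or inconsistent input files."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    """A sequence record with optional mean per-base read depth."""

    id: str
    seq: str
    depth: float | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise InputError(f"contig {self.id}: non-DNA characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneRecord:
    """A located coding feature with a category label.

    ``cds_seq`` is the strand-corrected (in reading direction) substring of
    the parent contig; its length is divisible by 3 except for pseudogenes.
    """

    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    category: str
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.category not in CATEGORIES:
            raise InputError(
                f"gene {self.gene_id}: unknown category {self.category!r}; "
                f"allowed: {', '.join(CATEGORIES)}"
            )
        if not (1 <= self.start <= self.end):
            raise InputError(f"gene {self.gene_id}: bad coordinates {self.start}..{self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReadPairAlignment:
    """Primary alignments of both mates of one read pair.

    Each mate is ``(contig_id, leftmost 1-based position, aligned reference
    length, orientation '+'/'-')``.
    """

    read_id: str
    mate1: tuple[str, int, int, str]
    mate2: tuple[str, int, int, str]
    proper_pair: bool = True


@dataclass
class AlignedRead:
    """One primary SAM alignment with enough detail for pileup analysis."""

    read_id: str
    contig_id: str
    pos: int  # 1-based leftmost
    cigar: list[tuple[str, int]]  # [(op, length), ...]
    seq: str
    is_reverse: bool
    is_read1: bool
    mate_contig: str | None = None
    mate_pos: int | None = None

    @property
    def ref_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MDN=X")

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference position."""
        return self.pos + self.ref_length - 1


@dataclass
class AssemblyGraph:
    """Contig-end adjacency graph (GFA1 semantics, ends are '5p'/'3p')."""

    nodes: set[str] = field(default_factory=set)
    edges: set[frozenset[tuple[str, str]]] = field(default_factory=set)

    def add_edge(self, a: str, a_end: str, b: str, b_end: str) -> None:
        for node in (a, b):
            if node not in self.nodes:
                raise InputError(f"graph edge references unknown segment {node!r}")
        self.edges.add(frozenset([(a, a_end), (b, b_end)]))

    def has_edge(self, a: str, a_end: str, b: str, b_end: str) -> bool:
        return frozenset([(a, a_end), (b, b_end)]) in self.edges

    def neighbors(self, contig: str, end: str) -> list[tuple[str, str]]:
        out = []
        for edge in self.edges:
            pair = list(edge)
            if len(pair) == 1:  # self-loop on the same end
                if pair[0] == (contig, end):
                    out.append(pair[0])
                continue
            (a, a_end), (b, b_end) = pair
            if (a, a_end) == (contig, end):
                out.append((b, b_end))
            elif (b, b_end) == (contig, end):
                out.append((a, a_end))
        return sorted(out)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a FASTA file into a list of :class:`Contig`.

    The id is the header token before the first whitespace; sequences are
    uppercased and wrapped lines joined. A sequence line appearing before
    any header is a parse error naming the offending line number.
    """
    contigs: list[Contig] = []
    cur_id: str | None = None
    cur_chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        if cur_id is not None:
            if cur_id in seen:
                raise InputError(f"duplicate FASTA id {cur_id!r}")
            seen.add(cur_id)
            contigs.append(Contig(id=cur_id, seq="".join(cur_chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if len(line) > 1 else ""
                if not cur_id:
                    raise InputError(f"{path}: empty FASTA header at line {lineno}")
                cur_chunks = []
            else:
                if cur_id is None:
                    raise InputError(
                        f"{path}: sequence line before any header at line {lineno}"
                    )
                cur_chunks.append(line)
    flush()
    if not contigs:
        logger.warning("FASTA file %s contained no records", path)
    return contigs


def write_fasta(path: str | os.PathLike, contigs: Iterable[Contig], width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.id}\n")
            for i in range(0, len(contig.seq), width):
                fh.write(contig.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 + category table
# ---------------------------------------------------------------------------


def read_category_table(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column ``gene_id<TAB>category`` table."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gene_id, category = parts
            if category not in CATEGORIES:
                raise InputError(
                    f"{path}:{lineno}: unknown category {category!r}; "
                    f"allowed: {', '.join(CATEGORIES)}"
                )
            table[gene_id] = category
    return table


def write_category_table(path: str | os.PathLike, genes: Iterable[GeneRecord]) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            fh.write(f"{gene.gene_id}\t{gene.category}\n")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff_genes(
    gff_path: str | os.PathLike,
    category_table_path: str | os.PathLike,
    contigs: Sequence[Contig],
) -> list[GeneRecord]:
    """Read CDS features from GFF3 and attach categories and sequences.

    CDS features lacking a category default to "hypothetical" with a
    warning; coordinates outside the named contig are an error. ``contigs``
    supplies the sequences from which strand-corrected ``cds_seq`` is cut.
    """
    by_id = {c.id: c for c in contigs}
    categories = read_category_table(category_table_path)
    genes: list[GeneRecord] = []
    defaulted = 0
    with open(gff_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise InputError(f"{gff_path}:{lineno}: expected 9 columns")
            contig_id, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = parts
            if ftype != "CDS":
                continue
            if contig_id not in by_id:
                raise InputError(f"{gff_path}:{lineno}: unknown contig {contig_id!r}")
            contig = by_id[contig_id]
            start, end = int(start_s), int(end_s)
            if not (1 <= start <= end <= contig.length):
                raise InputError(
                    f"{gff_path}:{lineno}: coordinates {start}..{end} outside "
                    f"contig {contig_id} (length {contig.length})"
                )
            attrs = _parse_gff_attributes(attr_s)
            gene_id = attrs.get("ID")
            if not gene_id:
                raise InputError(f"{gff_path}:{lineno}: CDS lacks ID attribute")
            category = categories.get(gene_id)
            if category is None:
                category = "hypothetical"
                defaulted += 1
            sub = contig.seq[start - 1 : end]
            if strand == "-":
                sub = revcomp(sub)
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    category=category,
                    cds_seq=sub,
                )
            )
    if defaulted:
        logger.warning("%d CDS without category defaulted to 'hypothetical'", defaulted)
    return genes


def write_gff_genes(path: str | os.PathLike, genes: Iterable[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            fh.write(
                "\t".join(
                    [
                        gene.contig_id,
                        "symbgc",
                        "CDS",
                        str(gene.start),
                        str(gene.end),
                        ".",
                        gene.strand,
                        "0",
                        f"ID={gene.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=XB"


def _check_sam_references(path: str | os.PathLike) -> None:
    # pysam silently downgrades reads on unknown references to "unmapped";
    # pre-scan the text so they are a hard error instead
    refs: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for fld in line.rstrip("\n").split("\t"):
                        if fld.startswith("SN:"):
                            refs.add(fld[3:])
                continue
            parts = line.split("\t", 4)
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: truncated SAM line")
            rname = parts[2]
            if rname != "*" and rname not in refs:
                raise InputError(
                    f"{path}:{lineno}: reference {rname!r} absent from header"
                )


def read_sam(path: str | os.PathLike) -> list[AlignedRead]:
    """Read primary alignments from a SAM text file via pysam."""
    _check_sam_references(path)
    reads: list[AlignedRead] = []
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=True)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot parse SAM {path}: {exc}") from exc
    with sam:
        try:
            alns = list(sam.fetch(until_eof=True))
        except (OSError, ValueError) as exc:
            raise InputError(f"cannot parse SAM {path}: {exc}") from exc
        for aln in alns:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            cigar = [(_CIGAR_OPS[op], n) for op, n in (aln.cigartuples or [])]
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    contig_id=aln.reference_name,
                    pos=aln.reference_start + 1,
                    cigar=cigar,
                    seq=aln.query_sequence or "",
                    is_reverse=aln.is_reverse,
                    is_read1=not aln.is_read2,
                    mate_contig=(
                        aln.next_reference_name if aln.next_reference_id >= 0 else None
                    ),
                    mate_pos=(
                        aln.next_reference_start + 1 if aln.next_reference_start >= 0 else None
                    ),
                )
            )
    return reads


def pair_reads(reads: Sequence[AlignedRead]) -> list[ReadPairAlignment]:
    """Join mates by read id; unpaired reads are dropped with a logged count."""
    buckets: dict[str, list[AlignedRead]] = {}
    for read in reads:
        buckets.setdefault(read.read_id, []).append(read)
    pairs: list[ReadPairAlignment] = []
    dropped = 0
    for read_id, members in buckets.items():
        first = [m for m in members if m.is_read1]
        second = [m for m in members if not m.is_read1]
        if len(first) == 1 and len(second) == 1:
            m1, m2 = first[0], second[0]
            pairs.append(
                ReadPairAlignment(
                    read_id=read_id,
                    mate1=(m1.contig_id, m1.pos, m1.ref_length, "-" if m1.is_reverse else "+"),
                    mate2=(m2.contig_id, m2.pos, m2.ref_length, "-" if m2.is_reverse else "+"),
                    proper_pair=m1.contig_id == m2.contig_id,
                )
            )
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d reads without exactly one mate each", dropped)
    return pairs


def read_sam_pairs(path: str | os.PathLike) -> list[ReadPairAlignment]:
    """Read a SAM file and join mates into :class:`ReadPairAlignment`."""
    return pair_reads(read_sam(path))


def write_sam(
    path: str | os.PathLike,
    references: Sequence[Contig],
    reads: Sequence[AlignedRead],
) -> None:
    """Write alignments as SAM text with an @SQ header per reference."""

    def cigar_str(cigar: list[tuple[str, int]]) -> str:
        return "".join(f"{n}{op}" for op, n in cigar) or "*"

    by_id: dict[str, list[AlignedRead]] = {}
    for read in reads:
        by_id.setdefault(read.read_id, []).append(read)

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref in references:
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{ref.length}\n")
        for read in reads:
            flag = 1  # paired
            mates = by_id[read.read_id]
            mate = next((m for m in mates if m.is_read1 != read.is_read1), None)
            if mate is not None and mate.contig_id == read.contig_id:
                flag |= 2
            if read.is_reverse:
                flag |= 16
            if mate is not None and mate.is_reverse:
                flag |= 32
            flag |= 64 if read.is_read1 else 128
            rnext, pnext = "*", 0
            if mate is not None:
                rnext = "=" if mate.contig_id == read.contig_id else mate.contig_id
                pnext = mate.pos
            tlen = 0
            if mate is not None and mate.contig_id == read.contig_id:
                left = min(read.pos, mate.pos)
                right = max(read.end, mate.end)
                tlen = right - left + 1
                if read.pos > mate.pos or (read.pos == mate.pos and not read.is_read1):
                    tlen = -tlen
            fh.write(
                "\t".join(
                    [
                        read.read_id,
                        str(flag),
                        read.contig_id,
                        str(read.pos),
                        "60",
                        cigar_str(read.cigar),
                        rnext,
                        str(pnext),
                        str(tlen),
                        read.seq,
                        "I" * len(read.seq),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFA1
# ---------------------------------------------------------------------------


def read_gfa(path: str | os.PathLike) -> AssemblyGraph:
    """Read a GFA1 file (S and L lines) into an :class:`AssemblyGraph`.

    Orientation mapping per L line ``from orient to orient``: a ``+``
    from-segment contributes its 3' end (``-`` its 5'); a ``+`` to-segment
    its 5' end (``-`` its 3'). Duplicate links collapse into one edge.
    """
    graph = AssemblyGraph()
    links: list[tuple[str, str, str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "S":
                if len(parts) < 3:
                    raise InputError(f"{path}:{lineno}: malformed S line")
                graph.nodes.add(parts[1])
            elif parts[0] == "L":
                if len(parts) < 6:
                    raise InputError(f"{path}:{lineno}: malformed L line")
                _, from_seg, from_or, to_seg, to_or, _cigar = parts[:6]
                links.append((from_seg, from_or, to_seg, to_or))
    for from_seg, from_or, to_seg, to_or in links:
        a_end = "3p" if from_or == "+" else "5p"
        b_end = "5p" if to_or == "+" else "3p"
        graph.add_edge(from_seg, a_end, to_seg, b_end)
    return graph


def write_gfa(
    path: str | os.PathLike,
    contigs: Sequence[Contig],
    edges: Iterable[tuple[str, str, str, str]],
) -> None:
    """Write a GFA1 file; edges are ``(contig, end, contig, end)`` tuples."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for contig in contigs:
            fh.write(f"S\t{contig.id}\t{contig.seq}\n")
        for a, a_end, b, b_end in edges:
            from_or = "+" if a_end == "3p" else "-"
            to_or = "+" if b_end == "5p" else "-"
            fh.write(f"L\t{a}\t{from_or}\t{b}\t{to_or}\t0M\n")


# ---------------------------------------------------------------------------
# variant table (VCF-like TSV: CHROM POS ID REF ALT AD)
# ---------------------------------------------------------------------------


@dataclass
class VariantRow:
    """One row of a VCF-like variant table.

    Insertions use ``.`` as REF and ``+SEQ`` as ALT; AD is "ref,alt".
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    ad: tuple[int, int]

    @property
    def is_insertion(self) -> bool:
        return self.alt.startswith("+")

    @property
    def inserted_seq(self) -> str:
        if not self.is_insertion:
            raise ValueError(f"variant {self.id} is not an insertion")
        return self.alt[1:]


def read_variant_table(path: str | os.PathLike) -> list[VariantRow]:
    rows: list[VariantRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["CHROM", "POS", "ID", "REF", "ALT", "AD"]
        if header != expected:
            raise InputError(f"{path}: expected header {expected}, got {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise InputError(f"{path}:{lineno}: expected 6 columns")
            chrom, pos_s, vid, ref, alt, ad_s = parts
            ad_parts = ad_s.replace(" ", "").split(",")
            rows.append(
                VariantRow(
                    chrom=chrom,
                    pos=int(pos_s),
                    id=vid,
                    ref=ref,
                    alt=alt,
                    ad=(int(ad_parts[0]), int(ad_parts[1])),
                )
            )
    return rows


def write_variant_table(path: str | os.PathLike, rows: Iterable[VariantRow]) -> None:
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tID\tREF\tALT\tAD\n")
        for row in rows:
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t"
                f"{row.ad[0]},{row.ad[1]}\n"
            )


# ---------------------------------------------------------------------------
# homolog-length table
# ---------------------------------------------------------------------------


def read_homolog_table(path: str | os.PathLike) -> list[tuple[str, int, int | None]]:
    """Read ``gene_id<TAB>gene_aa_length<TAB>closest_homolog_aa_length``.

    A homolog length of ``.`` (or empty) means no homolog was found.
    """
    rows: list[tuple[str, int, int | None]] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("gene_id"):
            fh.seek(0)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(f"{path}:{lineno}: expected 3 columns")
            gene_id, own_s, hom_s = parts
            hom = None if hom_s in (".", "") else int(hom_s)
            rows.append((gene_id, int(own_s), hom))
    return rows


def write_homolog_table(
    path: str | os.PathLike, rows: Iterable[tuple[str, int, int | None]]
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgene_aa_length\tclosest_homolog_aa_length\n")
        for gene_id, own, hom in rows:
            fh.write(f"{gene_id}\t{own}\t{'.' if hom is None else hom}\n")
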