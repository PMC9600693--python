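"""Seeded generator of complete synthetic metagenome scenarios.

A scenario consists of a host "bin" of contigs with homogeneous base /
codon composition, one BGC region with shifted composition but
ribosomal-like codon usage, present in several near-identical copies
(one lacking a short leading segment), uniform-depth paired-end reads
emitted both as FASTQ and as SAM pre-aligned to the collapsed assembly,
gene sets in five categories, and a homolog-length table in which true
pseudogenes are detectable by the length-ratio rule.

Reads are aligned by coordinate projection from the repeat-expanded
genome onto the collapsed reference, so no external aligner is needed;
insertion-carrying copies produce reads with I CIGAR operations and
junction-spanning fragments produce mates on different contigs.
"""

from __future__ import annotations

import json
import logging
import math
import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from . import codon_adaptation as ca
from .sequence_io import (
    AlignedRead,
    AssemblyGraph,
    Contig,
    GeneRecord,
    InputError,
    ReadPairAlignment,
    pair_reads,
    revcomp,
    write_category_table,
    write_fasta,
    write_gfa,
    write_gff_genes,
    write_homolog_table,
    write_sam,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"

DEFAULT_N_GENES = {
    "annotated": 60,
    "hypothetical": 60,
    "pseudogene": 50,
    "ribosomal": 50,
    "bgc": 50,
}

# default injected variant geometry: three in-frame insertions (multiples
# of 3: 60, 24, 54 bp) plus one synonymous and one noncoding SNP
DEFAULT_INSERTION_LENGTHS = (60, 24, 54)


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic metagenome scenario."""

    seed: int = 1
    host_length: int = 300_000
    n_host_contigs: int = 12
    host_gc: float = 0.54
    bgc_length: int = 20_000
    bgc_gc: float = 0.46
    bgc_copy_number: int = 3
    leading_segment_length: int = 1_000
    leading_segment_copies: int = 2
    insertion_specs: list[tuple[int, str]] | None = None  # (position, sequence)
    snp_specs: list[tuple[int, str, str]] | None = None  # (position, ref, alt)
    read_length: int = 150
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    depth: float = 50.0
    error_rate: float = 0.0
    n_genes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_GENES))
    gene_length_range: tuple[int, int] = (60, 140)  # body codons
    pseudogene_truncation_fraction: float = 0.5
    ribosomal_codon_bias_strength: float = 12.0
    cai_bias_jitter_sd: float = 0.3
    compose_5mer_bias: bool = True  # informational: bias follows bgc_gc shift

    def validate(self) -> None:
        if self.depth <= 0:
            raise InputError("depth must be > 0")
        if self.bgc_copy_number < 1:
            raise InputError("bgc_copy_number must be >= 1")
        if self.leading_segment_copies < 1:
            raise InputError("leading_segment_copies must be >= 1")
        if not (0 < self.host_gc < 1 and 0 < self.bgc_gc < 1):
            raise InputError("gc fractions must be in (0, 1)")
        if self.insert_mean <= self.read_length:
            raise InputError("insert_mean must exceed read_length")
        if self.n_host_contigs < 2 * self.bgc_copy_number:
            raise InputError(
                "n_host_contigs must be >= 2 * bgc_copy_number to provide "
                "distinct flanking contexts"
            )
        if self.ribosomal_codon_bias_strength < 1:
            raise InputError("ribosomal_codon_bias_strength must be >= 1")
        if not (0 < self.pseudogene_truncation_fraction < 0.8):
            raise InputError("pseudogene_truncation_fraction must be in (0, 0.8)")
        for pos, seq in self.insertion_specs or []:
            if set(seq.upper()) - set(BASES):
                raise InputError(f"insertion at {pos}: sequence must be over ACGT")


@dataclass
class TrueVariant:
    position: int  # 1-based on the collapsed BGC; insertions go after it
    vtype: str  # "SNP" | "insertion"
    ref: str
    alt: str  # alt base, or inserted sequence
    carrier_copies: list[int]
    expected_class: str  # synonymous/nonsynonymous/noncoding/in_frame/...


@dataclass
class ScenarioTruth:
    """Ground truth for parameter-recovery tests."""

    config: ScenarioConfig
    segment_copy_numbers: dict[str, int]  # {"leading": ..., "body": ...}
    variants: list[TrueVariant]
    gene_categories: dict[str, str]
    pseudogenes: set[str]
    bgc_contig_id: str
    host_contig_ids: list[str]
    flanks_5p: list[str]  # upstream partners of copies that keep the leading segment
    flanks_internal: list[str]  # upstream partners of copies lacking it
    flanks_3p: list[str]  # downstream partners, one per copy


@dataclass
class ScenarioBundle:
    """In-memory scenario; files are only written when an outdir is given."""

    config: ScenarioConfig
    truth: ScenarioTruth
    contigs: list[Contig]  # collapsed assembly: host contigs + BGC contig
    genes: list[GeneRecord]
    alignments: list[AlignedRead]
    graph: AssemblyGraph
    homolog_table: list[tuple[str, int, int | None]]
    paths: dict[str, str] = field(default_factory=dict)

    @property
    def pairs(self) -> list[ReadPairAlignment]:
        return pair_reads(self.alignments)


# ---------------------------------------------------------------------------
# codon-level machinery
# ---------------------------------------------------------------------------

AMINO_ACIDS = sorted(ca.SYNONYMOUS_FAMILIES)


def _optimal_codon(aa: str) -> str:
    """Deterministic 'optimal' codon per amino acid: max GC, then lexicographic."""
    return max(
        ca.SYNONYMOUS_FAMILIES[aa], key=lambda c: (sum(b in "GC" for b in c), c)
    )

OPTIMAL_CODONS: dict[str, str] = {aa: _optimal_codon(aa) for aa in AMINO_ACIDS}


def equalized_bias_strengths(base_strength: float) -> dict[int, float]:
    """Per-family-size weight on the optimal codon equalizing E[ln w].

    With weight S on the optimal codon and 1 on each of the other s-1
    synonymous codons, the expected log relative-adaptiveness of a random
    codon is -(s-1) ln(S) / (S+s-1). Solving for S per family size makes
    this equal across sizes, so a gene's expected CAI does not depend on
    its amino-acid composition — only on how strongly codons are biased.
    """
    if base_strength <= 1.0:
        return {s: 1.0 for s in (1, 2, 3, 4, 6)}
    target = math.log(base_strength) / (base_strength + 1)
    out = {1: 1.0, 2: base_strength}
    for s in (3, 4, 6):
        f = lambda S, s=s: (s - 1) * math.log(S) / (S + s - 1) - target
        out[s] = float(brentq(f, base_strength, 1e12))
    return out


def _family_probs_background(gc: float) -> dict[str, np.ndarray]:
    """Within-family codon probabilities from i.i.d. bases at the given GC."""
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    probs = {}
    for aa, codons in ca.SYNONYMOUS_FAMILIES.items():
        weights = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
        probs[aa] = weights / weights.sum()
    return probs


def _family_probs_biased(strengths: dict[int, float]) -> dict[str, np.ndarray]:
    """Within-family probabilities concentrated on the optimal codon."""
    probs = {}
    for aa, codons in ca.SYNONYMOUS_FAMILIES.items():
        s_weight = strengths[len(codons)]
        weights = np.array(
            [s_weight if c == OPTIMAL_CODONS[aa] else 1.0 for c in codons]
        )
        probs[aa] = weights / weights.sum()
    return probs


def _aa_distribution(family_probs: dict[str, np.ndarray], target_gc: float) -> np.ndarray:
    """Exponentially tilt a uniform amino-acid distribution to a target GC."""
    g = np.array(
        [
            sum(
                q * sum(b in "GC" for b in codon) / 3.0
                for q, codon in zip(family_probs[aa], ca.SYNONYMOUS_FAMILIES[aa])
            )
            for aa in AMINO_ACIDS
        ]
    )
    lo, hi = g.min(), g.max()
    if not (lo < target_gc < hi):
        raise InputError(
            f"target gene GC {target_gc} outside achievable range ({lo:.3f}, {hi:.3f})"
        )

    def mean_gc(lam: float) -> float:
        w = np.exp(lam * (g - g.mean()))
        return float((w * g).sum() / w.sum()) - target_gc

    lam = brentq(mean_gc, -500, 500)
    w = np.exp(lam * (g - g.mean()))
    return w / w.sum()


class _GeneFactory:
    """Samples CDS sequences for each gene category."""

    def __init__(self, config: ScenarioConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.background = _family_probs_background(config.host_gc)
        self.strengths = equalized_bias_strengths(config.ribosomal_codon_bias_strength)
        self.biased = _family_probs_biased(self.strengths)
        self.aa_host = _aa_distribution(self.background, config.host_gc)
        self.aa_ribo = _aa_distribution(self.biased, config.host_gc)
        self.aa_bgc = _aa_distribution(self.biased, config.bgc_gc)
        self._codon_arrays = {
            aa: np.array(ca.SYNONYMOUS_FAMILIES[aa]) for aa in AMINO_ACIDS
        }

    def _sample_body(
        self, n_codons: int, aa_probs: np.ndarray, family_probs: dict[str, np.ndarray]
    ) -> str:
        aa_idx = self.rng.choice(len(AMINO_ACIDS), size=n_codons, p=aa_probs)
        codons = np.empty(n_codons, dtype="<U3")
        for i, aa in enumerate(AMINO_ACIDS):
            mask = aa_idx == i
            count = int(mask.sum())
            if count:
                fam = self._codon_arrays[aa]
                picks = self.rng.choice(len(fam), size=count, p=family_probs[aa])
                codons[mask] = fam[picks]
        return "".join(codons)

    def _jittered_biased(self) -> dict[str, np.ndarray]:
        sd = self.config.cai_bias_jitter_sd
        if sd <= 0:
            return self.biased
        factor = float(np.exp(self.rng.normal(0.0, sd)))
        strengths = equalized_bias_strengths(
            max(1.0, self.config.ribosomal_codon_bias_strength * factor)
        )
        return _family_probs_biased(strengths)

    def make_cds(self, category: str) -> str:
        lo, hi = self.config.gene_length_range
        n_codons = int(self.rng.integers(lo, hi + 1))
        if category in ("ribosomal", "bgc"):
            aa_probs = self.aa_ribo if category == "ribosomal" else self.aa_bgc
            body = self._sample_body(n_codons, aa_probs, self._jittered_biased())
        else:
            body = self._sample_body(n_codons, self.aa_host, self.background)
        stop = str(self.rng.choice(["TAA", "TAG", "TGA"]))
        return "ATG" + body + stop


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    if length <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return "".join(np.array(list(BASES))[idx])


# ---------------------------------------------------------------------------
# contig construction
# ---------------------------------------------------------------------------


def _layout_contig(
    contig_id: str,
    cds_list: list[tuple[str, str, str]],  # (gene_id, category, cds)
    target_length: int,
    gc: float,
    rng: np.random.Generator,
) -> tuple[Contig, list[GeneRecord]]:
    """Embed CDS sequences into random spacer DNA up to a target length."""
    gene_bp = sum(len(cds) for _, _, cds in cds_list)
    n_gaps = len(cds_list) + 1
    remaining = max(target_length - gene_bp, n_gaps * 20)
    gap_sizes = rng.multinomial(remaining - n_gaps * 20, [1.0 / n_gaps] * n_gaps) + 20
    pieces: list[str] = []
    genes: list[GeneRecord] = []
    cursor = 0
    for i, (gene_id, category, cds) in enumerate(cds_list):
        spacer = _random_dna(rng, int(gap_sizes[i]), gc)
        pieces.append(spacer)
        cursor += len(spacer)
        strand = "+" if rng.random() < 0.7 else "-"
        placed = cds if strand == "+" else revcomp(cds)
        start = cursor + 1
        end = cursor + len(cds)
        pieces.append(placed)
        cursor = end
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
                category=category,
                cds_seq=cds,
            )
        )
    pieces.append(_random_dna(rng, int(gap_sizes[-1]), gc))
    return Contig(id=contig_id, seq="".join(pieces)), genes


# ---------------------------------------------------------------------------
# read simulation and projection
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    """Maps an expanded-genome interval onto the collapsed reference.

    ``ref_contig`` is None for inserted (reference-free) sequence.
    All coordinates 0-based half-open internally.
    """

    exp_start: int
    length: int
    ref_contig: str | None
    ref_start: int


@dataclass
class _Chromosome:
    id: str
    seq: str
    blocks: list[_Block]


def simulate_read_pairs(
    genome: Sequence[tuple[str, str]],
    read_length: int,
    insert_mean: float,
    insert_sd: float,
    depth: float,
    rng: np.random.Generator,
    error_rate: float = 0.0,
) -> list[tuple[str, int, int]]:
    """Draw fragments uniformly from a genome at a configured mean depth.

    Returns ``(chrom_id, left_start0, fragment_length)`` triples; the pair
    count is chosen so total sequenced bases / genome length matches
    ``depth``. Chromosomes shorter than the mean insert are skipped with a
    warning.
    """
    if insert_mean <= read_length:
        raise InputError("insert_mean must exceed read_length")
    eligible = [(cid, seq) for cid, seq in genome if len(seq) >= insert_mean]
    for cid, seq in genome:
        if len(seq) < insert_mean:
            logger.warning("chromosome %s shorter than insert size; skipped", cid)
    total = sum(len(seq) for _, seq in eligible)
    if total == 0:
        logger.warning("no eligible chromosomes; empty read set")
        return []
    n_pairs = int(round(depth * total / (2 * read_length)))
    lengths = np.array([len(seq) for _, seq in eligible], dtype=float)
    chrom_idx = rng.choice(len(eligible), size=n_pairs, p=lengths / lengths.sum())
    frag_lens = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int)
    fragments: list[tuple[str, int, int]] = []
    for i in range(n_pairs):
        cid, seq = eligible[chrom_idx[i]]
        flen = int(min(max(frag_lens[i], read_length), len(seq)))
        left = int(rng.integers(0, len(seq) - flen + 1))
        fragments.append((cid, left, flen))
    return fragments


def _project_read(
    chrom: _Chromosome, start: int, end: int
) -> tuple[str, int, list[tuple[str, int]]] | None:
    """Project an expanded-genome interval [start, end) onto the reference.

    Returns (ref_contig, 1-based pos, cigar) for the primary contig (the
    one receiving the most aligned bases); other-contig and inserted
    portions become soft clips, internal inserted portions become I ops.
    Returns None when no base aligns to any reference contig.
    """
    starts = [b.exp_start for b in chrom.blocks]
    i = bisect_right(starts, start) - 1
    pieces: list[tuple[str | None, int, int]] = []  # (ref_contig, ref_start, length)
    pos = start
    while pos < end and i < len(chrom.blocks):
        block = chrom.blocks[i]
        block_end = block.exp_start + block.length
        take = min(end, block_end) - pos
        if take > 0:
            offset = pos - block.exp_start
            pieces.append(
                (
                    block.ref_contig,
                    block.ref_start + offset if block.ref_contig else 0,
                    take,
                )
            )
            pos += take
        i += 1
    aligned: dict[str, int] = {}
    for ref, _, ln in pieces:
        if ref is not None:
            aligned[ref] = aligned.get(ref, 0) + ln
    if not aligned:
        return None
    primary = max(aligned, key=lambda r: (aligned[r], r))
    first = next(k for k, p in enumerate(pieces) if p[0] == primary)
    last = max(k for k, p in enumerate(pieces) if p[0] == primary)
    cigar: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    push("S", sum(p[2] for p in pieces[:first]))
    for ref, _, ln in pieces[first : last + 1]:
        push("M" if ref == primary else "I", ln)
    push("S", sum(p[2] for p in pieces[last + 1 :]))
    ref_pos = pieces[first][1] + 1  # 1-based
    return primary, ref_pos, cigar


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for h in hits:
        choices = [b for b in BASES if b != arr[h]]
        arr[h] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------


def _split_counts(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def build_scenario(
    config: ScenarioConfig, outdir: str | os.PathLike | None = None
) -> ScenarioBundle:
    """Generate a full scenario; write its files when ``outdir`` is given.

    Deterministic given ``config.seed``. The collapsed assembly contains
    the host contigs plus a single-copy BGC contig; the repeat-expanded
    genome (three flanked BGC copies by default) exists only as the read
    source.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    factory = _GeneFactory(config, rng)
    n_genes = {**DEFAULT_N_GENES, **config.n_genes}
    copies = config.bgc_copy_number
    leading_copies = min(config.leading_segment_copies, copies)

    # --- genes -------------------------------------------------------------
    host_cds: list[tuple[str, str, str]] = []
    pseudo_full_codons: dict[str, int] = {}
    for category in ("annotated", "hypothetical", "ribosomal", "pseudogene"):
        for i in range(n_genes.get(category, 0)):
            gene_id = f"{category[:4]}_{i:04d}"
            cds = factory.make_cds("annotated" if category == "pseudogene" else category)
            if category == "pseudogene":
                full_codons = len(cds) // 3
                keep = max(30, int(len(cds) * config.pseudogene_truncation_fraction))
                cds = cds[:keep]
                pseudo_full_codons[gene_id] = full_codons
            host_cds.append((gene_id, category, cds))
    order = rng.permutation(len(host_cds))
    host_cds = [host_cds[int(i)] for i in order]

    bgc_cds = [
        (f"bgc_{i:04d}", "bgc", factory.make_cds("bgc"))
        for i in range(n_genes.get("bgc", 0))
    ]

    # --- host contigs ------------------------------------------------------
    host_targets = _split_counts(config.host_length, config.n_host_contigs)
    per_contig = _split_counts(len(host_cds), config.n_host_contigs)
    host_contigs: list[Contig] = []
    genes: list[GeneRecord] = []
    taken = 0
    for idx in range(config.n_host_contigs):
        chunk = host_cds[taken : taken + per_contig[idx]]
        taken += per_contig[idx]
        contig, placed = _layout_contig(
            f"host_{idx:03d}", chunk, host_targets[idx], config.host_gc, rng
        )
        host_contigs.append(contig)
        genes.extend(placed)

    # --- BGC contig --------------------------------------------------------
    bgc_contig, bgc_genes = _layout_contig(
        "bgc", bgc_cds, config.bgc_length, config.bgc_gc, rng
    )
    if bgc_contig.length < config.bgc_length:
        pad = _random_dna(rng, config.bgc_length - bgc_contig.length, config.bgc_gc)
        bgc_contig = Contig(id="bgc", seq=bgc_contig.seq + pad)
    genes.extend(bgc_genes)
    bgc_len = bgc_contig.length
    leading_len = config.leading_segment_length
    if leading_len >= bgc_len:
        raise InputError("leading_segment_length must be shorter than the BGC")

    # --- variants ----------------------------------------------------------
    variants = _make_variants(config, rng, bgc_contig, bgc_genes, leading_len, copies)

    # --- expanded genome ---------------------------------------------------
    flank_u = [c.id for c in host_contigs[:copies]]
    flank_d = [c.id for c in host_contigs[copies : 2 * copies]]
    host_by_id = {c.id: c for c in host_contigs}
    chromosomes: list[_Chromosome] = []
    for contig in host_contigs[2 * copies :]:
        chromosomes.append(
            _Chromosome(
                id=contig.id,
                seq=contig.seq,
                blocks=[_Block(0, contig.length, contig.id, 0)],
            )
        )
    for copy_no in range(1, copies + 1):
        has_leading = copy_no <= leading_copies
        copy_seq, copy_blocks = _copy_sequence(
            bgc_contig.seq, variants, copy_no, 0 if has_leading else leading_len
        )
        u_seq = host_by_id[flank_u[copy_no - 1]].seq
        d_seq = host_by_id[flank_d[copy_no - 1]].seq
        blocks = [_Block(0, len(u_seq), flank_u[copy_no - 1], 0)]
        off = len(u_seq)
        for b in copy_blocks:
            blocks.append(_Block(off + b.exp_start, b.length, b.ref_contig, b.ref_start))
        off += len(copy_seq)
        blocks.append(_Block(off, len(d_seq), flank_d[copy_no - 1], 0))
        chromosomes.append(
            _Chromosome(
                id=f"repeat_context_{copy_no}",
                seq=u_seq + copy_seq + d_seq,
                blocks=blocks,
            )
        )

    # --- reads -------------------------------------------------------------
    fragments = simulate_read_pairs(
        [(c.id, c.seq) for c in chromosomes],
        config.read_length,
        config.insert_mean,
        config.insert_sd,
        config.depth,
        rng,
    )
    chrom_by_id = {c.id: c for c in chromosomes}
    alignments: list[AlignedRead] = []
    fastq1: list[tuple[str, str]] = []
    fastq2: list[tuple[str, str]] = []
    rl = config.read_length
    for i, (cid, left, flen) in enumerate(fragments):
        chrom = chrom_by_id[cid]
        read_id = f"frag{i:07d}"
        r1_fwd = chrom.seq[left : left + rl]
        r2_fwd = chrom.seq[left + flen - rl : left + flen]
        if config.error_rate > 0:
            r1_fwd = _apply_errors(r1_fwd, rng, config.error_rate)
            r2_fwd = _apply_errors(r2_fwd, rng, config.error_rate)
        p1 = _project_read(chrom, left, left + rl)
        p2 = _project_read(chrom, left + flen - rl, left + flen)
        if p1 is None or p2 is None:
            continue
        mate_reads = []
        for mate_no, (proj, seq_fwd, is_rev) in enumerate(
            [(p1, r1_fwd, False), (p2, r2_fwd, True)]
        ):
            ref, pos, cigar = proj
            mate_reads.append(
                AlignedRead(
                    read_id=read_id,
                    contig_id=ref,
                    pos=pos,
                    cigar=cigar,
                    seq=seq_fwd,
                    is_reverse=is_rev,
                    is_read1=mate_no == 0,
                )
            )
        mate_reads[0].mate_contig = mate_reads[1].contig_id
        mate_reads[0].mate_pos = mate_reads[1].pos
        mate_reads[1].mate_contig = mate_reads[0].contig_id
        mate_reads[1].mate_pos = mate_reads[0].pos
        alignments.extend(mate_reads)
        fastq1.append((read_id, r1_fwd))
        fastq2.append((read_id, revcomp(r2_fwd)))

    # --- assembly graph ----------------------------------------------------
    collapsed = host_contigs + [bgc_contig]
    graph = AssemblyGraph(nodes={c.id for c in collapsed})
    gfa_edges: list[tuple[str, str, str, str]] = []
    for copy_no in range(1, copies + 1):
        if copy_no <= leading_copies:
            gfa_edges.append((flank_u[copy_no - 1], "3p", "bgc", "5p"))
        gfa_edges.append(("bgc", "3p", flank_d[copy_no - 1], "5p"))
    for a, a_end, b, b_end in gfa_edges:
        graph.add_edge(a, a_end, b, b_end)

    # --- truth and homologs -------------------------------------------------
    truth = ScenarioTruth(
        config=config,
        segment_copy_numbers={"leading": leading_copies, "body": copies},
        variants=variants,
        gene_categories={g.gene_id: g.category for g in genes},
        pseudogenes={g.gene_id for g in genes if g.category == "pseudogene"},
        bgc_contig_id="bgc",
        host_contig_ids=[c.id for c in host_contigs],
        flanks_5p=flank_u[:leading_copies],
        flanks_internal=flank_u[leading_copies:],
        flanks_3p=list(flank_d),
    )
    homolog_table = make_homolog_table(genes, truth, rng, pseudo_full_codons)

    bundle = ScenarioBundle(
        config=config,
        truth=truth,
        contigs=collapsed,
        genes=genes,
        alignments=alignments,
        graph=graph,
        homolog_table=homolog_table,
    )
    if outdir is not None:
        bundle.paths = _write_bundle(bundle, outdir, fastq1, fastq2)
    return bundle


def _make_variants(
    config: ScenarioConfig,
    rng: np.random.Generator,
    bgc_contig: Contig,
    bgc_genes: list[GeneRecord],
    leading_len: int,
    copies: int,
) -> list[TrueVariant]:
    if copies < 2:
        return []
    seq = bgc_contig.seq
    specs_given = config.insertion_specs is not None or config.snp_specs is not None
    variants: list[TrueVariant] = []
    carrier_cycle = [2 + (i % (copies - 1)) for i in range(64)]

    def in_cds(pos: int) -> GeneRecord | None:
        for g in bgc_genes:
            if g.start <= pos <= g.end:
                return g
        return None

    if specs_given:
        k = 0
        for pos, ins_seq in config.insertion_specs or []:
            if not (1 <= pos <= bgc_contig.length):
                raise InputError(f"insertion position {pos} outside BGC")
            gene = in_cds(pos)
            cls = (
                ("in_frame" if len(ins_seq) % 3 == 0 else "frameshift")
                if gene
                else "intergenic"
            )
            variants.append(
                TrueVariant(pos, "insertion", ".", ins_seq.upper(),
                            [carrier_cycle[k]], cls)
            )
            k += 1
        for pos, ref, alt in config.snp_specs or []:
            if not (1 <= pos <= bgc_contig.length):
                raise InputError(f"SNP position {pos} outside BGC")
            if seq[pos - 1] != ref.upper():
                raise InputError(f"SNP ref {ref} disagrees with BGC at {pos}")
            gene = in_cds(pos)
            if gene is None:
                cls = "noncoding"
            else:
                cls = ca.classify_snp(
                    gene.cds_seq,
                    ca.cds_position(gene, pos),
                    ca.strand_base(gene, ref),
                    ca.strand_base(gene, alt),
                )
            variants.append(
                TrueVariant(pos, "SNP", ref.upper(), alt.upper(),
                            [carrier_cycle[k]], cls)
            )
            k += 1
        return variants

    # defaults: three in-frame insertions in distinct '+' body genes, one
    # synonymous SNP, one noncoding SNP — all in the body segment
    plus_body = [
        g for g in bgc_genes
        if g.strand == "+" and g.start > leading_len + 100 and g.span >= 150
    ]
    if len(plus_body) < 5:
        return []
    picks = [plus_body[int(i)] for i in
             rng.choice(len(plus_body), size=5, replace=False)]
    k = 0
    for gene, ins_len in zip(picks[:3], DEFAULT_INSERTION_LENGTHS):
        pos = gene.start + 3 * ((gene.span // 2) // 3)  # inside the CDS
        ins_seq = _random_dna(rng, ins_len, config.bgc_gc)
        variants.append(
            TrueVariant(pos, "insertion", ".", ins_seq, [carrier_cycle[k]], "in_frame")
        )
        k += 1
    # synonymous SNP: third base C -> T is synonymous for every family
    syn_gene = picks[3]
    syn_pos = None
    for codon_i in range(10, (syn_gene.span // 3) - 2):
        base_pos = syn_gene.start + codon_i * 3 + 2
        if seq[base_pos - 1] == "C":
            syn_pos = base_pos
            break
    if syn_pos is not None:
        variants.append(
            TrueVariant(syn_pos, "SNP", "C", "T", [carrier_cycle[k]], "synonymous")
        )
        k += 1
    # noncoding SNP in a body spacer
    gene_spans = [(g.start, g.end) for g in bgc_genes]
    for pos in range(leading_len + 50, bgc_contig.length - 50):
        if seq[pos - 1] == "A" and not any(s <= pos <= e for s, e in gene_spans):
            if all(abs(pos - v.position) > 200 for v in variants):
                variants.append(
                    TrueVariant(pos, "SNP", "A", "G", [carrier_cycle[k]], "noncoding")
                )
                break
    return variants


def _copy_sequence(
    collapsed: str, variants: list[TrueVariant], copy_no: int, start_offset: int
) -> tuple[str, list[_Block]]:
    """Materialize one repeat copy and its projection blocks.

    ``start_offset`` > 0 drops the leading segment (copy lacks it).
    Internal coordinates 0-based half-open.
    """
    seq = list(collapsed[start_offset:])
    base0 = start_offset
    for v in variants:
        if v.vtype == "SNP" and copy_no in v.carrier_copies and v.position > base0:
            seq[v.position - 1 - base0] = v.alt
    mutated = "".join(seq)
    insertions = sorted(
        (v for v in variants
         if v.vtype == "insertion" and copy_no in v.carrier_copies
         and v.position > base0),
        key=lambda v: v.position,
    )
    pieces: list[str] = []
    blocks: list[_Block] = []
    cursor_ref = base0  # absolute 0-based position on collapsed contig
    exp_off = 0
    for v in insertions:
        ref_take = v.position - cursor_ref  # copy collapsed[cursor_ref:v.position]
        if ref_take > 0:
            pieces.append(mutated[cursor_ref - base0 : v.position - base0])
            blocks.append(_Block(exp_off, ref_take, "bgc", cursor_ref))
            exp_off += ref_take
            cursor_ref = v.position
        pieces.append(v.alt)
        blocks.append(_Block(exp_off, len(v.alt), None, 0))
        exp_off += len(v.alt)
    tail = len(collapsed) - cursor_ref
    if tail > 0:
        pieces.append(mutated[cursor_ref - base0 :])
        blocks.append(_Block(exp_off, tail, "bgc", cursor_ref))
    return "".join(pieces), blocks


def make_homolog_table(
    genes: Sequence[GeneRecord],
    truth: ScenarioTruth,
    rng: np.random.Generator | None = None,
    pseudo_full_codons: dict[str, int] | None = None,
) -> list[tuple[str, int, int | None]]:
    """Fabricate a closest-homolog length table consistent with truth.

    Pseudogenes receive a homolog of length own / truncation_fraction
    (ratio < 0.8 by construction); other genes a homolog within +/-10% of
    their own length (ratio strictly inside (0.9, 1.12), never < 0.8).
    """
    rng = rng or np.random.default_rng(truth.config.seed + 7)
    frac = truth.config.pseudogene_truncation_fraction
    rows: list[tuple[str, int, int | None]] = []
    for gene in genes:
        own = len(gene.cds_seq) // 3
        if gene.gene_id in truth.pseudogenes:
            if pseudo_full_codons and gene.gene_id in pseudo_full_codons:
                hom = pseudo_full_codons[gene.gene_id]
            else:
                hom = int(round(own / frac))
        else:
            hom = max(1, int(round(own * (1 + rng.uniform(-0.1, 0.1)))))
        rows.append((gene.gene_id, own, hom))
    return rows


def _write_bundle(
    bundle: ScenarioBundle,
    outdir: str | os.PathLike,
    fastq1: list[tuple[str, str]],
    fastq2: list[tuple[str, str]],
) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "assembly": os.path.join(outdir, "assembly.fasta"),
        "gff": os.path.join(outdir, "genes.gff"),
        "categories": os.path.join(outdir, "categories.tsv"),
        "sam": os.path.join(outdir, "reads.sam"),
        "fastq1": os.path.join(outdir, "reads_1.fastq"),
        "fastq2": os.path.join(outdir, "reads_2.fastq"),
        "gfa": os.path.join(outdir, "graph.gfa"),
        "homologs": os.path.join(outdir, "homologs.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(paths["assembly"], bundle.contigs)
    write_gff_genes(paths["gff"], bundle.genes)
    write_category_table(paths["categories"], bundle.genes)
    write_sam(paths["sam"], bundle.contigs, bundle.alignments)
    for key, records in (("fastq1", fastq1), ("fastq2", fastq2)):
        with open(paths[key], "w") as fh:
            for read_id, seq in records:
                suffix = "/1" if key == "fastq1" else "/2"
                fh.write(f"@{read_id}{suffix}\n{seq}\n+\n{'I' * len(seq)}\n")
    edges = []
    for edge in sorted(bundle.graph.edges, key=lambda e: sorted(e)):
        pair = sorted(edge)
        (a, a_end), (b, b_end) = pair if len(pair) == 2 else (pair[0], pair[0])
        # write in from-3p/to-5p orientation where possible
        if a_end == "3p":
            edges.append((a, a_end, b, b_end))
        else:
            edges.append((b, b_end, a, a_end))
    write_gfa(paths["gfa"], bundle.contigs, edges)
    write_homolog_table(paths["homologs"], bundle.homolog_table)
    truth = bundle.truth
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "segment_copy_numbers": truth.segment_copy_numbers,
                "variants": [
                    {
                        "position": v.position,
                        "type": v.vtype,
                        "ref": v.ref,
                        "alt": v.alt,
                        "carrier_copies": v.carrier_copies,
                        "expected_class": v.expected_class,
                    }
                    for v in truth.variants
                ],
                "pseudogenes": sorted(truth.pseudogenes),
                "bgc_contig_id": truth.bgc_contig_id,
                "flanks_5p": truth.flanks_5p,
                "flanks_internal": truth.flanks_internal,
                "flanks_3p": truth.flanks_3p,
            },
            fh,
            indent=1,
        )
    return paths


def simulate_gene_sets(
    config: ScenarioConfig, seed: int | None = None
) -> list[GeneRecord]:
    """Fast path: generate only the categorized gene set (no contigs/reads).

    Used for statistical studies of GC / CAI category contrasts where the
    read layer is irrelevant.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    factory = _GeneFactory(config, rng)
    n_genes = {**DEFAULT_N_GENES, **config.n_genes}
    genes: list[GeneRecord] = []
    for category in ("annotated", "hypothetical", "ribosomal", "pseudogene", "bgc"):
        for i in range(n_genes.get(category, 0)):
            cds = factory.make_cds("annotated" if category == "pseudogene" else category)
            if category == "pseudogene":
                keep = max(30, int(len(cds) * config.pseudogene_truncation_fraction))
                cds = cds[:keep]
            genes.append(
                GeneRecord(
                    gene_id=f"{category[:4]}_{i:04d}",
                    contig_id="unplaced",
                    start=1,
                    end=len(cds),
                    strand="+",
                    category=category,
                    cds_seq=cds,
                )
            )
    return genes
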