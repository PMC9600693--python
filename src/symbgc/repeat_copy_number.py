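"""Copy-number inference, junction counting and pileup variant detection
on a collapsed repeat.

The collapsed repeat is a multi-copy region assembled as one contig: its
read depth scales with copy number, distinct flanking contexts show up as
multiple junction partners at the contig ends, and divergence between
copies appears as mixed alleles in the pileup.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_io import (
    AlignedRead,
    AssemblyGraph,
    Contig,
    InputError,
    ReadPairAlignment,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1_000
DEFAULT_MIN_SUPPORT = 3

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------


@dataclass
class DepthSummary:
    region_id: str
    mean_depth: float
    window_means: list[float]
    ci95: tuple[float, float]


def depth_array(
    alignments: Sequence[AlignedRead], contig_id: str, length: int
) -> np.ndarray:
    """Per-base depth over a contig from M/=X/D CIGAR spans (0-based array)."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for read in alignments:
        if read.contig_id != contig_id:
            continue
        ref = read.pos - 1
        for op, n in read.cigar:
            if op in "M=X":
                lo = max(0, ref)
                hi = min(length, ref + n)
                if hi > lo:
                    diff[lo] += 1
                    diff[hi] -= 1
                ref += n
            elif op in "DN":
                ref += n
    return np.cumsum(diff[:-1])


def depth_summary(
    alignments: Sequence[AlignedRead],
    region: tuple[str, int, int],
    window: int = DEFAULT_WINDOW,
    n_bootstrap: int = 1_000,
    seed: int = 0,
) -> DepthSummary:
    """Mean depth over a region with a windowed bootstrap 95% CI.

    ``region`` is (contig_id, start, end), 1-based inclusive. Windows tile
    the region without overlap; the CI resamples whole windows.
    """
    if not alignments:
        raise InputError("empty alignment set")
    contig_id, start, end = region
    if not (1 <= start <= end):
        raise InputError(f"bad region {start}..{end}")
    depth = depth_array(alignments, contig_id, end)[start - 1 : end]
    if depth.sum() == 0:
        logger.warning("region %s:%d-%d has zero coverage", contig_id, start, end)
        return DepthSummary(f"{contig_id}:{start}-{end}", 0.0, [], (0.0, 0.0))
    n = depth.size
    n_windows = max(1, n // window)
    win_means = [
        float(depth[i * window : (i + 1) * window if i < n_windows - 1 else n].mean())
        for i in range(n_windows)
    ]
    rng = np.random.default_rng(seed)
    arr = np.array(win_means)
    if arr.size > 1:
        boots = rng.choice(arr, size=(n_bootstrap, arr.size), replace=True).mean(axis=1)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        ci = (arr[0], arr[0])
    return DepthSummary(
        region_id=f"{contig_id}:{start}-{end}",
        mean_depth=float(depth.mean()),
        window_means=win_means,
        ci95=ci,
    )


def host_reference_depth(
    alignments: Sequence[AlignedRead],
    host_contigs: Sequence[Contig],
    aggregate: str = "median",
) -> float:
    """Bin-level reference depth: median (default) of host contig means."""
    means = []
    for contig in host_contigs:
        depth = depth_array(alignments, contig.id, contig.length)
        means.append(float(depth.mean()))
    if not means:
        raise InputError("no host contigs")
    if aggregate == "median":
        return float(np.median(means))
    if aggregate == "mean":
        return float(np.mean(means))
    raise InputError(f"unknown aggregate {aggregate!r}")


def estimate_copy_number(bgc_depth: float, genome_depth: float) -> tuple[float, int]:
    """Depth ratio and its rounded integer copy number (minimum 1).

    Ties at x.5 round half away from zero.
    """
    if genome_depth <= 0:
        raise InputError("genome depth must be > 0")
    ratio = bgc_depth / genome_depth
    copies = max(1, int(math.floor(ratio + 0.5)))
    return ratio, copies


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------


@dataclass
class PartnerSupport:
    contig_id: str
    n_pairs: int
    graph_confirmed: bool = False


@dataclass
class JunctionEvidence:
    focus_end: tuple[str, str]  # (contig_id, '5p'|'3p')
    partners: list[PartnerSupport] = field(default_factory=list)


@dataclass
class InternalAttachment:
    partner: str
    n_pairs: int
    terminus: str  # nearest focus terminus
    median_offset: float  # bp from that terminus


@dataclass
class JunctionSummary:
    focus: str
    end5: JunctionEvidence
    end3: JunctionEvidence
    internal: list[InternalAttachment] = field(default_factory=list)


def count_junctions(
    pairs: Sequence[ReadPairAlignment],
    graph: AssemblyGraph | None,
    focus: str,
    contigs: Sequence[Contig],
    end_window: int | None = None,
    insert_mean: float | None = None,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> JunctionSummary:
    """Count cross-contig read-pair support at each end of a focus contig.

    A partner contig is counted at an end when >= ``min_support`` pairs
    have one mate within ``end_window`` of that focus terminus and the
    other mate within ``end_window`` of one of the partner's termini.
    Partners whose focus mates cluster farther than ``end_window`` from
    both termini are reported as internal attachments with their median
    offset. ``end_window`` defaults to 2x the mean insert size (600 bp
    when no insert size is given).
    """
    lengths = {c.id: c.length for c in contigs}
    if focus not in lengths:
        raise InputError(f"focus contig {focus!r} not in assembly")
    if end_window is None:
        end_window = int(2 * insert_mean) if insert_mean else 600
    flen = lengths[focus]

    end_hits: dict[str, dict[str, int]] = {"5p": {}, "3p": {}}
    internal_hits: dict[str, list[int]] = {}
    partner_end_votes: dict[tuple[str, str], dict[str, int]] = {}
    n_on_focus = 0
    for pair in pairs:
        mates = [pair.mate1, pair.mate2]
        on_focus = [m for m in mates if m[0] == focus]
        off_focus = [m for m in mates if m[0] != focus]
        if any(m[0] == focus for m in mates):
            n_on_focus += 1
        if len(on_focus) != 1 or len(off_focus) != 1:
            continue
        fc, fpos, falen, _ = on_focus[0]
        pc, ppos, palen, _ = off_focus[0]
        if pc not in lengths:
            continue
        plen = lengths[pc]
        p_d5 = ppos - 1
        p_d3 = plen - (ppos + palen - 1)
        if min(p_d5, p_d3) > end_window:
            continue  # partner mate not near a partner terminus
        partner_terminus = "5p" if p_d5 <= p_d3 else "3p"
        d5 = fpos - 1
        d3 = flen - (fpos + falen - 1)
        if d5 <= end_window and d5 <= d3:
            end_hits["5p"][pc] = end_hits["5p"].get(pc, 0) + 1
            partner_end_votes.setdefault(("5p", pc), {}).setdefault(partner_terminus, 0)
            partner_end_votes[("5p", pc)][partner_terminus] += 1
        elif d3 <= end_window:
            end_hits["3p"][pc] = end_hits["3p"].get(pc, 0) + 1
            partner_end_votes.setdefault(("3p", pc), {}).setdefault(partner_terminus, 0)
            partner_end_votes[("3p", pc)][partner_terminus] += 1
        else:
            # signed offset: positive -> measured from 5p, negative -> from 3p
            internal_hits.setdefault(pc, []).append(d5 if d5 <= d3 else -d3)

    if n_on_focus == 0:
        logger.warning("no alignments on focus contig %s", focus)

    def evidence(which: str) -> JunctionEvidence:
        partners = []
        for pc, count in sorted(end_hits[which].items()):
            if count < min_support:
                continue
            votes = partner_end_votes.get((which, pc), {})
            partner_terminus = max(votes, key=votes.get) if votes else "5p"
            confirmed = bool(
                graph is not None
                and graph.has_edge(focus, which, pc, partner_terminus)
            )
            partners.append(PartnerSupport(pc, count, confirmed))
        return JunctionEvidence(focus_end=(focus, which), partners=partners)

    internal = []
    for pc, offsets in sorted(internal_hits.items()):
        if len(offsets) < min_support:
            continue
        signed = np.array(offsets, dtype=float)
        from_5p = (signed >= 0).sum() >= (signed < 0).sum()
        selected = signed[signed >= 0] if from_5p else -signed[signed < 0]
        internal.append(
            InternalAttachment(
                partner=pc,
                n_pairs=len(offsets),
                terminus="5p" if from_5p else "3p",
                median_offset=float(np.median(selected)),
            )
        )
    return JunctionSummary(
        focus=focus, end5=evidence("5p"), end3=evidence("3p"), internal=internal
    )


# ---------------------------------------------------------------------------
# repeat model
# ---------------------------------------------------------------------------


@dataclass
class RepeatSegment:
    segment_id: str
    span: tuple[int, int]  # 1-based inclusive on the collapsed BGC
    depth_ratio: float
    copy_number: int


@dataclass
class RepeatModel:
    segments: list[RepeatSegment]
    junctions: JunctionSummary
    inconsistencies: list[str] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.inconsistencies


def split_segments(
    bgc_length: int,
    junctions: JunctionSummary,
    min_segment: int = DEFAULT_WINDOW,
) -> list[tuple[int, int]]:
    """Split the collapsed BGC at internal attachment points.

    Segments shorter than ``min_segment`` are merged into their neighbor
    with a warning. Returns 1-based inclusive spans covering the BGC.
    """
    breakpoints = set()
    for att in junctions.internal:
        bp = (
            int(round(att.median_offset))
            if att.terminus == "5p"
            else bgc_length - int(round(att.median_offset))
        )
        if 0 < bp < bgc_length:
            breakpoints.add(bp)
    cuts = sorted(breakpoints)
    spans: list[tuple[int, int]] = []
    prev = 0
    for cut in cuts + [bgc_length]:
        spans.append((prev + 1, cut))
        prev = cut
    merged: list[tuple[int, int]] = []
    for span in spans:
        if span[1] - span[0] + 1 < min_segment and merged:
            logger.warning("segment %s shorter than %d bp; merged", span, min_segment)
            merged[-1] = (merged[-1][0], span[1])
        else:
            merged.append(span)
    if merged and merged[0][1] - merged[0][0] + 1 < min_segment and len(merged) > 1:
        logger.warning("leading segment too short; merged into neighbor")
        first = merged.pop(0)
        merged[0] = (first[0], merged[0][1])
    return merged


def reconcile_repeat_model(
    segment_ratios: Sequence[tuple[str, tuple[int, int], float]],
    junctions: JunctionSummary,
) -> RepeatModel:
    """Round segment depth ratios to copies and check junction consistency.

    The copy number of the segment touching the 3' terminus must equal the
    number of 3' junction partners; the segment touching the 5' terminus
    must match the 5' partners. Mismatches are flagged, never silently
    fixed.
    """
    if not segment_ratios:
        raise InputError("no segments")
    segments = [
        RepeatSegment(seg_id, span, ratio, max(1, int(math.floor(ratio + 0.5))))
        for seg_id, span, ratio in segment_ratios
    ]
    segments.sort(key=lambda s: s.span[0])
    inconsistencies = []
    n5 = len(junctions.end5.partners)
    n3 = len(junctions.end3.partners)
    first, last = segments[0], segments[-1]
    if n5 and first.copy_number != n5:
        inconsistencies.append(
            f"5' segment copy number {first.copy_number} != {n5} 5' junction partners"
        )
    if n3 and last.copy_number != n3:
        inconsistencies.append(
            f"3' segment copy number {last.copy_number} != {n3} 3' junction partners"
        )
    return RepeatModel(
        segments=segments, junctions=junctions, inconsistencies=inconsistencies
    )


def infer_repeat_model(
    alignments: Sequence[AlignedRead],
    pairs: Sequence[ReadPairAlignment],
    bgc_contig: Contig,
    contigs: Sequence[Contig],
    graph: AssemblyGraph | None,
    host_depth: float,
    end_window: int | None = None,
    insert_mean: float | None = None,
    min_support: int = DEFAULT_MIN_SUPPORT,
    window: int = DEFAULT_WINDOW,
    seed: int = 0,
) -> RepeatModel:
    """End-to-end repeat model: junctions -> segments -> depth -> reconcile."""
    junctions = count_junctions(
        pairs, graph, bgc_contig.id, contigs,
        end_window=end_window, insert_mean=insert_mean, min_support=min_support,
    )
    spans = split_segments(bgc_contig.length, junctions, min_segment=window)
    depth = depth_array(alignments, bgc_contig.id, bgc_contig.length)
    ratios = []
    for i, (start, end) in enumerate(spans):
        mean = float(depth[start - 1 : end].mean())
        ratios.append((f"segment_{i + 1}", (start, end), mean / host_depth))
    return reconcile_repeat_model(ratios, junctions)


# ---------------------------------------------------------------------------
# pileup variants
# ---------------------------------------------------------------------------


@dataclass
class VariantCall:
    position: int  # 1-based on the collapsed BGC; insertions fall after it
    vtype: str  # "SNP" | "insertion"
    ref: str
    alt: str
    allelic_depth: tuple[int, int]  # (ref, alt) informative reads
    alt_fraction: float  # estimated fraction of copies carrying the alt
    est_copies: int
    classification: str | None = None


def _edit_distance_leq1(a: str, b: str) -> bool:
    if a == b:
        return True
    if abs(len(a) - len(b)) > 1:
        return False
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b)) <= 1
    if len(a) > len(b):
        a, b = b, a
    for i in range(len(b)):
        if b[:i] + b[i + 1 :] == a:
            return True
    return False


def pileup_variants(
    alignments: Sequence[AlignedRead],
    collapsed_bgc: Contig,
    copies: int,
    min_alt_depth: int = 4,
    min_alt_fraction: float = 0.1,
    mismatch_tolerant: bool = False,
) -> list[VariantCall]:
    """Detect repeat-divergence variants from a pileup on the collapsed BGC.

    SNPs come from per-column base counts; insertions from reads whose
    alignments carry an I operation at a shared position with an identical
    inserted sequence (``mismatch_tolerant`` merges clusters at edit
    distance <= 1, for reads with sequencing errors). The estimated number
    of copies carrying the alt allele is round(copies * alt fraction),
    clamped to [1, copies - 1].

    For insertions the raw read counts are geometry-biased: a read is
    alt-informative only when it spans the whole insertion (rl - L - 1
    eligible start positions) but ref-informative whenever it spans the
    1-bp junction (rl - 1 positions). The reported ``alt_fraction``
    rescales the alt count by (rl - 1)/(rl - L - 1) to undo this;
    ``allelic_depth`` stays raw.
    """
    if copies < 2:
        raise InputError("copies must be >= 2 (no divergence possible otherwise)")
    length = collapsed_bgc.length
    counts = np.zeros((length, 4), dtype=np.int64)
    span_diff = np.zeros(length + 1, dtype=np.int64)  # reads spanning p..p+1 in one M
    ins_clusters: dict[tuple[int, str], int] = {}

    pos_chunks: list[np.ndarray] = []
    base_chunks: list[np.ndarray] = []
    for read in alignments:
        if read.contig_id != collapsed_bgc.id:
            continue
        ref = read.pos - 1
        query = 0
        seq = read.seq
        for op, n in read.cigar:
            if op in "M=X":
                lo, hi = max(0, ref), min(length, ref + n)
                if hi > lo:
                    sub = seq[query + (lo - ref) : query + (hi - ref)]
                    codes = np.frombuffer(sub.encode("ascii"), dtype=np.uint8)
                    pos_chunks.append(np.arange(lo, hi))
                    base_chunks.append(codes)
                    if hi - lo >= 2:
                        span_diff[lo] += 1
                        span_diff[hi - 1] -= 1
                ref += n
                query += n
            elif op == "I":
                if 0 < ref <= length:
                    key = (ref, seq[query : query + n])
                    ins_clusters[key] = ins_clusters.get(key, 0) + 1
                query += n
            elif op == "S":
                query += n
            elif op in "DN":
                ref += n
    if pos_chunks:
        positions = np.concatenate(pos_chunks)
        raw = np.concatenate(base_chunks)
        code_map = np.full(256, -1, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            code_map[ord(b)] = i
        codes = code_map[raw]
        valid = codes >= 0
        np.add.at(counts, (positions[valid], codes[valid]), 1)
    spanning = np.cumsum(span_diff[:-1])

    calls: list[VariantCall] = []
    col_total = counts.sum(axis=1)
    ref_codes = np.full(length, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        idx = np.frombuffer(collapsed_bgc.seq.encode("ascii"), dtype=np.uint8) == ord(b)
        ref_codes[idx] = i
    for p in np.nonzero(col_total > 0)[0]:
        rc = ref_codes[p]
        if rc < 0:
            continue
        col = counts[p]
        alt_code = int(np.argmax([c if i != rc else -1 for i, c in enumerate(col)]))
        alt_n = int(col[alt_code])
        if alt_n < min_alt_depth:
            continue
        if alt_n / col_total[p] < min_alt_fraction:
            continue
        frac = alt_n / (col[rc] + alt_n)
        calls.append(
            VariantCall(
                position=int(p) + 1,
                vtype="SNP",
                ref="ACGT"[rc],
                alt="ACGT"[alt_code],
                allelic_depth=(int(col[rc]), alt_n),
                alt_fraction=frac,
                est_copies=int(np.clip(round(copies * frac), 1, copies - 1)),
            )
        )

    read_lengths = [
        len(r.seq) for r in alignments if r.contig_id == collapsed_bgc.id and r.seq
    ]
    typical_rl = int(np.median(read_lengths)) if read_lengths else 0

    merged: dict[tuple[int, str], int] = {}
    if mismatch_tolerant:
        for (pos, seq), n in sorted(
            ins_clusters.items(), key=lambda kv: -kv[1]
        ):
            placed = False
            for (mpos, mseq) in list(merged):
                if mpos == pos and _edit_distance_leq1(seq, mseq):
                    merged[(mpos, mseq)] += n
                    placed = True
                    break
            if not placed:
                merged[(pos, seq)] = n
    else:
        merged = dict(ins_clusters)
    for (ref0, ins_seq), alt_n in sorted(merged.items()):
        if alt_n < min_alt_depth:
            continue
        ref_n = int(spanning[ref0 - 1]) if ref0 >= 1 else 0
        eligible_alt = typical_rl - len(ins_seq) - 1
        if eligible_alt > 0:
            corrected_alt = alt_n * (typical_rl - 1) / eligible_alt
        else:  # insertion not spannable by single reads; no correction possible
            corrected_alt = float(alt_n)
        if corrected_alt + ref_n == 0:
            continue
        frac = min(1.0, corrected_alt / (corrected_alt + ref_n))
        if frac < min_alt_fraction:
            continue
        calls.append(
            VariantCall(
                position=ref0,  # insertion after this 1-based position
                vtype="insertion",
                ref=".",
                alt=ins_seq,
                allelic_depth=(ref_n, alt_n),
                alt_fraction=frac,
                est_copies=int(np.clip(round(copies * frac), 1, copies - 1)),
            )
        )
    calls.sort(key=lambda c: (c.position, c.vtype))
    return calls
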