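"""Genome-reduction metrics: pseudogene calling by homolog length ratio
and repeat-aware length-weighted coding density."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .sequence_io import InputError

PSEUDOGENE_RATIO_CUTOFF = 0.8


@dataclass
class PseudogeneCall:
    gene_id: str
    gene_aa_length: int
    homolog_aa_length: int | None
    ratio: float | None
    is_pseudogene: bool | None  # None when unclassified (no homolog)


def call_pseudogenes(
    homolog_table: Sequence[tuple[str, int, int | None]],
    cutoff: float = PSEUDOGENE_RATIO_CUTOFF,
) -> list[PseudogeneCall]:
    """Flag genes strictly shorter than ``cutoff`` of their closest homolog.

    Genes with no homolog are reported unclassified (``is_pseudogene`` is
    None) and excluded from downstream fractions. The inequality is
    strict: a ratio of exactly 0.8 is NOT a pseudogene.
    """
    calls: list[PseudogeneCall] = []
    for gene_id, own, homolog in homolog_table:
        if own <= 0:
            raise InputError(f"gene {gene_id}: nonpositive length {own}")
        if homolog is None:
            calls.append(PseudogeneCall(gene_id, own, None, None, None))
            continue
        if homolog <= 0:
            raise InputError(f"gene {gene_id}: nonpositive homolog length {homolog}")
        ratio = own / homolog
        calls.append(PseudogeneCall(gene_id, own, homolog, ratio, ratio < cutoff))
    return calls


def pseudogene_fraction(calls: Sequence[PseudogeneCall]) -> float:
    """Percent of classified ORFs flagged as pseudogenes."""
    classified = [c for c in calls if c.is_pseudogene is not None]
    if not classified:
        raise InputError("no classified genes")
    flagged = sum(1 for c in classified if c.is_pseudogene)
    return 100.0 * flagged / len(classified)


@dataclass
class RepliconDensity:
    replicon_id: str
    length_bp: int
    coding_bp: int
    copy_number: int
    density_percent: float


@dataclass
class CodingDensityReport:
    replicons: list[RepliconDensity]
    overall_percent: float
    overall_percent_excluding_pseudogenes: float
    details: dict = field(default_factory=dict)


def coding_density(
    replicons: Sequence[tuple[str, int, int, int] | tuple[str, int, int, int, int]],
) -> CodingDensityReport:
    """Length-weighted coding density with repeat segments at copy number.

    Each replicon is ``(id, length_bp, coding_bp, copy_number)`` with an
    optional fifth element giving the coding bp contributed by
    pseudogenes (subtracted from the numerator in the pseudogene-excluded
    variant). Overall density = 100 * sum(copy * coding) / sum(copy * length).
    """
    if not replicons:
        raise InputError("empty replicon list")
    rows: list[RepliconDensity] = []
    num = num_np = denom = 0
    for rep in replicons:
        rep_id, length, coding, copy = rep[:4]
        pseudo_coding = rep[4] if len(rep) > 4 else 0
        if length <= 0:
            raise InputError(f"replicon {rep_id}: nonpositive length")
        if coding > length:
            raise InputError(f"replicon {rep_id}: coding bp {coding} > length {length}")
        if pseudo_coding > coding:
            raise InputError(f"replicon {rep_id}: pseudogene coding bp > coding bp")
        if copy < 1:
            raise InputError(f"replicon {rep_id}: copy number must be >= 1")
        rows.append(
            RepliconDensity(rep_id, length, coding, copy, 100.0 * coding / length)
        )
        num += copy * coding
        num_np += copy * (coding - pseudo_coding)
        denom += copy * length
    return CodingDensityReport(
        replicons=rows,
        overall_percent=100.0 * num / denom,
        overall_percent_excluding_pseudogenes=100.0 * num_np / denom,
    )
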