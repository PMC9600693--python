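"""Codon adaptation index against a ribosomal reference set, plus
codon-level variant classification.

CAI follows the Sharp & Li construction: relative adaptiveness w of a codon
is its count in the reference set divided by the count of the most-used
synonymous codon, and a gene's CAI is the geometric mean of w over its
codons. Single-codon amino acids (ATG, TGG under table 11) and stop codons
are excluded from the geometric mean; codons unobserved in the reference
receive a pseudocount of 0.5 occurrences so no CAI is ever exactly zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from .sequence_io import GeneRecord, InputError

logger = logging.getLogger(__name__)

TRANSLATION_TABLE_ID = 11  # bacterial

_table = CodonTable.unambiguous_dna_by_id[TRANSLATION_TABLE_ID]
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

#: codon -> amino acid (sense codons only)
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)

#: amino acid -> sorted list of synonymous codons
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, []).append(_codon)

#: codons excluded from CAI products: stops plus single-codon families
SINGLE_CODON_FAMILY: frozenset[str] = frozenset(
    codons[0] for codons in SYNONYMOUS_FAMILIES.values() if len(codons) == 1
)
EXCLUDED_CODONS: frozenset[str] = STOP_CODONS | SINGLE_CODON_FAMILY


def translate_codon(codon: str) -> str:
    """Translate one codon with the bacterial table; stops give '*'."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise InputError(f"not an unambiguous codon: {codon!r}") from None


def iter_codons(cds_seq: str) -> list[str]:
    """Split a CDS into codons, dropping a trailing partial codon."""
    seq = cds_seq.upper()
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


@dataclass
class RelativeAdaptiveness:
    """Relative adaptiveness w per codon, built from a reference gene set."""

    w: dict[str, float]
    reference_gene_count: int

    def __getitem__(self, codon: str) -> float:
        return self.w[codon]


@dataclass
class CaiObservation:
    gene_id: str
    category: str
    cai: float


def build_reference(
    ribosomal_genes: Sequence[GeneRecord | str],
    pseudocount: float = 0.5,
) -> RelativeAdaptiveness:
    """Build relative adaptiveness from a highly expressed reference set.

    For each amino acid, w(codon) = count / max synonymous count; codons
    never observed get ``pseudocount / max count``. Families with no
    observed codon at all get a neutral w = 1 for every member.
    """
    if not ribosomal_genes:
        raise InputError("reference set is empty")
    counts: dict[str, int] = {}
    for gene in ribosomal_genes:
        seq = gene.cds_seq if isinstance(gene, GeneRecord) else gene
        if len(seq) % 3 != 0:
            raise InputError("reference gene length not divisible by 3")
        for codon in iter_codons(seq):
            if codon in CODON_TO_AA:  # skips stops and ambiguous codons
                counts[codon] = counts.get(codon, 0) + 1
    if not counts:
        raise InputError("reference set contains no countable codons")
    w: dict[str, float] = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        max_count = max(counts.get(c, 0) for c in codons)
        if max_count == 0:
            for c in codons:
                w[c] = 1.0
            continue
        for c in codons:
            n = counts.get(c, 0)
            w[c] = n / max_count if n > 0 else pseudocount / max_count
    n_genes = len(ribosomal_genes)
    return RelativeAdaptiveness(w=w, reference_gene_count=n_genes)


def cai(gene: GeneRecord | str, ref: RelativeAdaptiveness) -> float:
    """Codon adaptation index of a gene: exp(mean ln w) over countable codons.

    A trailing partial codon (broken-frame pseudogenes) is dropped with a
    warning; ATG, TGG and stop codons do not enter the geometric mean.
    """
    seq = gene.cds_seq if isinstance(gene, GeneRecord) else gene
    if len(seq) % 3 != 0:
        logger.warning("CDS length %d not divisible by 3; truncating", len(seq))
    log_sum = 0.0
    n = 0
    for codon in iter_codons(seq):
        if codon in EXCLUDED_CODONS or codon not in CODON_TO_AA:
            continue
        log_sum += math.log(ref.w[codon])
        n += 1
    if n == 0:
        raise InputError("gene has no countable codons for CAI")
    return math.exp(log_sum / n)


def cai_observations(
    genes: Iterable[GeneRecord], ref: RelativeAdaptiveness
) -> list[CaiObservation]:
    return [CaiObservation(g.gene_id, g.category, cai(g, ref)) for g in genes]


def classify_snp(
    cds_seq: str, position_in_cds: int, ref_base: str, alt_base: str
) -> str:
    """Classify a single-base substitution relative to one CDS.

    ``position_in_cds`` is 1-based along the reading direction of the CDS;
    positions outside [1, len] are noncoding. Returns one of
    {"synonymous", "nonsynonymous", "nonsense", "noncoding"}.
    """
    seq = cds_seq.upper()
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if position_in_cds < 1 or position_in_cds > len(seq):
        return "noncoding"
    if seq[position_in_cds - 1] != ref_base:
        raise InputError(
            f"reference base mismatch at CDS position {position_in_cds}: "
            f"sequence has {seq[position_in_cds - 1]}, variant says {ref_base}"
        )
    codon_index = (position_in_cds - 1) // 3
    offset = (position_in_cds - 1) % 3
    ref_codon = seq[codon_index * 3 : codon_index * 3 + 3]
    if len(ref_codon) < 3:
        return "noncoding"  # dangling partial codon carries no amino acid
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    return "nonsynonymous"


def classify_insertion(
    length_bp: int, within_cds: bool, between_domains: bool = False
) -> str:
    """Classify an insertion as in_frame / frameshift / intergenic.

    ``between_domains`` is informational only (an in-frame insertion that
    falls between functional domains is not expected to disrupt function).
    """
    if length_bp < 1:
        raise InputError("insertion length must be >= 1")
    if not within_cds:
        return "intergenic"
    return "in_frame" if length_bp % 3 == 0 else "frameshift"


def locate_in_genes(
    contig_id: str, position: int, genes: Iterable[GeneRecord]
) -> GeneRecord | None:
    """Return the gene whose span contains ``position`` on ``contig_id``."""
    for gene in genes:
        if gene.contig_id == contig_id and gene.start <= position <= gene.end:
            return gene
    return None


def cds_position(gene: GeneRecord, contig_position: int) -> int:
    """Map a 1-based contig position to a 1-based position along the CDS."""
    if gene.strand == "+":
        return contig_position - gene.start + 1
    return gene.end - contig_position + 1


def strand_base(gene: GeneRecord, base: str) -> str:
    """Express a forward-strand base in the gene's reading direction."""
    if gene.strand == "+":
        return base.upper()
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[base.upper()]
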