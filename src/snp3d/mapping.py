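"""Mapping high-risk GWAS variants to regulatory elements in 1D and 3D.

1D mapping searches a resolution-sized window centered on the SNP in the
linear genome. 3D mapping walks the SNP's significant Hi-C contacts
(q <= 0.05), keeps partner fragments containing at least one regulatory
element, and selects a single fragment per SNP: the one with the lowest
contact q-value, ties broken toward the longest-range contact (an
inter-chromosomal contact counting as longer than any intra-chromosomal
one), and any remaining ties by (chrom, bin) order. Elements found in the
window / selected fragment are linked to their target genes and summarized
with median DA scores, or the disease-associated fraction for score-less
TFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .aggregate import fraction_da, median_da
from .genomic import (
    Bin,
    ElementIndex,
    Gene,
    RegulatoryElement,
    SNP,
    bin_index,
    window_around,
)

__all__ = [
    "CandidateFragment",
    "SNPMapping",
    "select_high_risk",
    "map_1d",
    "candidate_fragments",
    "select_fragment",
    "map_3d",
    "GWAS_P_MAX",
]

#: Genome-wide significance threshold for GWAS hits (inclusive).
GWAS_P_MAX = 5e-8


@dataclass(frozen=True)
class CandidateFragment:
    """A partner bin of a SNP's significant contact, with the contact's q-value.

    ``distance`` is bp between the SNP bin and the partner bin;
    ``None`` marks an inter-chromosomal contact.
    """

    bin: Bin
    qvalue: float
    distance: Optional[float]

    def sort_key(self):
        # lowest q first; then inter before intra; then longest range;
        # then (chrom, index) ascending — a total order
        inter_rank = 0 if self.distance is None else 1
        dist = -(self.distance if self.distance is not None else 0.0)
        return (self.qvalue, inter_rank, dist, self.bin.chrom, self.bin.index)


@dataclass
class SNPMapping:
    """Per-SNP result of 1D or 3D mapping."""

    snp: SNP
    mode: str  # "1D" | "3D"
    selected_fragments: tuple[CandidateFragment, ...] = field(default_factory=tuple)
    enhancers: tuple[RegulatoryElement, ...] = field(default_factory=tuple)
    tfbs: tuple[RegulatoryElement, ...] = field(default_factory=tuple)
    target_genes: tuple[Gene, ...] = field(default_factory=tuple)
    median_da_enhancer: Optional[float] = None
    median_da_tf: Optional[float] = None
    median_da_targets: Optional[float] = None
    tf_fraction: Optional[float] = None

    @property
    def is_empty(self) -> bool:
        return not (self.enhancers or self.tfbs)


def select_high_risk(snps: Sequence[SNP], p_max: float = GWAS_P_MAX) -> list[SNP]:
    """SNPs reaching genome-wide significance, p <= p_max (inclusive bound)."""
    return [s for s in snps if s.pvalue <= p_max]


def _resolve_targets(
    elements: Sequence[RegulatoryElement], genes: Mapping[str, Gene]
) -> tuple[Gene, ...]:
    """Union of the elements' target genes, de-duplicated by symbol.

    Target symbols absent from the gene score table are dropped: a gene
    without a DA score cannot enter the median.
    """
    seen: dict[str, Gene] = {}
    for el in elements:
        for sym in el.target_genes:
            if sym in genes and sym not in seen:
                seen[sym] = genes[sym]
    return tuple(seen[sym] for sym in sorted(seen))


def _aggregate(mapping: SNPMapping, genes: Mapping[str, Gene]) -> SNPMapping:
    """Fill the median/fraction summary fields of a mapping in place."""
    mapping.target_genes = _resolve_targets(mapping.enhancers + mapping.tfbs, genes)
    if mapping.enhancers:
        mapping.median_da_enhancer = median_da(mapping.enhancers)
    if mapping.tfbs:
        if all(el.da_score is not None for el in mapping.tfbs):
            mapping.median_da_tf = median_da(mapping.tfbs)
        else:
            mapping.tf_fraction = fraction_da(mapping.tfbs)
    if mapping.target_genes:
        mapping.median_da_targets = median_da(mapping.target_genes)
    return mapping


def map_1d(
    snp: SNP,
    elements: ElementIndex,
    resolution: int,
    genes: Mapping[str, Gene] | None = None,
) -> SNPMapping:
    """Map one SNP to elements within a resolution-sized linear window."""
    window = window_around(snp, resolution)
    hits = elements.query(window)
    mapping = SNPMapping(
        snp=snp,
        mode="1D",
        enhancers=tuple(el for el in hits if el.kind == "enhancer"),
        tfbs=tuple(el for el in hits if el.kind == "tfbs"),
    )
    return _aggregate(mapping, genes or {})


def candidate_fragments(
    snp: SNP,
    sig_contacts: pd.DataFrame,
    elements: ElementIndex,
    resolution: int,
    kind_filter: Optional[str] = None,
) -> list[CandidateFragment]:
    """Element-bearing partner fragments of the SNP's significant contacts.

    Either side of a contact pair may hold the SNP's bin; the other side is
    the candidate partner. Partners containing no element (of ``kind_filter``
    when given) are discarded. ``sig_contacts`` must already be filtered to
    the significant set.
    """
    b = bin_index(snp.pos, resolution)
    mid = b * resolution + resolution // 2
    out: list[CandidateFragment] = []
    side1 = (sig_contacts["chrom1"] == snp.chrom) & (sig_contacts["mid1"] == mid)
    side2 = (sig_contacts["chrom2"] == snp.chrom) & (sig_contacts["mid2"] == mid)
    for rows, pc, pm in ((side1, "chrom2", "mid2"), (side2, "chrom1", "mid1")):
        for _, row in sig_contacts.loc[rows].iterrows():
            partner = Bin(str(row[pc]), int(row[pm]) // resolution, resolution)
            if not elements.query_bin(partner, kind=kind_filter):
                continue
            if partner.chrom == snp.chrom:
                dist: Optional[float] = abs(partner.index - b) * float(resolution)
            else:
                dist = None
            out.append(CandidateFragment(partner, float(row["qvalue"]), dist))
    return out


def select_fragment(
    candidates: Sequence[CandidateFragment],
) -> Optional[CandidateFragment]:
    """The single fragment kept per SNP: argmin q, longest range on ties.

    Inter-chromosomal candidates outrank every intra-chromosomal one at equal
    q; exact remaining ties fall back on (chrom, bin index) ascending so the
    choice is deterministic. ``None`` when there are no candidates.
    """
    if not candidates:
        return None
    return min(candidates, key=CandidateFragment.sort_key)


def map_3d(
    snp: SNP,
    sig_contacts: pd.DataFrame,
    elements: ElementIndex,
    resolution: int,
    genes: Mapping[str, Gene] | None = None,
    selection_scope: str = "per_class",
) -> SNPMapping:
    """Map one SNP to elements through its most confident significant contact.

    ``selection_scope="per_class"`` selects one fragment independently for
    enhancers and for TF binding sites (each class's best element-bearing
    contact); ``"joint"`` selects a single fragment over all element-bearing
    candidates and takes whatever it contains.
    """
    if selection_scope not in ("per_class", "joint"):
        raise ValueError(f"unknown selection_scope: {selection_scope}")
    selected: list[CandidateFragment] = []
    enhancers: tuple[RegulatoryElement, ...] = ()
    tfbs: tuple[RegulatoryElement, ...] = ()

    if selection_scope == "per_class":
        for kind in ("enhancer", "tfbs"):
            cands = candidate_fragments(
                snp, sig_contacts, elements, resolution, kind_filter=kind
            )
            best = select_fragment(cands)
            if best is None:
                continue
            selected.append(best)
            hits = tuple(elements.query_bin(best.bin, kind=kind))
            if kind == "enhancer":
                enhancers = hits
            else:
                tfbs = hits
    else:
        cands = candidate_fragments(snp, sig_contacts, elements, resolution)
        best = select_fragment(cands)
        if best is not None:
            selected.append(best)
            hits = elements.query_bin(best.bin)
            enhancers = tuple(el for el in hits if el.kind == "enhancer")
            tfbs = tuple(el for el in hits if el.kind == "tfbs")

    mapping = SNPMapping(
        snp=snp,
        mode="3D",
        selected_fragments=tuple(selected),
        enhancers=enhancers,
        tfbs=tfbs,
    )
    return _aggregate(mapping, genes or {})
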