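"""Coordinate conventions, genomic intervals, binning, and the shared annotation model.

Internally all coordinates are 0-based, half-open ``[start, end)`` — the BED
convention. GWAS positions (1-based, as published) are converted at ingest.
Strand is ignored throughout: none of the mapping rules depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "SNP",
    "RegulatoryElement",
    "Gene",
    "Bin",
    "bin_index",
    "bin_midpoint",
    "overlaps",
    "window_around",
    "normalize_chrom",
    "ElementIndex",
]


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chr``-prefixed dialect.

    ``"1"`` and ``"chr1"`` compare equal after normalization, so mixed-dialect
    inputs (GWAS tables vs Hi-C dumps) interoperate.
    """
    name = str(name).strip()
    if not name:
        raise ValueError("chromosome name must be non-empty")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SNP:
    """A GWAS variant with its published 1-based position and association p-value."""

    id: str
    chrom: str
    pos: int  # 1-based, as published by GWAS
    pvalue: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: pos must be >= 1, got {self.pos}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(
                f"SNP {self.id}: pvalue must be in (0, 1], got {self.pvalue}"
            )

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1


@dataclass(frozen=True)
class RegulatoryElement:
    """An enhancer or TF binding site with a disease-association annotation.

    Either a numeric ``da_score`` or a boolean ``disease_associated`` flag must
    be present (the flag covers resources that publish no numeric score for
    TFs). ``target_genes`` carries the symbols of the genes the element
    regulates.
    """

    id: str
    kind: str  # "enhancer" | "tfbs"
    interval: GenomicInterval
    da_score: Optional[float] = None
    disease_associated: Optional[bool] = None
    tf_name: Optional[str] = None
    target_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in ("enhancer", "tfbs"):
            raise ValueError(f"element {self.id}: kind must be enhancer|tfbs")
        if self.da_score is None and self.disease_associated is None:
            raise ValueError(
                f"element {self.id}: needs da_score or disease_associated"
            )
        if self.da_score is not None and self.da_score < 0:
            raise ValueError(f"element {self.id}: da_score must be >= 0")
        if self.kind == "tfbs" and not self.tf_name:
            raise ValueError(f"element {self.id}: tfbs requires tf_name")


@dataclass(frozen=True)
class Gene:
    symbol: str
    da_score: float

    def __post_init__(self) -> None:
        if self.da_score < 0:
            raise ValueError(f"gene {self.symbol}: da_score must be >= 0")


@dataclass(frozen=True, order=True)
class Bin:
    """A fixed-resolution genomic bin; covers ``[index*resolution, (index+1)*resolution)``."""

    chrom: str
    index: int
    resolution: int

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.index * self.resolution, (self.index + 1) * self.resolution
        )


def bin_index(pos: int, resolution: int) -> int:
    """Map a 1-based genomic position into its 0-based bin ordinal.

    The first base of the chromosome lands in bin 0; base ``resolution`` is the
    last base of bin 0 and base ``resolution + 1`` the first of bin 1.
    """
    if pos < 1:
        raise ValueError(f"pos must be >= 1, got {pos}")
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0, got {resolution}")
    return (pos - 1) // resolution


def bin_midpoint(index: int, resolution: int) -> int:
    """Midpoint (bp) of a bin, as written in FitHiC-style contact files."""
    return index * resolution + resolution // 2


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test; intervals on different chromosomes never overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def window_around(snp: SNP, window: int) -> GenomicInterval:
    """A window of total width ``window`` bp centered on the SNP, clipped at 0.

    With ``window`` equal to the Hi-C resolution this is the linear-proximity
    search region of the 1D mapping: half the window upstream, half downstream.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    half = window // 2
    start = max(0, snp.pos0 - half)
    return GenomicInterval(snp.chrom, start, snp.pos0 + half)


class ElementIndex:
    """Interval index over regulatory elements for fast overlap queries.

    Also maintains a per-(chrom, bin) view so 3D mapping can ask "which
    elements does this Hi-C fragment contain" without rescanning.
    """

    def __init__(self, elements: Iterable[RegulatoryElement]):
        self.elements: list[RegulatoryElement] = list(elements)
        self._trees: dict[str, IntervalTree] = {}
        seen: set[str] = set()
        for el in self.elements:
            if el.id in seen:
                raise ValueError(f"duplicate element id: {el.id}")
            seen.add(el.id)
            tree = self._trees.setdefault(el.interval.chrom, IntervalTree())
            tree.addi(el.interval.start, el.interval.end, el)

    def __len__(self) -> int:
        return len(self.elements)

    def query(
        self, region: GenomicInterval, kind: Optional[str] = None
    ) -> list[RegulatoryElement]:
        """Elements overlapping ``region`` by >= 1 bp, sorted by (start, id)."""
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(region.start, region.end)]
        if kind is not None:
            hits = [el for el in hits if el.kind == kind]
        return sorted(hits, key=lambda el: (el.interval.start, el.id))

    def query_bin(self, b: Bin, kind: Optional[str] = None) -> list[RegulatoryElement]:
        return self.query(b.interval, kind=kind)
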