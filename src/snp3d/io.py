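"""Readers and writers for the pipeline's plain-text formats.

Formats (all tab-separated, gzip-transparent by ``.gz`` suffix):

* contacts — FitHiC-style ``chrom1 mid1 chrom2 mid2 count``, with
  ``distance expected_p pvalue qvalue`` appended on annotated output; header
  row on output, optional on input.
* GWAS — header ``snp_id chrom pos_1based pvalue``.
* elements — headerless BED-plus: ``chrom start end id kind da_score
  disease_associated tf_name target_genes`` with ``.`` for absent fields and
  comma-separated target gene symbols.
* genes — header ``symbol da_score``.

Chromosome names are normalized to the ``chr`` dialect at ingest; malformed
rows raise :class:`FormatError` carrying the file and line number.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .contacts import CONTACT_COLUMNS
from .genomic import ElementIndex, Gene, GenomicInterval, RegulatoryElement, SNP, normalize_chrom

__all__ = [
    "FormatError",
    "read_contacts",
    "write_contacts",
    "read_gwas",
    "write_gwas",
    "read_elements",
    "write_elements",
    "read_genes",
    "write_genes",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A malformed input row, located by file and 1-based line number."""

    def __init__(self, path: PathLike, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path, self.line = str(path), line


def _open_text(path: PathLike, mode: str = "rt"):
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode)
    return open(p, mode)


def read_contacts(path: PathLike) -> pd.DataFrame:
    """Read a FitHiC-style contact table; header row optional."""
    with _open_text(path) as fh:
        first = fh.readline()
    if not first:
        logger.warning("%s: empty contact file", path)
        return pd.DataFrame(columns=CONTACT_COLUMNS)
    has_header = "chrom1" in first.split()
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        comment="#",
        dtype=str,
    )
    if not has_header:
        if df.shape[1] < 5:
            raise FormatError(path, 1, f"expected >= 5 columns, found {df.shape[1]}")
        df = df.iloc[:, :5]
        df.columns = CONTACT_COLUMNS
    missing = [c for c in CONTACT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(path, 1, f"missing columns: {missing}")
    for col in ("mid1", "mid2", "count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + (2 if has_header else 1)
            raise FormatError(path, line, f"non-numeric value in column {col!r}")
        df[col] = vals.astype(int)
    if (df["count"] < 0).any():
        line = int((df["count"] < 0).idxmax()) + (2 if has_header else 1)
        raise FormatError(path, line, "negative contact count")
    df["chrom1"] = df["chrom1"].map(normalize_chrom)
    df["chrom2"] = df["chrom2"].map(normalize_chrom)
    for col in ("distance", "expected_p", "pvalue", "qvalue"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    logger.info("%s: read %d contact records", path, len(df))
    return df


def write_contacts(contacts: pd.DataFrame, path: PathLike) -> None:
    contacts.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gwas(path: PathLike) -> list[SNP]:
    """Read a GWAS summary table into validated SNPs."""
    snps: list[SNP] = []
    with _open_text(path) as fh:
        header = fh.readline().split()
        expected = ["snp_id", "chrom", "pos_1based", "pvalue"]
        if header[: len(expected)] != expected:
            raise FormatError(path, 1, f"expected header {expected}, found {header}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(path, lineno, f"expected 4 fields, found {len(fields)}")
            try:
                snp = SNP(
                    id=fields[0],
                    chrom=normalize_chrom(fields[1]),
                    pos=int(fields[2]),
                    pvalue=float(fields[3]),
                )
            except (ValueError, TypeError) as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            snps.append(snp)
    if not snps:
        logger.warning("%s: no SNP rows", path)
    logger.info("%s: read %d SNPs", path, len(snps))
    return snps


def write_gwas(snps: Iterable[SNP], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("snp_id\tchrom\tpos_1based\tpvalue\n")
        for s in snps:
            fh.write(f"{s.id}\t{s.chrom}\t{s.pos}\t{s.pvalue:.6g}\n")


def _dot(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def read_elements(path: PathLike, one_based: bool = False) -> ElementIndex:
    """Read a BED-plus element table into an interval index.

    ``one_based=True`` converts inclusive 1-based start coordinates (as some
    annotation exports use) to the internal 0-based half-open convention;
    BED-conventional input passes through unchanged.
    """
    elements: list[RegulatoryElement] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(path, lineno, f"expected 9 fields, found {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
                if one_based:
                    start -= 1
                da = None if f[5] == "." else float(f[5])
                flag = None if f[6] == "." else f[6].strip().lower() in ("1", "true", "yes")
                el = RegulatoryElement(
                    id=f[3],
                    kind=f[4],
                    interval=GenomicInterval(normalize_chrom(f[0]), start, end),
                    da_score=da,
                    disease_associated=flag,
                    tf_name=None if f[7] == "." else f[7],
                    target_genes=tuple(t for t in f[8].split(",") if t and t != "."),
                )
            except (ValueError, TypeError) as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            elements.append(el)
    try:
        index = ElementIndex(elements)
    except ValueError as exc:
        raise FormatError(path, 0, str(exc)) from exc
    if not elements:
        logger.warning("%s: no element rows", path)
    logger.info("%s: read %d elements", path, len(elements))
    return index


def write_elements(elements: Iterable[RegulatoryElement], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for el in elements:
            iv = el.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        el.id,
                        el.kind,
                        _dot(el.da_score),
                        _dot(el.disease_associated),
                        _dot(el.tf_name),
                        ",".join(el.target_genes) if el.target_genes else ".",
                    ]
                )
                + "\n"
            )


def read_genes(path: PathLike) -> dict[str, Gene]:
    genes: dict[str, Gene] = {}
    with _open_text(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["symbol", "da_score"]:
            raise FormatError(path, 1, f"expected header [symbol, da_score], found {header}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 2:
                raise FormatError(path, lineno, f"expected 2 fields, found {len(f)}")
            try:
                gene = Gene(f[0], float(f[1]))
            except (ValueError, TypeError) as exc:
                raise FormatError(path, lineno, str(exc)) from exc
            if gene.symbol in genes:
                raise FormatError(path, lineno, f"duplicate gene symbol {gene.symbol}")
            genes[gene.symbol] = gene
    if not genes:
        logger.warning("%s: no gene rows", path)
    return genes


def write_genes(genes: Iterable[Gene], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("symbol\tda_score\n")
        for g in sorted(genes, key=lambda g: g.symbol):
            fh.write(f"{g.symbol}\t{g.da_score:.6g}\n")
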