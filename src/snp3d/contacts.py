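"""Statistical confidence for binned Hi-C contacts.

A simplified Fit-Hi-C-style stage: each bin-pair count ``k`` is tested against
a distance-dependent null. Intra-chromosomal pairs are grouped into
equal-occupancy distance strata (inter-chromosomal pairs form one extra
stratum); within a stratum the per-read-pair contact probability is

    p_exp = (stratum total count) / (N * stratum pair count)

with ``N`` the total observed count over all analyzed pairs. The upper-tail
binomial probability P(X >= k), X ~ Binomial(N, p_exp), is the contact
p-value; Benjamini-Hochberg correction over the whole genome-wide family
(intra + inter jointly) yields q-values, and contacts with q <= q_max
(default 0.05, inclusive) are retained as significant.

No spline smoothing, bias model, or matrix normalization is applied: raw
counts in, one flat expectation per stratum. The analyzed universe is the set
of records present in the input table.

Contacts are carried as a pandas DataFrame in FitHiC-style layout
(``chrom1, mid1, chrom2, mid2, count``) with annotation columns appended;
:class:`ContactRecord` is the record-level view of one row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic import Bin

__all__ = [
    "ContactRecord",
    "DistanceStratum",
    "CONTACT_COLUMNS",
    "canonicalize",
    "build_strata",
    "expected_probability",
    "binomial_pvalue",
    "bh_qvalues",
    "annotate_contacts",
    "significant_contacts",
]

#: Core columns of the FitHiC-style contact table.
CONTACT_COLUMNS = ["chrom1", "mid1", "chrom2", "mid2", "count"]

#: Columns appended by :func:`annotate_contacts`.
ANNOTATION_COLUMNS = ["distance", "expected_p", "pvalue", "qvalue"]


@dataclass(frozen=True)
class ContactRecord:
    """One bin pair with its observed count and significance annotation.

    ``distance`` is the bp separation of the two bin midpoints for
    intra-chromosomal pairs and ``None`` for inter-chromosomal ones.
    """

    bin_a: Bin
    bin_b: Bin
    count: int
    distance: Optional[int] = None
    expected_p: Optional[float] = None
    pvalue: Optional[float] = None
    qvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if (self.bin_a.chrom, self.bin_a.index) > (self.bin_b.chrom, self.bin_b.index):
            raise ValueError("bins must be in canonical (chrom, index) order")


@dataclass(frozen=True)
class DistanceStratum:
    """One distance class of the expectation model.

    ``lower``/``upper`` bound the member distances in bp (inclusive);
    both are ``None`` for the inter-chromosomal stratum.
    """

    lower: Optional[float]
    upper: Optional[float]
    n_pairs: int
    total_count: int

    @property
    def is_inter(self) -> bool:
        return self.lower is None


def canonicalize(contacts: pd.DataFrame) -> pd.DataFrame:
    """Return the table with each pair stored in canonical order.

    Canonical order is lexicographic (chrom, midpoint): the smaller locus is
    side 1. Idempotent; never mutates its input.
    """
    df = contacts.copy()
    swap = (df["chrom1"] > df["chrom2"]) | (
        (df["chrom1"] == df["chrom2"]) & (df["mid1"] > df["mid2"])
    )
    if swap.any():
        for a, b in (("chrom1", "chrom2"), ("mid1", "mid2")):
            df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    return df


def _distances(df: pd.DataFrame) -> np.ndarray:
    """Midpoint separation in bp; NaN flags inter-chromosomal pairs."""
    d = np.abs(df["mid2"].to_numpy(float) - df["mid1"].to_numpy(float))
    d[df["chrom1"].to_numpy() != df["chrom2"].to_numpy()] = np.nan
    return d


def build_strata(
    contacts: pd.DataFrame, n_strata: int
) -> tuple[np.ndarray, list[DistanceStratum]]:
    """Partition contact records into equal-occupancy distance strata.

    Intra-chromosomal records are ordered by genomic distance and cut into
    ``n_strata`` contiguous groups of as-nearly-as-possible equal pair counts;
    a stratum boundary never splits records sharing one distance, so fewer
    distinct distances than requested strata simply collapse into fewer
    strata. All inter-chromosomal records form one extra stratum.

    Returns ``(labels, strata)`` where ``labels[i]`` indexes ``strata`` for
    row ``i`` of ``contacts``.
    """
    if len(contacts) == 0:
        raise ValueError("no contact records to stratify")
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")

    dist = _distances(contacts)
    counts = contacts["count"].to_numpy()
    labels = np.full(len(contacts), -1, dtype=int)
    strata: list[DistanceStratum] = []

    intra = ~np.isnan(dist)
    if intra.any():
        d_intra = dist[intra]
        uniq, inverse, per_dist = np.unique(
            d_intra, return_inverse=True, return_counts=True
        )
        # equal-occupancy cut on distance groups: assign each distinct
        # distance to the stratum its cumulative-midpoint quantile falls in
        cum = np.cumsum(per_dist)
        mid = cum - per_dist / 2.0
        grp = np.minimum(
            (mid / cum[-1] * n_strata).astype(int), n_strata - 1
        )
        # relabel to consecutive stratum ids
        _, grp = np.unique(grp, return_inverse=True)
        lab_intra = grp[inverse]
        idx_intra = np.flatnonzero(intra)
        labels[idx_intra] = lab_intra
        for s in range(grp.max() + 1):
            members = idx_intra[lab_intra == s]
            strata.append(
                DistanceStratum(
                    lower=float(dist[members].min()),
                    upper=float(dist[members].max()),
                    n_pairs=len(members),
                    total_count=int(counts[members].sum()),
                )
            )

    inter = np.isnan(dist)
    if inter.any():
        labels[inter] = len(strata)
        strata.append(
            DistanceStratum(
                lower=None,
                upper=None,
                n_pairs=int(inter.sum()),
                total_count=int(counts[inter].sum()),
            )
        )
    return labels, strata


def expected_probability(stratum: DistanceStratum, n_total: int) -> float:
    """Per-read-pair probability of landing on one member pair of the stratum."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if stratum.n_pairs <= 0:
        raise ValueError("stratum has no member pairs")
    return stratum.total_count / (n_total * stratum.n_pairs)


def binomial_pvalue(k: int, n: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= k) for X ~ Binomial(n, p)."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min over j >= i of p_(j) * m / j on the ascending-sorted list,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_contacts(
    contacts: pd.DataFrame,
    n_strata: int = 1000,
    min_distance: Optional[float] = None,
    resolution: Optional[int] = None,
) -> pd.DataFrame:
    """Attach distance, expected probability, p-value and q-value to contacts.

    Intra-chromosomal pairs closer than ``min_distance`` bp (default: one bin
    when ``resolution`` is given, so self-pairs drop out; else 1 bp) are
    excluded from the analyzed set. BH runs jointly over every remaining
    record, intra- and inter-chromosomal alike.
    """
    df = canonicalize(contacts)
    dist = _distances(df)
    if min_distance is None:
        min_distance = float(resolution) if resolution else 1.0
    keep = np.isnan(dist) | (dist >= min_distance)
    df = df.loc[keep].reset_index(drop=True)
    if len(df) == 0:
        return df.assign(
            distance=pd.Series(dtype=float),
            expected_p=pd.Series(dtype=float),
            pvalue=pd.Series(dtype=float),
            qvalue=pd.Series(dtype=float),
        )
    dist = dist[keep]

    labels, strata = build_strata(df, n_strata)
    n_total = int(df["count"].sum())
    if n_total <= 0:
        raise ValueError("contact table has zero total count")
    p_exp = np.array([expected_probability(s, n_total) for s in strata])[labels]

    k = df["count"].to_numpy(int)
    pvals = np.ones(len(df))
    nz = k > 0
    pvals[nz] = stats.binom.sf(k[nz] - 1, n_total, p_exp[nz])
    np.clip(pvals, 0.0, 1.0, out=pvals)

    df["distance"] = dist
    df["expected_p"] = p_exp
    df["pvalue"] = pvals
    df["qvalue"] = bh_qvalues(pvals)
    return df


def significant_contacts(contacts: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """Records with q-value <= q_max (inclusive), input order preserved."""
    if "qvalue" not in contacts.columns or contacts["qvalue"].isna().any():
        raise ValueError("contacts lack q-values; run annotate_contacts first")
    return contacts.loc[contacts["qvalue"] <= q_max].copy()
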