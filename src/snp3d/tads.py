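"""TopDom-style TAD calling and SNP-rich vs control stratification.

For each inter-bin boundary ``i`` (between bins ``i`` and ``i+1``) the
boundary signal is the mean contact count over the ``w x w`` submatrix of
pairs spanning the boundary (rows ``i-w+1..i`` by columns ``i+1..i+w``,
truncated at chromosome edges). TAD boundaries deplete this signal, so
candidates are local minima of the signal within ``i +/- w``; each candidate
is then tested with a one-sided rank-sum comparison of the cross-boundary
counts against the pooled within-side counts, and kept when the depletion is
significant. Domains are the inter-boundary segments; runs of zero-coverage
bins of length >= w are emitted as gaps and excluded.

Calling consumes raw intra-chromosomal counts — no normalization — mirroring
the contact-significance stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import DistributionSummary, fraction_da, median_da, summarize
from .genomic import ElementIndex, GenomicInterval, RegulatoryElement, SNP

__all__ = [
    "ContactMatrix",
    "TAD",
    "matrix_from_contacts",
    "binsignal",
    "candidate_boundaries",
    "boundary_pvalue",
    "expected_normalize",
    "call_tads",
    "classify_tads",
    "assign_elements",
    "tad_group_summary",
]

logger = logging.getLogger(__name__)

#: Largest pooled sample size for which the rank-sum test is computed exactly.
_EXACT_RANKSUM_MAX = 60


@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal contact matrix at fixed resolution."""

    chrom: str
    resolution: int
    counts: np.ndarray  # (n_bins, n_bins), symmetric, non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class TAD:
    """A called domain; ``start``/``end`` are bin-aligned bp, half-open."""

    id: str
    chrom: str
    start: int
    end: int
    label: Optional[str] = None  # "snp_rich" | "control"
    snps: tuple[SNP, ...] = field(default_factory=tuple)
    elements: tuple[RegulatoryElement, ...] = field(default_factory=tuple)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def matrix_from_contacts(
    contacts: pd.DataFrame, chrom: str, resolution: int, n_bins: Optional[int] = None
) -> ContactMatrix:
    """Densify the intra-chromosomal records of one chromosome."""
    sub = contacts.loc[
        (contacts["chrom1"] == chrom) & (contacts["chrom2"] == chrom)
    ]
    i = (sub["mid1"].to_numpy(int)) // resolution
    j = (sub["mid2"].to_numpy(int)) // resolution
    if n_bins is None:
        n_bins = int(max(i.max(), j.max())) + 1 if len(sub) else 1
    m = np.zeros((n_bins, n_bins))
    m[i, j] = sub["count"].to_numpy(float)
    m[j, i] = m[i, j]
    return ContactMatrix(chrom, resolution, m)


def binsignal(matrix: ContactMatrix, i: int, w: int) -> float:
    """Mean cross-boundary count at the boundary between bins ``i`` and ``i+1``."""
    if w < 1:
        raise ValueError("w must be >= 1")
    n = matrix.n_bins
    if not (0 <= i < n - 1):
        raise ValueError(f"boundary index {i} out of range for {n} bins")
    rows = slice(max(0, i - w + 1), i + 1)
    cols = slice(i + 1, min(n, i + w + 1))
    return float(matrix.counts[rows, cols].mean())


def _signal_vector(matrix: ContactMatrix, w: int) -> np.ndarray:
    return np.array([binsignal(matrix, i, w) for i in range(matrix.n_bins - 1)])


def candidate_boundaries(signal: Sequence[float], w: int) -> list[int]:
    """Local minima of the boundary signal within a window of ``+/- w``.

    A position qualifies when its value is strictly below every earlier value
    and no later value undercuts or equals it within the window — i.e. on a
    plateau of equal minima only the leftmost survives.
    """
    sig = np.asarray(signal, dtype=float)
    out = []
    for i in range(len(sig)):
        lo, hi = max(0, i - w), min(len(sig), i + w + 1)
        left, right = sig[lo:i], sig[i + 1 : hi]
        if (left > sig[i]).all() and (right >= sig[i]).all():
            out.append(i)
    return out


def _cross_within(matrix: ContactMatrix, i: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    n = matrix.n_bins
    left = range(max(0, i - w + 1), i + 1)
    right = range(i + 1, min(n, i + w + 1))
    cross = matrix.counts[np.ix_(list(left), list(right))].ravel()
    within = []
    for side in (list(left), list(right)):
        for a_idx in range(len(side)):
            for b_idx in range(a_idx + 1, len(side)):
                within.append(matrix.counts[side[a_idx], side[b_idx]])
    return cross, np.asarray(within, dtype=float)


def boundary_pvalue(matrix: ContactMatrix, i: int, w: int) -> float:
    """One-sided rank-sum p-value for depletion of cross-boundary counts.

    Tests whether the ``w x w`` cross-boundary counts are stochastically
    smaller than the pooled within-side (upper-triangle) counts. Degenerate
    boundaries with an empty sample on either side return 1.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    cross, within = _cross_within(matrix, i, w)
    if cross.size == 0 or within.size == 0:
        return 1.0
    method = "exact" if cross.size + within.size <= _EXACT_RANKSUM_MAX else "asymptotic"
    res = stats.mannwhitneyu(cross, within, alternative="less", method=method)
    return float(res.pvalue)


def expected_normalize(matrix: ContactMatrix) -> ContactMatrix:
    """Observed/expected transform: divide each diagonal by its mean count.

    Removes the distance-decay trend so that boundary depletion, not decay,
    drives the boundary statistics; diagonals with zero expectation stay 0.
    """
    n = matrix.n_bins
    norm = np.zeros_like(matrix.counts)
    for d in range(n):
        diag = np.diagonal(matrix.counts, d)
        mean = diag.mean()
        if mean > 0:
            vals = diag / mean
            idx = np.arange(n - d)
            norm[idx, idx + d] = vals
            norm[idx + d, idx] = vals
    return ContactMatrix(matrix.chrom, matrix.resolution, norm)


def call_tads(
    matrix: ContactMatrix,
    w: int = 5,
    alpha: float = 0.05,
    min_tad_size: int = 2,
    normalize: str = "expected",
    id_prefix: str = "tad",
) -> list[TAD]:
    """Segment a chromosome into TADs from its contact matrix.

    With ``normalize="expected"`` (default) the boundary statistics run on
    the observed/expected matrix, so the steep contact-frequency decay does
    not masquerade as cross-boundary depletion; ``"raw"`` uses counts as-is.
    Boundaries are signal local minima whose rank-sum depletion p-value is
    below ``alpha``; chromosome ends are implicit boundaries. Segments
    shorter than ``min_tad_size`` bins merge into the preceding segment (the
    first segment, lacking one, merges forward). Zero-coverage runs of
    >= ``w`` bins are treated as gaps: boundaries are forced at their edges
    and the gap segments are dropped from the output.
    """
    if normalize not in ("expected", "raw"):
        raise ValueError(f"unknown normalize mode: {normalize}")
    n = matrix.n_bins
    res = matrix.resolution
    if n < 2 * w:
        logger.warning(
            "%s: %d bins < 2w=%d; emitting a single whole-chromosome TAD",
            matrix.chrom, n, 2 * w,
        )
        return [TAD(f"{id_prefix}_0", matrix.chrom, 0, n * res)]

    stat_matrix = expected_normalize(matrix) if normalize == "expected" else matrix
    signal = _signal_vector(stat_matrix, w)
    cands = candidate_boundaries(signal, w)
    bounds = sorted(
        i for i in cands if boundary_pvalue(stat_matrix, i, w) < alpha
    )

    # gap handling: zero-marginal runs >= w bins become excluded segments
    coverage = matrix.counts.sum(axis=0)
    gap_mask = coverage == 0
    gap_runs: list[tuple[int, int]] = []
    start = None
    for b in range(n + 1):
        if b < n and gap_mask[b]:
            start = b if start is None else start
        elif start is not None:
            if b - start >= w:
                gap_runs.append((start, b))
            start = None
    edges = set(bounds)
    for g0, g1 in gap_runs:
        if g0 > 0:
            edges.add(g0 - 1)  # boundary between g0-1 and g0
        if g1 < n:
            edges.add(g1 - 1)

    cuts = [0] + sorted(i + 1 for i in edges) + [n]
    segments: list[list[int]] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b <= a:
            continue
        if b - a < min_tad_size and segments:
            segments[-1][1] = b  # merge into preceding
        elif b - a < min_tad_size:
            segments.append([a, b])  # first segment: will absorb the next
        else:
            if segments and segments[-1][1] - segments[-1][0] < min_tad_size:
                segments[-1][1] = b  # short first segment merges forward
            else:
                segments.append([a, b])
    tads = []
    for k, (a, b) in enumerate(segments):
        if any(a >= g0 and b <= g1 for g0, g1 in gap_runs):
            continue  # gap segment, excluded
        tads.append(TAD(f"{id_prefix}_{k}", matrix.chrom, a * res, b * res))
    return tads


def classify_tads(tads: Sequence[TAD], high_risk_snps: Sequence[SNP]) -> list[TAD]:
    """Label TADs snp_rich (>= 1 contained high-risk SNP) or control.

    SNPs must already be filtered to genome-wide significance. Containment is
    half-open on the TAD interval, so a SNP at a shared boundary belongs to
    exactly one TAD.
    """
    out = []
    for tad in tads:
        inside = tuple(
            s
            for s in high_risk_snps
            if s.chrom == tad.chrom and tad.start <= s.pos0 < tad.end
        )
        label = "snp_rich" if inside else "control"
        out.append(replace(tad, label=label, snps=inside))
    return out


def assign_elements(tads: Sequence[TAD], elements: ElementIndex) -> list[TAD]:
    """Attach to each TAD the regulatory elements overlapping it (>= 1 bp)."""
    return [
        replace(tad, elements=tuple(elements.query(tad.interval))) for tad in tads
    ]


def tad_group_summary(
    tads: Sequence[TAD],
    elements: Optional[ElementIndex] = None,
    quantile_method: str = "linear",
) -> dict[str, dict[str, DistributionSummary]]:
    """Quantile summaries of per-TAD DA medians, by group and element class.

    Per TAD: the median enhancer DA, and the median TF DA (or, when TFs carry
    flags instead of scores, the disease-associated fraction) over contained
    elements. Those per-TAD values are then summarized within each label
    group. TADs with no elements of a class contribute nothing to that
    class's distribution. Returns
    ``{label: {"enhancer" | "tf": DistributionSummary}}``; empty groups are
    simply absent.
    """
    if elements is not None:
        tads = assign_elements(tads, elements)
    per_group: dict[str, dict[str, list[float]]] = {}
    for tad in tads:
        if tad.label is None:
            raise ValueError("tads must be classified before summarizing")
        enh = [el for el in tad.elements if el.kind == "enhancer"]
        tfs = [el for el in tad.elements if el.kind == "tfbs"]
        slot = per_group.setdefault(tad.label, {"enhancer": [], "tf": []})
        if enh:
            slot["enhancer"].append(median_da(enh))
        if tfs:
            if all(el.da_score is not None for el in tfs):
                slot["tf"].append(median_da(tfs))
            else:
                slot["tf"].append(fraction_da(tfs))
    return {
        label: {
            cls: summarize(vals, method=quantile_method)
            for cls, vals in classes.items()
            if vals
        }
        for label, classes in per_group.items()
    }
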