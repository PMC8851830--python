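"""Synthetic study generator: contact matrix, GWAS table, elements, genes, truth.

One simulated chromosome carries the full structure the pipeline consumes:

* a binned contact matrix with power-law distance decay ``A * d**(-alpha)``,
  block-enriched planted TADs (within-TAD cells scaled by ``1 + tau``) and
  planted long-range loops (loop cells scaled by ``1 + lambda``), under
  Poisson or negative-binomial count noise;
* a GWAS table whose genome-wide-significant subset sits at loop anchors
  (p-values log-uniform below 5e-8), the rest scattered with p above it;
* regulatory elements and genes with disease-association (DA) scores from a
  background distribution N(mu_bg, sigma) or an "associated" distribution
  N(mu_assoc, sigma), both truncated at 0. Associated elements are planted in
  loop-partner bins, background elements in the high-risk SNPs' linear
  windows and scattered genome-wide; scattered elements falling inside a
  SNP-rich TAD have their DA mean raised by ``tad_da_shift`` (and, for TFs,
  the elevated disease-associated flag probability), emulating the TAD-level
  co-localization of variants and disease-associated elements.

Everything is deterministic given ``(config, seed)``; the ground truth
(planted boundaries, loops, SNP-to-partner assignments, element classes) is
recorded alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genomic import Bin, Gene, RegulatoryElement, GenomicInterval, SNP, window_around
from .tads import ContactMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_matrix",
    "simulate_annotations",
    "simulate_study",
    "matrix_to_contacts",
]

_LOG10_P_HIGH_RISK = (-30.0, math.log10(5e-8))
# background p-values start just above the genome-wide threshold
_LOG10_P_BACKGROUND = (-7.3, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults describe one 20 Mbp chromosome binned at 10 kbp with deep
    coverage: 2,000 bins, nearest-neighbour expected count ``base_intensity``,
    decay exponent 1, TADs of 20-60 bins at within-TAD enrichment tau = 2,
    40 loops spanning 100-800 kbp at enrichment lambda = 5, 60 of 500 SNPs
    genome-wide significant and anchored at loops.
    """

    chrom: str = "chr1"
    n_bins: int = 2000
    resolution: int = 10_000
    # contact model
    alpha: float = 1.0
    base_intensity: float = 300.0
    tad_boundaries: Optional[tuple[int, ...]] = None  # explicit TAD start bins
    tad_size_range: tuple[int, int] = (20, 60)
    tau: float = 2.0
    loops: Optional[tuple[tuple[int, int], ...]] = None  # explicit bin pairs
    n_loops: int = 40
    loop_enrichment: float = 5.0
    loop_distance_range: tuple[int, int] = (10, 80)
    noise: str = "poisson"  # "poisson" | "negative-binomial"
    nb_dispersion: float = 0.1
    # annotation model
    n_snps: int = 500
    n_high_risk: int = 60
    n_enhancers: int = 600
    n_tfbs: int = 300
    enhancers_per_anchor: int = 2
    tfbs_per_anchor: int = 3
    enhancers_per_partner: int = 2
    tfbs_per_partner: int = 3
    enhancer_length: int = 1000
    tfbs_length: int = 15
    mu_bg: float = 2.5
    mu_assoc: float = 5.0
    sigma: float = 0.5
    tf_da_prob_bg: float = 0.33
    tf_da_prob_assoc: float = 0.67
    tad_da_shift: float = 1.0
    targets_range: tuple[int, int] = (1, 3)
    gene_pool_size: int = 200  # per element class
    n_tf_names: int = 25

    def validate(self) -> None:
        if self.n_bins < 2 or self.resolution <= 0:
            raise ValueError("n_bins must be >= 2 and resolution > 0")
        if self.tau < 0 or self.loop_enrichment < 0:
            raise ValueError("tau and loop_enrichment must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be > 0")
        if self.n_high_risk > self.n_snps:
            raise ValueError("n_high_risk cannot exceed n_snps")
        if self.noise not in ("poisson", "negative-binomial"):
            raise ValueError(f"unknown noise model: {self.noise}")
        lo, hi = self.loop_distance_range
        if not (1 <= lo <= hi < self.n_bins):
            raise ValueError("invalid loop_distance_range")


@dataclass
class GroundTruth:
    """Planted structure of one simulated study."""

    tad_starts: tuple[int, ...] = ()
    loops: tuple[tuple[int, int], ...] = ()
    snp_partner: dict[str, int] = field(default_factory=dict)  # snp id -> partner bin
    element_class: dict[str, str] = field(default_factory=dict)  # "associated"|"background"
    mu_bg: float = 2.5
    mu_assoc: float = 5.0

    @property
    def internal_boundaries(self) -> tuple[int, ...]:
        """Boundary positions in the between-bins-(i, i+1) convention."""
        return tuple(s - 1 for s in self.tad_starts if s > 0)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            tad_starts=tuple(d["tad_starts"]),
            loops=tuple(tuple(p) for p in d["loops"]),
            snp_partner={k: int(v) for k, v in d["snp_partner"].items()},
            element_class=dict(d["element_class"]),
            mu_bg=d["mu_bg"],
            mu_assoc=d["mu_assoc"],
        )


def _tad_starts(config: SimulationConfig, rng: np.random.Generator) -> tuple[int, ...]:
    if config.tad_boundaries is not None:
        starts = tuple(sorted(set(config.tad_boundaries) | {0}))
        if any(not (0 <= s < config.n_bins) for s in starts):
            raise ValueError("tad_boundaries out of range")
        return starts
    lo, hi = config.tad_size_range
    starts = [0]
    while True:
        nxt = starts[-1] + int(rng.integers(lo, hi + 1))
        if nxt >= config.n_bins - lo:  # last TAD absorbs the remainder
            break
        starts.append(nxt)
    return tuple(starts)


def _sample_loops(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    if config.loops is not None:
        loops = tuple((min(a, b), max(a, b)) for a, b in config.loops)
        if any(not (0 <= a < b < config.n_bins) for a, b in loops):
            raise ValueError("explicit loops out of range")
        return loops
    lo, hi = config.loop_distance_range
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    attempts = 0
    while len(chosen) < config.n_loops:
        attempts += 1
        if attempts > 1000 * max(1, config.n_loops):
            raise ValueError("cannot place loops with distinct endpoint bins")
        d = int(rng.integers(lo, hi + 1))
        i = int(rng.integers(0, config.n_bins - d))
        # distinct endpoint bins keep anchor and partner roles unambiguous
        if i in used or i + d in used:
            continue
        chosen.append((i, i + d))
        used.update((i, i + d))
    return tuple(sorted(chosen))


def simulate_matrix(
    config: SimulationConfig, seed: int
) -> tuple[ContactMatrix, GroundTruth]:
    """Draw one contact matrix with planted TAD blocks and loops.

    Expected count at bin pair (i, j), i != j:
    ``A * |i-j|**(-alpha) * (1 + tau*[same TAD]) * (1 + lambda*[loop])``,
    sampled under the configured noise model. The diagonal is left at zero
    (self-pairs are excluded from every downstream analysis).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    tad_starts = _tad_starts(config, rng)
    if config.loops is None and config.n_loops == 0:
        loops: tuple[tuple[int, int], ...] = ()
    else:
        loops = _sample_loops(config, rng)

    n = config.n_bins
    tad_id = np.zeros(n, dtype=int)
    for k, s in enumerate(tad_starts):
        tad_id[s:] = k

    iu, ju = np.triu_indices(n, k=1)
    d = (ju - iu).astype(float)
    mu = config.base_intensity * d ** (-config.alpha)
    mu *= np.where(tad_id[iu] == tad_id[ju], 1.0 + config.tau, 1.0)
    if loops:
        la = np.fromiter((a for a, _ in loops), int)
        lb = np.fromiter((b for _, b in loops), int)
        loop_lin = la * n + lb
        pair_lin = iu * n + ju
        mu[np.isin(pair_lin, loop_lin)] *= 1.0 + config.loop_enrichment

    if config.noise == "poisson":
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu * config.nb_dispersion)
        counts = rng.poisson(lam)

    m = np.zeros((n, n))
    m[iu, ju] = counts
    m[ju, iu] = counts
    truth = GroundTruth(
        tad_starts=tad_starts,
        loops=loops,
        mu_bg=config.mu_bg,
        mu_assoc=config.mu_assoc,
    )
    return ContactMatrix(config.chrom, config.resolution, m), truth


def matrix_to_contacts(matrix: ContactMatrix) -> pd.DataFrame:
    """Nonzero upper-triangle entries as a FitHiC-style contact table."""
    iu, ju = np.triu_indices(matrix.n_bins, k=1)
    counts = matrix.counts[iu, ju]
    nz = counts > 0
    res = matrix.resolution
    half = res // 2
    return pd.DataFrame(
        {
            "chrom1": matrix.chrom,
            "mid1": iu[nz] * res + half,
            "chrom2": matrix.chrom,
            "mid2": ju[nz] * res + half,
            "count": counts[nz].astype(int),
        }
    )


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float) -> float:
    """Normal draw truncated at 0 (by redraw; mass below 0 is tiny here)."""
    for _ in range(100):
        x = rng.normal(mu, sigma)
        if x >= 0:
            return float(x)
    return 0.0


class _GenePool:
    """Lazily scored gene pool, one per element class."""

    def __init__(self, prefix: str, size: int, mu: float, sigma: float):
        self.prefix, self.size, self.mu, self.sigma = prefix, size, mu, sigma
        self.genes: dict[str, Gene] = {}

    def draw_targets(self, rng: np.random.Generator, k: int) -> tuple[str, ...]:
        idx = rng.choice(self.size, size=min(k, self.size), replace=False)
        symbols = []
        for i in sorted(int(x) for x in idx):
            sym = f"{self.prefix}{i:04d}"
            if sym not in self.genes:
                self.genes[sym] = Gene(sym, _truncated_normal(rng, self.mu, self.sigma))
            symbols.append(sym)
        return tuple(symbols)


def simulate_annotations(
    config: SimulationConfig, truth: GroundTruth, seed: int
) -> tuple[list[SNP], list[RegulatoryElement], dict[str, Gene]]:
    """Draw the GWAS, element, and gene tables consistent with a matrix truth.

    Mutates ``truth`` in place with SNP-to-partner-bin assignments and
    element class labels.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    res = config.resolution
    chrom_len = config.n_bins * res

    # --- high-risk SNPs at loop anchors ----------------------------------
    # One side of each loop is designated the anchor (SNP-bearing) side, the
    # other the partner side, so background anchor elements and associated
    # partner elements never share a bin. Loops host a second SNP on the
    # same anchor side when there are more high-risk SNPs than loops.
    if config.n_high_risk > 2 * max(1, len(truth.loops)):
        raise ValueError(
            f"n_high_risk={config.n_high_risk} exceeds "
            f"{2 * len(truth.loops)} loop anchor slots"
        )
    sides = [
        (a, b) if rng.random() < 0.5 else (b, a) for a, b in truth.loops
    ]
    n_loops = len(sides)
    if config.n_high_risk <= n_loops:
        pick = rng.choice(n_loops, size=config.n_high_risk, replace=False)
        slots = [sides[int(i)] for i in sorted(int(x) for x in pick)]
    else:
        extra = rng.choice(n_loops, size=config.n_high_risk - n_loops, replace=False)
        slots = sorted(sides + [sides[int(i)] for i in extra])
    snps: list[SNP] = []
    lo_hr, hi_hr = _LOG10_P_HIGH_RISK
    for k, (anchor, partner) in enumerate(slots):
        pos = int(anchor * res + rng.integers(res // 4, 3 * res // 4)) + 1
        pval = 10.0 ** rng.uniform(lo_hr, hi_hr)
        snp = SNP(f"rs{k:05d}", config.chrom, pos, min(pval, 5e-8))
        snps.append(snp)
        truth.snp_partner[snp.id] = partner

    # --- background SNPs --------------------------------------------------
    lo_bg, hi_bg = _LOG10_P_BACKGROUND
    for k in range(config.n_high_risk, config.n_snps):
        pos = int(rng.integers(0, chrom_len)) + 1
        pval = min(1.0, 10.0 ** rng.uniform(lo_bg, hi_bg))
        snps.append(SNP(f"rs{k:05d}", config.chrom, pos, pval))

    # --- TAD context for DA shifts ---------------------------------------
    tad_edges = list(truth.tad_starts) + [config.n_bins]
    hr_bins = {(s.pos - 1) // res for s in snps[: config.n_high_risk]}
    snp_rich_tads = {
        t
        for t in range(len(truth.tad_starts))
        if any(tad_edges[t] <= b < tad_edges[t + 1] for b in hr_bins)
    }

    def tad_of(bin_idx: int) -> int:
        return int(np.searchsorted(truth.tad_starts, bin_idx, side="right") - 1)

    pools = {
        "associated": _GenePool("GA", config.gene_pool_size, config.mu_assoc, config.sigma),
        "background": _GenePool("GB", config.gene_pool_size, config.mu_bg, config.sigma),
    }
    tf_names = [f"TF{k:02d}" for k in range(config.n_tf_names)]
    elements: list[RegulatoryElement] = []
    counters = {"enhancer": 0, "tfbs": 0}

    def add_element(
        kind: str, start: int, cls: str, da_mu: float, tf_prob: float
    ) -> None:
        length = config.enhancer_length if kind == "enhancer" else config.tfbs_length
        start = max(0, min(start, chrom_len - length))
        counters[kind] += 1
        eid = f"{'enh' if kind == 'enhancer' else 'tfbs'}_{counters[kind]:05d}"
        t_lo, t_hi = config.targets_range
        targets = pools[cls].draw_targets(rng, int(rng.integers(t_lo, t_hi + 1)))
        if kind == "enhancer":
            el = RegulatoryElement(
                id=eid,
                kind=kind,
                interval=GenomicInterval(config.chrom, start, start + length),
                da_score=_truncated_normal(rng, da_mu, config.sigma),
                target_genes=targets,
            )
        else:
            el = RegulatoryElement(
                id=eid,
                kind=kind,
                interval=GenomicInterval(config.chrom, start, start + length),
                disease_associated=bool(rng.random() < tf_prob),
                tf_name=str(rng.choice(tf_names)),
                target_genes=targets,
            )
        elements.append(el)
        truth.element_class[eid] = cls

    # planted elements: background in each high-risk SNP's linear window,
    # associated in its loop-partner bin
    for snp in snps[: config.n_high_risk]:
        win = window_around(snp, res)
        partner = truth.snp_partner[snp.id]
        p_lo, p_hi = partner * res, (partner + 1) * res
        for _ in range(config.enhancers_per_anchor):
            start = int(rng.integers(win.start, max(win.start + 1, win.end - config.enhancer_length)))
            add_element("enhancer", start, "background", config.mu_bg, config.tf_da_prob_bg)
        for _ in range(config.tfbs_per_anchor):
            start = int(rng.integers(win.start, win.end - config.tfbs_length))
            add_element("tfbs", start, "background", config.mu_bg, config.tf_da_prob_bg)
        for _ in range(config.enhancers_per_partner):
            start = int(rng.integers(p_lo, p_hi - config.enhancer_length))
            add_element("enhancer", start, "associated", config.mu_assoc, config.tf_da_prob_assoc)
        for _ in range(config.tfbs_per_partner):
            start = int(rng.integers(p_lo, p_hi - config.tfbs_length))
            add_element("tfbs", start, "associated", config.mu_assoc, config.tf_da_prob_assoc)

    # scattered background elements; inside SNP-rich TADs the DA mean is
    # shifted by tad_da_shift and the TF flag probability is elevated
    for kind, n_el in (("enhancer", config.n_enhancers), ("tfbs", config.n_tfbs)):
        for _ in range(n_el):
            start = int(rng.integers(0, chrom_len))
            in_rich = tad_of(start // res) in snp_rich_tads
            mu = config.mu_bg + (config.tad_da_shift if in_rich else 0.0)
            tf_p = config.tf_da_prob_assoc if in_rich else config.tf_da_prob_bg
            add_element(kind, start, "background", mu, tf_p)

    genes: dict[str, Gene] = {}
    for pool in pools.values():
        genes.update(pool.genes)
    return snps, elements, genes


def simulate_study(
    config: SimulationConfig, outdir: str | Path, seed: int
) -> dict[str, Path]:
    """Write a complete synthetic input bundle to ``outdir``.

    Emits ``contacts.tsv``, ``gwas.tsv``, ``elements.bed``, ``genes.tsv``,
    ``truth.json`` and ``config.json``; returns the path of each. The bundle
    is fully consumable by the pipeline readers.
    """
    from . import io as _io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_matrix(config, seed)
    snps, elements, genes = simulate_annotations(config, truth, seed + 1)

    paths = {
        "contacts": outdir / "contacts.tsv",
        "gwas": outdir / "gwas.tsv",
        "elements": outdir / "elements.bed",
        "genes": outdir / "genes.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    _io.write_contacts(matrix_to_contacts(matrix), paths["contacts"])
    _io.write_gwas(snps, paths["gwas"])
    _io.write_elements(elements, paths["elements"])
    _io.write_genes(genes.values(), paths["genes"])
    paths["truth"].write_text(truth.to_json() + "\n")
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True) + "\n"
    )
    return paths
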