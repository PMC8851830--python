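"""End-to-end workflows: contact significance -> SNP mapping -> TAD stratification.

``run_pipeline`` executes the two analyses on one input bundle:

1. the 1D-vs-3D comparison — annotate contacts, keep the significant set
   (q <= q_max), select genome-wide-significant SNPs (p <= p_max), map each
   through a linear window and through its most confident contact, and
   summarize per-SNP median DA scores per condition;
2. the TAD stratification — call TADs per chromosome, label them SNP-rich or
   control, and summarize per-TAD element DA by group.

All outputs are plain text and a run is fully determined by its manifest
(config echo + input checksums): rerunning with identical inputs reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from . import io as _io
from .aggregate import DistributionSummary, summarize
from .contacts import annotate_contacts, significant_contacts
from .genomic import ElementIndex, Gene, SNP
from .mapping import GWAS_P_MAX, SNPMapping, map_1d, map_3d, select_high_risk
from .tads import (
    TAD,
    assign_elements,
    call_tads,
    classify_tads,
    matrix_from_contacts,
    tad_group_summary,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "map_all_snps",
    "mapping_table",
    "mapping_summary",
    "summaries_to_frame",
    "render_report",
    "call_and_classify_tads",
]

logger = logging.getLogger(__name__)

SUMMARY_STATS = ["n", "q1", "q2", "q3", "iqr"]


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, plus input locations."""

    contacts: str = "contacts.tsv"
    gwas: str = "gwas.tsv"
    elements: str = "elements.bed"
    genes: str = "genes.tsv"
    outdir: str = "results"
    resolution: int = 10_000
    q_max: float = 0.05
    p_max: float = GWAS_P_MAX
    n_strata: int = 1000
    min_contact_distance: Optional[float] = None  # default: one bin
    selection_scope: str = "per_class"
    tad_w: int = 5
    tad_alpha: float = 0.05
    min_tad_size: int = 2
    quantile_method: str = "linear"
    elements_one_based: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        for name in ("q_max", "p_max"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.selection_scope not in ("per_class", "joint"):
            raise ValueError("selection_scope must be per_class or joint")


def map_all_snps(
    snps: Sequence[SNP],
    sig_contacts: pd.DataFrame,
    elements: ElementIndex,
    genes: Mapping[str, Gene],
    resolution: int,
    selection_scope: str = "per_class",
) -> list[SNPMapping]:
    """1D and 3D mappings for every SNP, interleaved per SNP."""
    out: list[SNPMapping] = []
    for snp in snps:
        out.append(map_1d(snp, elements, resolution, genes))
        out.append(
            map_3d(snp, sig_contacts, elements, resolution, genes, selection_scope)
        )
    return out


def mapping_table(mappings: Sequence[SNPMapping]) -> pd.DataFrame:
    """One row per (SNP, mode): selected fragment, elements, genes, summaries."""
    rows = []
    for m in mappings:
        frag = m.selected_fragments[0] if m.selected_fragments else None
        rows.append(
            {
                "snp_id": m.snp.id,
                "mode": m.mode,
                "chrom": m.snp.chrom,
                "pos_1based": m.snp.pos,
                "snp_pvalue": m.snp.pvalue,
                "fragment": (
                    ";".join(
                        f"{f.bin.chrom}:{f.bin.interval.start}-{f.bin.interval.end}"
                        for f in m.selected_fragments
                    )
                    or "."
                ),
                "contact_q": frag.qvalue if frag else None,
                "contact_distance": (
                    frag.distance if frag and frag.distance is not None else
                    ("inter" if frag else None)
                ),
                "enhancer_ids": ",".join(el.id for el in m.enhancers) or ".",
                "tfbs_ids": ",".join(el.id for el in m.tfbs) or ".",
                "target_genes": ",".join(g.symbol for g in m.target_genes) or ".",
                "median_da_enhancer": m.median_da_enhancer,
                "median_da_tf": m.median_da_tf,
                "median_da_targets": m.median_da_targets,
                "tf_fraction": m.tf_fraction,
            }
        )
    return pd.DataFrame(rows)


def per_snp_values(mappings: Sequence[SNPMapping]) -> dict[str, list[float]]:
    """Per-SNP summary values grouped by condition; unmapped SNPs contribute nothing."""
    conds: dict[str, list[float]] = {}
    for m in mappings:
        mode = m.mode.lower()
        for name, value in (
            (f"enhancer_da_{mode}", m.median_da_enhancer),
            (f"target_da_{mode}", m.median_da_targets),
            (f"tf_da_{mode}", m.median_da_tf),
            (f"tf_fraction_{mode}", m.tf_fraction),
        ):
            if value is not None:
                conds.setdefault(name, []).append(value)
    return conds


def mapping_summary(
    mappings: Sequence[SNPMapping], quantile_method: str = "linear"
) -> dict[str, DistributionSummary]:
    """Quantile/IQR summaries over per-SNP values, one per condition."""
    return {
        name: summarize(vals, method=quantile_method)
        for name, vals in sorted(per_snp_values(mappings).items())
        if vals
    }


def summaries_to_frame(summaries: Mapping[str, DistributionSummary]) -> pd.DataFrame:
    """Statistic-by-condition table mirroring the violin-figure statistics."""
    frame = pd.DataFrame(
        {
            name: [s.n, s.q1, s.q2, s.q3, s.iqr]
            for name, s in summaries.items()
        },
        index=SUMMARY_STATS,
    )
    frame.index.name = "statistic"
    return frame


def call_and_classify_tads(
    contacts: pd.DataFrame,
    high_risk: Sequence[SNP],
    elements: ElementIndex,
    resolution: int,
    w: int = 5,
    alpha: float = 0.05,
    min_tad_size: int = 2,
) -> list[TAD]:
    """Call, label, and annotate TADs on every chromosome present in contacts."""
    chroms = sorted(set(contacts["chrom1"]) | set(contacts["chrom2"]))
    tads: list[TAD] = []
    for chrom in chroms:
        matrix = matrix_from_contacts(contacts, chrom, resolution)
        called = call_tads(
            matrix, w=w, alpha=alpha, min_tad_size=min_tad_size,
            id_prefix=f"tad_{chrom}",
        )
        tads.extend(called)
    tads = classify_tads(tads, high_risk)
    return assign_elements(tads, elements)


def tads_to_bed(tads: Sequence[TAD]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [t.chrom for t in tads],
            "start": [t.start for t in tads],
            "end": [t.end for t in tads],
            "id": [t.id for t in tads],
            "label": [t.label or "." for t in tads],
        }
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def render_report(
    mapping_summaries: Mapping[str, DistributionSummary],
    tad_summaries: Mapping[str, Mapping[str, DistributionSummary]],
    outdir: Path,
    plots: bool = False,
    values: Optional[Mapping[str, Sequence[float]]] = None,
) -> dict[str, Path]:
    """Write the statistic tables (and optional violin figures) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["mapping_summary"] = outdir / "mapping_summary.tsv"
    summaries_to_frame(mapping_summaries).to_csv(
        paths["mapping_summary"], sep="\t", float_format="%.6g"
    )

    flat = {
        f"{cls}_{label}": s
        for label, classes in sorted(tad_summaries.items())
        for cls, s in sorted(classes.items())
    }
    paths["tad_summary"] = outdir / "tad_summary.tsv"
    summaries_to_frame(flat).to_csv(paths["tad_summary"], sep="\t", float_format="%.6g")

    report = {
        "mapping": {k: dataclasses.asdict(s) for k, s in sorted(mapping_summaries.items())},
        "tads": {
            label: {cls: dataclasses.asdict(s) for cls, s in sorted(classes.items())}
            for label, classes in sorted(tad_summaries.items())
        },
    }
    paths["report"] = outdir / "report.json"
    paths["report"].write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")

    if plots and values:
        try:
            path = _violin_plot(values, outdir / "da_violins.png")
            if path is not None:
                paths["violins"] = path
        except ImportError:  # matplotlib is an optional extra
            logger.warning("matplotlib not installed; skipping violin figures")
    return paths


def _violin_plot(values: Mapping[str, Sequence[float]], path: Path) -> Optional[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    items = [(k, list(v)) for k, v in sorted(values.items()) if len(v) > 0]
    if not items:
        return None
    fig, ax = plt.subplots(figsize=(1.5 * len(items) + 2, 4))
    ax.violinplot([v for _, v in items], showmedians=True)
    ax.set_xticks(range(1, len(items) + 1))
    ax.set_xticklabels([k for k, _ in items], rotation=45, ha="right")
    ax.set_ylabel("disease-association score")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def run_pipeline(config: RunConfig, plots: bool = False) -> dict[str, Path]:
    """Execute both workflows and write every declared output plus a manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = {
        "contacts": Path(config.contacts),
        "gwas": Path(config.gwas),
        "elements": Path(config.elements),
        "genes": Path(config.genes),
    }
    try:
        contacts = _io.read_contacts(inputs["contacts"])
        snps = _io.read_gwas(inputs["gwas"])
        elements = _io.read_elements(inputs["elements"], one_based=config.elements_one_based)
        genes = _io.read_genes(inputs["genes"])
    except Exception as exc:
        raise RuntimeError(f"[ingest] {exc}") from exc

    try:
        annotated = annotate_contacts(
            contacts,
            n_strata=config.n_strata,
            min_distance=config.min_contact_distance,
            resolution=config.resolution,
        )
        sig = significant_contacts(annotated, config.q_max)
    except Exception as exc:
        raise RuntimeError(f"[contact-significance] {exc}") from exc
    logger.info("%d of %d contacts significant at q <= %g", len(sig), len(annotated), config.q_max)

    high_risk = select_high_risk(snps, config.p_max)
    logger.info("%d of %d SNPs at p <= %g", len(high_risk), len(snps), config.p_max)

    try:
        mappings = map_all_snps(
            high_risk, sig, elements, genes, config.resolution, config.selection_scope
        )
        summaries = mapping_summary(mappings, config.quantile_method)
    except Exception as exc:
        raise RuntimeError(f"[variant-mapping] {exc}") from exc

    try:
        tads = call_and_classify_tads(
            contacts, high_risk, elements, config.resolution,
            w=config.tad_w, alpha=config.tad_alpha, min_tad_size=config.min_tad_size,
        )
        tad_summaries = tad_group_summary(tads, quantile_method=config.quantile_method)
    except Exception as exc:
        raise RuntimeError(f"[tad-analysis] {exc}") from exc

    paths: dict[str, Path] = {}
    paths["annotated_contacts"] = outdir / "contacts_annotated.tsv"
    _io.write_contacts(annotated, paths["annotated_contacts"])
    paths["significant_contacts"] = outdir / "significant_contacts.tsv"
    _io.write_contacts(sig, paths["significant_contacts"])
    paths["mappings"] = outdir / "snp_mappings.tsv"
    mapping_table(mappings).to_csv(paths["mappings"], sep="\t", index=False, float_format="%.6g")
    paths["tads"] = outdir / "tads.bed"
    tads_to_bed(tads).to_csv(paths["tads"], sep="\t", index=False, header=False)
    paths.update(
        render_report(
            summaries, tad_summaries, outdir,
            plots=plots, values=per_snp_values(mappings),
        )
    )

    manifest = {
        "package": {"name": "snp3d", "version": __version__},
        "config": dataclasses.asdict(config),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(paths.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path
    return paths
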