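"""Descriptive surfaces and the end-to-end pipeline.

Emits the study's presentation-layer artifacts as *data* rather than
figures: volcano/scatter tables, PCA sample coordinates, clustered
row/column orderings for heat maps, ranked top tables, and a structured
summary — everything a plotting layer would need, all deterministic
functions of the inputs, parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from . import classify as _classify
from . import diffexpr as _de
from . import enrich as _enrich
from . import simdata as _sim

__all__ = [
    "PcaCoordinates",
    "pca_coords",
    "scatter_table",
    "top_table",
    "cluster_order",
    "PipelineConfig",
    "run_pipeline",
]


@dataclass
class PcaCoordinates:
    """Sample scores and per-component variance fractions."""

    scores: pd.DataFrame  # samples x PC1..PCk
    variance_ratio: np.ndarray


def pca_coords(
    logcpm: pd.DataFrame, n_components: int = 2, n_top_genes: int | None = None
) -> PcaCoordinates:
    """PCA of samples from a genes x samples log-expression matrix.

    Optionally restricts to the ``n_top_genes`` most variable genes.  The
    sign of each component is fixed so that its largest-magnitude gene
    loading is positive, making the coordinates deterministic.
    """
    if logcpm.shape[0] < 2 or logcpm.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 samples")
    mat = logcpm
    if n_top_genes is not None and n_top_genes < mat.shape[0]:
        var = mat.var(axis=1)
        keep = var.sort_values(ascending=False, kind="mergesort").index[:n_top_genes]
        mat = mat.loc[keep]
    x = mat.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise ValueError("degenerate input: expression matrix is constant")

    k = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    for i in range(k):
        j = int(np.argmax(np.abs(pca.components_[i])))
        if pca.components_[i, j] < 0:
            pca.components_[i] *= -1
            scores[:, i] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcaCoordinates(
        scores=pd.DataFrame(scores, index=logcpm.columns, columns=cols),
        variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def scatter_table(triplet: _de.ContrastTriplet) -> pd.DataFrame:
    """Per-gene λ4 vs λ3 fold changes with a four-way significance class.

    Classes: "both" (DEG in both vs-NT contrasts), "l3_only", "l4_only",
    "neither" — exactly the DEG calls of the two vs-NT contrasts.
    """
    a = triplet.results["L3vNT"].table
    b = triplet.results["L4vNT"].table
    sig3 = a["is_DEG"]
    sig4 = b["is_DEG"]
    cls = np.where(
        sig3 & sig4, "both",
        np.where(sig3, "l3_only", np.where(sig4, "l4_only", "neither")),
    )
    return pd.DataFrame(
        {"FC_l4": b["signed_FC"], "FC_l3": a["signed_FC"], "sig_class": cls},
        index=a.index,
    )


def top_table(
    result: _de.ContrastResult, n: int = 10, direction: str = "up"
) -> pd.DataFrame:
    """Top-n DEGs of one direction, ranked by |signed FC| descending.

    Ties broken by p-value (ascending) then gene id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    t = result.table
    mask = t["is_DEG"] & ((t["signed_FC"] > 0) == (direction == "up"))
    sub = t[mask].copy()
    sub["_absfc"] = sub["signed_FC"].abs()
    sub["_gene"] = sub.index
    sub = sub.sort_values(
        ["_absfc", "p_value", "_gene"], ascending=[False, True, True], kind="mergesort"
    )
    return sub.drop(columns=["_absfc", "_gene"]).head(n)


def cluster_order(logcpm: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Average-linkage (Euclidean, z-scored rows) leaf orders for heat maps.

    Returns (gene order, sample order).  Rows with zero variance are
    z-scored to zero.
    """
    x = logcpm.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    z = (x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
    gene_order = list(logcpm.index)
    if len(gene_order) > 2:
        link = hierarchy.linkage(pdist(z), method="average")
        gene_order = [logcpm.index[i] for i in hierarchy.leaves_list(link)]
    sample_order = list(logcpm.columns)
    if len(sample_order) > 2:
        link = hierarchy.linkage(pdist(z.T), method="average")
        sample_order = [logcpm.columns[i] for i in hierarchy.leaves_list(link)]
    return gene_order, sample_order


@dataclass
class PipelineConfig:
    """End-to-end run parameters.

    Either ``simulate`` is true (counts drawn from ``sim``) or
    ``counts_path`` / ``design_path`` point at TSV inputs.  ``gmt_path``
    switches on over-representation analysis of the per-contrast DEG
    sets.  All randomness flows from ``seed`` (which overrides
    ``sim.seed`` when simulating).
    """

    simulate: bool = True
    counts_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    sim: _sim.SimConfig = field(default_factory=_sim.SimConfig)
    tiers: _classify.TierThresholds = field(default_factory=_classify.TierThresholds)
    min_cpm: float = 1.0
    min_samples: int = 2
    ora_fdr: float = 0.05
    pca_top_genes: int = 500
    seed: int = 0


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate or load counts, then test, classify, enrich and report.

    Writes per-contrast tables, per-gene classifications, PCA
    coordinates, scatter and top tables, optional enrichment tables, and
    a machine-readable ``summary.json`` plus a human-readable
    ``summary.txt``.  Identical config gives bit-identical outputs.
    Returns the summary dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config

    if cfg.simulate:
        sim_cfg = _sim.SimConfig(**{**asdict(cfg.sim), "seed": cfg.seed})
        counts, design, truth = _sim.simulate_counts(sim_cfg)
        _sim.write_counts(counts, out / "counts.tsv")
        _sim.write_design(design, out / "design.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        if cfg.counts_path is None or cfg.design_path is None:
            raise ValueError("counts_path and design_path are required when not simulating")
        counts = _sim.read_counts(cfg.counts_path)
        design = _sim.read_design(cfg.design_path)
        missing = set(design.index) - set(counts.columns)
        if missing:
            raise ValueError(f"design samples missing from counts: {sorted(missing)[:5]}")

    thresholds = _de.deg_thresholds_from_tiers(cfg.tiers)
    collection = _enrich.read_gmt(cfg.gmt_path) if cfg.gmt_path else None

    cell_types = sorted(design["cell_type"].unique())
    classes_by_ct: dict[str, pd.DataFrame] = {}
    deg_counts: dict[str, dict[str, int]] = {}
    for ct in cell_types:
        triplet = _de.run_triplet(
            counts, design, ct, thresholds=thresholds,
            min_cpm=cfg.min_cpm, min_samples=cfg.min_samples,
        )
        deg_counts[ct] = {}
        for name, res in triplet.results.items():
            res.table.to_csv(out / f"{ct}_{name}.tsv", sep="\t", index_label="gene")
            deg_counts[ct][name] = int(res.table["is_DEG"].sum())
            for direction in ("up", "down"):
                top_table(res, n=10, direction=direction).to_csv(
                    out / f"{ct}_{name}_top_{direction}.tsv", sep="\t", index_label="gene"
                )
        scatter_table(triplet).to_csv(out / f"{ct}_scatter.tsv", sep="\t", index_label="gene")

        classes = _classify.classify_table(triplet.to_classify_input(), cfg.tiers)
        classes.to_csv(out / f"{ct}_classification.tsv", sep="\t", index_label="gene")
        classes_by_ct[ct] = classes

        if collection is not None:
            universe = set(triplet.results["L3vNT"].table.index)
            ora = {}
            for name, res in triplet.results.items():
                rows = _enrich.run_ora(_de.call_degs(res), universe, collection)
                rows.to_csv(out / f"{ct}_{name}_ora.tsv", sep="\t", index=False)
                ora[name] = rows
            labels = _enrich.compare_contrast_enrichments(
                ora["L3vNT"], ora["L4vNT"], ora["L4vL3"], cfg.ora_fdr
            )
            labels.to_csv(out / f"{ct}_ora_labels.tsv", sep="\t", index=False)

    # PCA across all samples on log2 CPM of the most-variable genes
    lib = counts.sum(axis=0)
    logcpm = np.log2(_de.cpm(counts, lib) + 1.0)
    coords = pca_coords(logcpm, n_components=2, n_top_genes=cfg.pca_top_genes)
    pca_out = coords.scores.join(design)
    pca_out.to_csv(out / "pca.tsv", sep="\t", index_label="sample")

    gene_order, sample_order = cluster_order(
        logcpm.loc[logcpm.var(axis=1).sort_values(ascending=False, kind="mergesort").index[:200]]
    )
    (out / "heatmap_order.json").write_text(
        json.dumps({"genes": gene_order, "samples": sample_order}, indent=1) + "\n"
    )

    summary = _classify.summarize(classes_by_ct).to_dict()
    summary["deg_counts"] = deg_counts
    summary["pca_variance_ratio"] = [float(v) for v in coords.variance_ratio]
    summary["parameters"] = {
        "seed": cfg.seed,
        "simulate": cfg.simulate,
        "tiers": asdict(cfg.tiers),
        "min_cpm": cfg.min_cpm,
        "min_samples": cfg.min_samples,
        "ora_fdr": cfg.ora_fdr,
        "pca_top_genes": cfg.pca_top_genes,
    }
    if cfg.simulate:
        summary["parameters"]["sim"] = _jsonable(asdict(sim_cfg))

    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1, sort_keys=True) + "\n")
    (out / "summary.txt").write_text(_render_summary(summary))
    return summary


def _render_summary(summary: dict) -> str:
    lines = ["Three-contrast perturbation analysis summary", "=" * 44, ""]
    for ct, s in summary["per_cell_type"].items():
        lines.append(f"[{ct}]")
        lines.append(f"  genes significant in >=1 contrast: {s['n_significant']}")
        lines.append("  Venn regions: " + ", ".join(
            f"{k}={v}" for k, v in s["region_counts"].items() if k != "none"
        ))
        lines.append("  categories:   " + ", ".join(
            f"{k}={v}" for k, v in s["category_counts"].items()
        ))
        lines.append(f"  unperturbed by IFN-λ4: {s['unperturbed_by_l4']}")
        lines.append(f"  unperturbed by IFN-λ3: {s['unperturbed_by_l3']}")
        lines.append(f"  reciprocally regulated: {s['reciprocal']}")
        lines.append("")
    lines.append(f"reciprocal genes, all cell types: {summary['reciprocal_total']}")
    lines.append(
        "uniquely IFN-λ4-significant genes, all cell types: "
        f"{summary['lambda4_unique_total']}"
    )
    lines.append(
        "  of which same-direction: "
        f"{summary['lambda4_unique_same_direction_total']}"
    )
    lines.append("")
    return "\n".join(lines)
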