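"""Visualisation toolkit and machine-readable run summary.

Renders the framework's standard figure set — the expanded dissimilarity
heatmap with its dendrogram, the classified comparison-level heatmap (green
for "low", red for "likely concerning"), the silhouette profile and width
plots, the stacked bar of fragmented comparisons and per-cluster
characteristic distributions — plus a deterministic JSON summary that
round-trips the numeric results.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from scipy.cluster import hierarchy

from .clustering import (
    FragmentationReport,
    SilhouetteProfile,
    TransitivityClustering,
    fragmented_comparisons,
)
from .comparison import (
    ClassifiedMatrix,
    ComparisonDissimMatrix,
    build_comparison_matrix,
    classify,
    lookup_threshold,
)
from .dataset import ComparisonTable, StudyDataset, expand_comparisons
from .gower import DistMatrix, GowerDissimilarity

#: above this many observations the dendrogram-heatmap is still produced but
#: flagged as appendix material, where large networks are best reported
APPENDIX_SCALE_N = 40


@dataclass
class AnalysisResult:
    """All objects produced by one full run of the framework."""

    dataset: StudyDataset
    table: ComparisonTable
    dist: DistMatrix
    comparison_matrix: ComparisonDissimMatrix
    classified: ClassifiedMatrix
    clusterer: TransitivityClustering
    fragmentation: FragmentationReport

    @property
    def threshold(self) -> float:
        return self.classified.threshold


def run_pipeline(
    ds: StudyDataset,
    threshold: Optional[float] = None,
    outcome: str = "general",
    comparator: str = "general",
    size: str = "general",
    linkage: str = "auto",
    n_clusters="auto",
    random_state: Optional[int] = None,
    elope_threshold_pct: float = 5.0,
) -> AnalysisResult:
    """Full analysis: expand, Gower, comparison matrix, classify, cluster."""
    ct = expand_comparisons(ds)
    gd = GowerDissimilarity().fit(ds)
    values = gd.transform(ct)
    dist = gd.dist_matrix_
    cm = build_comparison_matrix(dist, ct)
    if threshold is None:
        threshold = lookup_threshold(outcome, comparator, size)
    cls = classify(cm, threshold)
    clusterer = TransitivityClustering(
        linkage=linkage, n_clusters=n_clusters, random_state=random_state
    ).fit(dist)
    frag = fragmented_comparisons(clusterer.labels_, ct, elope_threshold_pct)
    return AnalysisResult(ds, ct, dist, cm, cls, clusterer, frag)


@dataclass
class RunManifest:
    """Paths of every artifact written by :func:`render_report`."""

    outdir: str
    files: dict = field(default_factory=dict)
    appendix_scale: bool = False

    def to_dict(self) -> dict:
        return {"outdir": self.outdir, "files": dict(self.files),
                "appendix_scale": self.appendix_scale}


def _save(fig, outdir: Path, stem: str, manifest: RunManifest) -> None:
    for ext in ("png", "svg"):
        path = outdir / f"{stem}.{ext}"
        fig.savefig(path, dpi=150, bbox_inches="tight",
                    metadata={"Date": None} if ext == "svg" else None)
        manifest.files[f"{stem}_{ext}"] = str(path)
    plt.close(fig)


def _plot_d_heatmap_dendrogram(res: AnalysisResult, outdir: Path, m: RunManifest):
    dm = res.dist
    Z = res.clusterer.merge_tree_
    order = hierarchy.leaves_list(Z)
    n = dm.n
    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(max(6, n * 0.28), max(7, n * 0.3)),
        gridspec_kw={"height_ratios": [1, 4], "hspace": 0.02},
    )
    hierarchy.dendrogram(Z, ax=ax_d, no_labels=True,
                         color_threshold=None, link_color_func=lambda _: "0.3")
    ax_d.set_axis_off()
    ordered = dm.values[np.ix_(order, order)]
    labels = [dm.labels[i] for i in order]
    sns.heatmap(ordered, ax=ax_h, cmap="viridis", vmin=0, vmax=1,
                xticklabels=labels, yticklabels=labels, cbar_kws={"shrink": 0.6},
                square=False, annot=n <= 12, fmt=".2f")
    ax_h.tick_params(labelsize=6)
    fig.suptitle("Pairwise Gower dissimilarities with dendrogram")
    _save(fig, outdir, "d_heatmap_dendrogram", m)


def _plot_classified_heatmap(res: AnalysisResult, outdir: Path, m: RunManifest):
    cm, cls = res.comparison_matrix, res.classified
    P = cm.P
    colors = np.where(cls.labels == "low", 0, 1).astype(float)
    fig, ax = plt.subplots(figsize=(max(5, P * 0.6), max(4, P * 0.55)))
    sns.heatmap(colors, ax=ax, cmap=matplotlib.colors.ListedColormap(["#2e7d32", "#c62828"]),
                vmin=0, vmax=1, cbar=False,
                xticklabels=cm.comparisons, yticklabels=cm.comparisons,
                annot=np.round(cm.values, 2), fmt=".2f",
                annot_kws={"color": "white", "fontsize": 8})
    ax.set_title(f"Within (diagonal) and between comparison dissimilarities\n"
                 f"green: low (< {cls.threshold:g}), red: likely concerning")
    ax.tick_params(labelsize=7)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    _save(fig, outdir, "D_heatmap_classified", m)


def _plot_silhouette_profile(profile: SilhouetteProfile, outdir: Path, m: RunManifest):
    ks = profile.k_range
    avgs = [profile.average(k) for k in ks]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ks, avgs, "o-", color="0.2")
    ax.axvline(profile.optimal_k, color="#c62828", ls="--",
               label=f"optimal k = {profile.optimal_k}")
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("overall average silhouette width")
    ax.legend()
    _save(fig, outdir, "silhouette_profile", m)


def _plot_silhouette_widths(res: AnalysisResult, outdir: Path, m: RunManifest):
    w = res.clusterer.silhouette_widths_
    labels = res.clusterer.labels_
    order = np.lexsort((-w, labels))
    fig, ax = plt.subplots(figsize=(6, max(4, len(w) * 0.18)))
    palette = sns.color_palette("deep", int(labels.max()) + 1)
    ax.barh(np.arange(len(w)), w[order],
            color=[palette[labels[i]] for i in order])
    ax.set_yticks(np.arange(len(w)))
    ax.set_yticklabels([res.dist.labels[i] for i in order], fontsize=6)
    ax.set_xlabel("silhouette width")
    ax.invert_yaxis()
    _save(fig, outdir, "silhouette_widths", m)


def _plot_stacked_bar(res: AnalysisResult, outdir: Path, m: RunManifest):
    frag = res.fragmentation
    comps = list(frag.per_comparison)
    clusters = sorted({c for v in frag.per_comparison.values() for c in v})
    palette = sns.color_palette("deep", len(clusters))
    fig, ax = plt.subplots(figsize=(max(6, len(comps) * 0.6), 4))
    bottom = np.zeros(len(comps))
    for ci, c in enumerate(clusters):
        heights = np.array([frag.per_comparison[p].get(c, 0.0) for p in comps])
        ax.bar(comps, heights, bottom=bottom, color=palette[ci],
               label=f"cluster {c + 1}")
        bottom += heights
    ax.set_ylabel("% of studies")
    ax.legend(fontsize=7)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=7)
    ax.set_title(f"Cluster membership per comparison "
                 f"({len(frag.fragmented)} fragmented)")
    _save(fig, outdir, "fragmented_stacked_bar", m)


def _plot_cluster_distributions(res: AnalysisResult, outdir: Path, m: RunManifest):
    df = res.table.to_frame()
    df["cluster"] = res.clusterer.labels_ + 1
    specs = res.dataset.specs
    ncol = 3
    nrow = math.ceil(len(specs) / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow))
    for ax, spec in zip(np.ravel(axes), specs):
        if spec.is_quantitative:
            sns.violinplot(data=df, x="cluster", y=spec.name, ax=ax,
                           inner="point", density_norm="width")
        else:
            sub = (df.groupby(["cluster", spec.name], observed=True)
                   .size().reset_index(name="n"))
            sns.barplot(data=sub, x="cluster", y="n", hue=spec.name, ax=ax)
            ax.legend(fontsize=6)
        ax.set_title(spec.name, fontsize=8)
    for ax in np.ravel(axes)[len(specs):]:
        ax.set_axis_off()
    fig.tight_layout()
    _save(fig, outdir, "cluster_characteristic_distributions", m)


def summary_dict(res: AnalysisResult) -> dict:
    """JSON-serialisable summary of all numeric results (deterministic)."""
    prof = res.clusterer.silhouette_profile_
    return {
        "n_studies": res.dataset.n_studies,
        "n_characteristics": res.dataset.n_characteristics,
        "n_observations": res.table.n_rows,
        "comparisons": list(res.comparison_matrix.comparisons),
        "D_matrix": [[round(float(v), 10) for v in row]
                     for row in res.comparison_matrix.values],
        "threshold": res.threshold,
        "classification": [[str(l) for l in row] for row in res.classified.labels],
        "linkage": res.clusterer.linkage_,
        "ccc_by_method": {k: (None if not np.isfinite(v) else round(float(v), 10))
                          for k, v in sorted(res.clusterer.ccc_by_method_.items())},
        "optimal_k": prof.optimal_k,
        "n_clusters": int(res.clusterer.n_clusters_),
        "overall_average_silhouette_by_k": {
            str(k): round(prof.average(k), 10) for k in prof.k_range
        },
        "cluster_labels": [int(v) for v in res.clusterer.labels_],
        "fragmentation": res.fragmentation.to_dict(),
    }


def write_summary(res: AnalysisResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary_dict(res), fh, indent=2, sort_keys=True)
        fh.write("\n")


def render_report(res: AnalysisResult, outdir) -> RunManifest:
    """Write the full figure set and JSON summary into ``outdir``."""
    if res is None:
        raise ValueError("no analysis result to report; run the pipeline first")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(str(outdir), appendix_scale=res.dist.n > APPENDIX_SCALE_N)
    _plot_d_heatmap_dendrogram(res, outdir, manifest)
    _plot_classified_heatmap(res, outdir, manifest)
    _plot_silhouette_profile(res.clusterer.silhouette_profile_, outdir, manifest)
    _plot_silhouette_widths(res, outdir, manifest)
    _plot_stacked_bar(res, outdir, manifest)
    _plot_cluster_distributions(res, outdir, manifest)

    res.dist.to_csv(outdir / "d_matrix.csv")
    manifest.files["d_matrix_csv"] = str(outdir / "d_matrix.csv")
    res.comparison_matrix.to_csv(outdir / "D_matrix.csv")
    manifest.files["D_matrix_csv"] = str(outdir / "D_matrix.csv")
    res.classified.to_frame().to_csv(outdir / "classification.csv")
    manifest.files["classification_csv"] = str(outdir / "classification.csv")
    write_summary(res, outdir / "summary.json")
    manifest.files["summary_json"] = str(outdir / "summary.json")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
    manifest.files["manifest_json"] = str(outdir / "manifest.json")
    return manifest
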