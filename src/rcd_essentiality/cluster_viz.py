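"""Clustered fitness heatmaps and essentiality-frequency bar plots.

Hierarchical clustering (Euclidean distance, average linkage by default)
is applied to both genes and cell lines of a fitness matrix; heatmaps are
rendered with rows = genes and columns = cell lines. The testable artifact
of every plot is its sidecar TSV — the exact reordered values or bar data
— while image files are only smoke-checked, never pixel-compared.

Missing scores are mean-imputed per gene for distance computation only;
imputed values are never written to any output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .types import FitnessMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterLayout",
    "hierarchical_layout",
    "render_heatmap",
    "frequency_barplot",
]


@dataclass
class ClusterLayout:
    """Leaf orders and linkage trees for both axes of a fitness matrix."""

    gene_order: np.ndarray   # permutation of gene indices
    line_order: np.ndarray   # permutation of cell-line indices
    gene_linkage: np.ndarray
    line_linkage: np.ndarray
    metric: str
    method: str


def _imputed_values(matrix: FitnessMatrix) -> np.ndarray:
    """(line, gene) array with per-gene mean imputation of missing cells."""
    X = matrix.scores.to_numpy(dtype=float).copy()
    n_missing_lines = np.isnan(X).all(axis=1)
    if n_missing_lines.any():
        bad = np.asarray(matrix.cell_line_ids)[n_missing_lines].tolist()
        raise ValidationError(f"cell line(s) with all scores missing: {bad}")
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = np.asarray(matrix.gene_labels)[all_missing].tolist()
        raise ValidationError(f"gene(s) with all scores missing: {bad}")
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        rows, cols = np.nonzero(np.isnan(X))
        X[rows, cols] = col_means[cols]
        logger.info("mean-imputed %d missing cells for clustering only",
                    rows.size)
    return X


def hierarchical_layout(
    matrix: FitnessMatrix,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterLayout:
    """Cluster both axes of a fitness matrix.

    Deterministic for fixed input: scipy's linkage breaks distance ties by
    merging the pair with the lower original index first, and the leaf
    order is read off the resulting tree.
    """
    n_lines, n_genes = matrix.shape
    if n_genes < 2:
        raise ValidationError(f"clustering needs >= 2 genes, got {n_genes}")
    if n_lines < 2:
        raise ValidationError(f"clustering needs >= 2 cell lines, got {n_lines}")
    X = _imputed_values(matrix)
    gene_Z = linkage(pdist(X.T, metric=metric), method=method)
    line_Z = linkage(pdist(X, metric=metric), method=method)
    return ClusterLayout(
        gene_order=np.asarray(leaves_list(gene_Z)),
        line_order=np.asarray(leaves_list(line_Z)),
        gene_linkage=gene_Z,
        line_linkage=line_Z,
        metric=metric,
        method=method,
    )


def _reordered(matrix: FitnessMatrix, layout: ClusterLayout) -> pd.DataFrame:
    """Genes x cell lines frame under the layout permutations (rows = genes)."""
    scores = matrix.scores
    return scores.iloc[layout.line_order, layout.gene_order].T


def _write_sidecar(df: pd.DataFrame, path: Path, index_label: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=True, index_label=index_label,
                  lineterminator="\n")


def render_heatmap(
    matrix: FitnessMatrix,
    layout: ClusterLayout,
    out_path: str | Path,
    *,
    write_image: bool = True,
) -> dict[str, Path]:
    """Render the clustered heatmap and write its sidecar TSV.

    The sidecar (``<out_path stem>.tsv``) carries the exact reordered
    scores, rows = genes, columns = cell lines. The colour scale defaults
    to symmetric around 0 covering the data range. With
    ``write_image=False`` only the sidecar is written.
    """
    out_path = Path(out_path)
    reordered = _reordered(matrix, layout)
    sidecar = out_path.with_suffix(".tsv")
    _write_sidecar(reordered, sidecar, index_label="gene")
    paths = {"sidecar": sidecar}
    if write_image:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        data = reordered.to_numpy(dtype=float)
        vmax = float(np.nanmax(np.abs(data))) or 1.0
        fig, ax = plt.subplots(
            figsize=(max(4.0, min(12.0, data.shape[1] / 40)),
                     max(3.0, min(10.0, data.shape[0] / 8))))
        im = ax.imshow(data, aspect="auto", cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax, interpolation="nearest")
        ax.set_xlabel("cell lines (clustered)")
        ax.set_ylabel("genes (clustered)")
        ax.set_yticks(range(len(reordered.index)) if len(reordered.index) <= 60
                      else [])
        if len(reordered.index) <= 60:
            ax.set_yticklabels(reordered.index, fontsize=6)
        ax.set_xticks([])
        fig.colorbar(im, ax=ax, label="gene fitness effect score")
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        paths["image"] = out_path
    return paths


_CATEGORY_COLORS = {
    "always_essential": "#b2182b",
    "partially_essential": "#ef8a62",
    "rarely_essential": "#67a9cf",
}


def frequency_barplot(
    classification: pd.DataFrame,
    pathway: str,
    gene_sets: GeneSetCollection,
    out_path: str | Path,
    *,
    write_image: bool = True,
) -> dict[str, Path]:
    """Per-gene essentiality-frequency bars for one pathway.

    Bars sort by frequency descending, ties broken by gene symbol
    ascending; the category is colour-encoded. The sidecar TSV
    (gene, frequency, category) is the acceptance surface.
    """
    out_path = Path(out_path)
    if pathway not in gene_sets:
        raise ValidationError(f"unknown pathway {pathway!r}")
    members = set(gene_sets.genes(pathway))
    sub = classification[classification["gene_symbol"].isin(members)]
    if sub.empty:
        raise ValidationError(
            f"pathway {pathway!r} has no genes in the classification")
    sub = sub.sort_values(["frequency", "gene_symbol"],
                          ascending=[False, True]).reset_index(drop=True)
    sidecar = out_path.with_suffix(".tsv")
    with open(sidecar, "w", encoding="utf-8", newline="\n") as fh:
        sub[["gene_symbol", "frequency", "category"]].to_csv(
            fh, sep="\t", index=False, lineterminator="\n")
    paths = {"sidecar": sidecar}
    if write_image:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4.0, min(16.0, len(sub) / 6)), 3.5))
        colors = [_CATEGORY_COLORS.get(c, "#999999") for c in sub["category"]]
        ax.bar(range(len(sub)), sub["frequency"], color=colors, width=0.8)
        ax.axhline(0.9, color="k", lw=0.6, ls="--")
        ax.axhline(0.1, color="k", lw=0.6, ls="--")
        ax.set_ylim(0, 1)
        ax.set_ylabel("essentiality frequency")
        ax.set_title(pathway)
        if len(sub) <= 60:
            ax.set_xticks(range(len(sub)))
            ax.set_xticklabels(sub["gene_symbol"], rotation=90, fontsize=6)
        else:
            ax.set_xticks([])
        fig.tight_layout()
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        paths["image"] = out_path
    return paths
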