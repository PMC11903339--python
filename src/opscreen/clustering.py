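"""Correlation matrices, Ward ordering and diagonally merged heatmaps.

Cross-screen comparison of perturbation profiles: pairwise Pearson
correlation matrices of (PCA-reduced) gene profiles are ordered by the
leaf order of a Ward-linkage tree built on Euclidean distances between
correlation-matrix rows, and two screens sharing a gene set are merged
into a single square matrix — the lower triangle showing one screen's
correlations, the upper triangle the other's, both in the order derived
from a single screen so block structure can be compared by eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering

from .profiles import ProfileTable


def correlation_matrix(gene_profiles: ProfileTable) -> pd.DataFrame:
    """Symmetric gene-by-gene Pearson correlation matrix with unit
    diagonal."""
    frame = gene_profiles.frame
    genes = frame["Metadata_gene"].tolist()
    if len(genes) < 2:
        raise ValueError("need at least 2 gene profiles")
    X = frame[gene_profiles.features].to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = [g for g, s in zip(genes, sd) if s == 0.0]
    if flat:
        raise ValueError(f"zero-variance profile for gene(s) {flat[:5]}")
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


def ward_order(
    corr: pd.DataFrame | ProfileTable, optimal: bool = False
) -> list[str]:
    """Leaf order of the Ward variance-minimization tree on Euclidean
    distances between correlation-matrix rows.

    Deterministic for fixed input (ties broken by input order via the
    agglomeration bookkeeping); optionally applies optimal leaf
    ordering.
    """
    if isinstance(corr, ProfileTable):
        corr = correlation_matrix(corr)
    X = corr.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("correlation matrix contains non-finite values")
    if len(corr) == 2:
        return list(corr.index)
    Z = linkage(X, method="ward", metric="euclidean")
    if optimal:
        Z = optimal_leaf_ordering(Z, X)
    return [corr.index[i] for i in leaves_list(Z)]


@dataclass
class MergedHeatmap:
    """Two screens' correlations in one square matrix sharing one gene
    order: lower triangle = screen A, upper triangle = screen B,
    diagonal = 1."""

    order: list[str]
    matrix: pd.DataFrame
    order_from: str

    def triangle(self, which: str) -> pd.DataFrame:
        """Reconstruct one screen's full symmetric correlation matrix on
        the shared genes."""
        M = self.matrix.to_numpy(dtype=float)
        if which == "A":
            tri = np.tril(M, k=-1)
        elif which == "B":
            tri = np.triu(M, k=1)
        else:
            raise ValueError("which must be 'A' or 'B'")
        full = tri + tri.T
        np.fill_diagonal(full, 1.0)
        return pd.DataFrame(full, index=self.order, columns=self.order)


def diagonal_merge(
    corr_a: pd.DataFrame, corr_b: pd.DataFrame, order_from: str = "A"
) -> MergedHeatmap:
    """Merge two correlation matrices into a diagonally split heatmap.

    Genes are restricted to the intersection of both screens' gene sets;
    the row/column order comes from the Ward ordering of the chosen
    screen's restricted matrix and is applied to both.
    """
    shared = [g for g in corr_a.index if g in set(corr_b.index)]
    if not shared:
        raise ValueError("screens share no genes")
    sub_a = corr_a.loc[shared, shared]
    sub_b = corr_b.loc[shared, shared]
    if order_from == "A":
        order = ward_order(sub_a) if len(shared) >= 2 else shared
    elif order_from == "B":
        order = ward_order(sub_b) if len(shared) >= 2 else shared
    else:
        raise ValueError("order_from must be 'A' or 'B'")
    A = sub_a.loc[order, order].to_numpy(dtype=float)
    B = sub_b.loc[order, order].to_numpy(dtype=float)
    merged = np.tril(A, k=-1) + np.triu(B, k=1)
    np.fill_diagonal(merged, 1.0)
    return MergedHeatmap(
        order=order,
        matrix=pd.DataFrame(merged, index=order, columns=order),
        order_from=order_from,
    )


def plot_merged_heatmap(merged: MergedHeatmap, path: str) -> None:
    """Render a merged heatmap to file (diverging colormap over
    [-1, 1])."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(merged.matrix.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_xlabel(f"order from screen {merged.order_from}")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
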