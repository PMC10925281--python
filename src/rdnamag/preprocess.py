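"""Cell QC, normalization, embedding, graph clustering and annotation.

The stages mirror a standard droplet single-cell workflow: cells are kept
when their library size and detected-gene count fall inside inclusive QC
windows; counts are scaled per cell to a common target (median library size
by default) and log1p-transformed; the top variable genes are standardized
and projected onto principal components; a k-nearest-neighbour graph on the
embedding is partitioned by resolution-parameterized modularity (Leiden);
and clusters are labelled by marker-panel positivity.

Each stage is an estimator in the scikit-learn idiom (constructor
parameters, ``fit``/``transform``, fitted attributes with a trailing
underscore); the module-level functions are thin one-shot wrappers.
"""

from __future__ import annotations

import logging

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .config import AnalysisParams, MarkerPanel, QCParams
from .containers import GeneExpressionMatrix, ValidationError

logger = logging.getLogger("rdnamag")


# ---------------------------------------------------------------------------
# QC


class CellQC(BaseEstimator):
    """Filter cells on inclusive total-count and detected-feature windows."""

    def __init__(self, min_counts=5500, max_counts=250000, min_features=200, max_features=9000):
        self.min_counts = min_counts
        self.max_counts = max_counts
        self.min_features = min_features
        self.max_features = max_features

    def fit(self, X: GeneExpressionMatrix, y=None):
        totals = X.counts_per_cell()
        features = X.features_per_cell()
        mask = (
            (totals >= self.min_counts)
            & (totals <= self.max_counts)
            & (features >= self.min_features)
            & (features <= self.max_features)
        )
        self.mask_ = mask
        self.kept_barcodes_ = [b for b, m in zip(X.cell_barcodes, mask) if m]
        self.n_removed_ = int((~mask).sum())
        return self

    def transform(self, X: GeneExpressionMatrix) -> GeneExpressionMatrix:
        self.fit(X)
        if not self.kept_barcodes_:
            logger.warning("QC removed every cell (%d input cells)", X.n_cells)
        return X.subset_cells(self.kept_barcodes_)


def qc_filter_cells(matrix: GeneExpressionMatrix, params: QCParams = None) -> GeneExpressionMatrix:
    """Keep cells with min_counts <= total <= max_counts and
    min_features <= detected genes <= max_features (bounds inclusive)."""
    params = params or QCParams()
    params.validate()
    return CellQC(params.min_counts, params.max_counts,
                  params.min_features, params.max_features).transform(matrix)


# ---------------------------------------------------------------------------
# normalization


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Scale each cell to a common total, then log1p.

    ``target=None`` uses the median library size of the fitted matrix.
    Zeros map to zeros, so the sparsity pattern is preserved.
    """

    def __init__(self, target=None):
        self.target = target

    def fit(self, X: GeneExpressionMatrix, y=None):
        totals = X.counts_per_cell()
        if (totals == 0).any():
            raise ValidationError("cannot normalize: cell(s) with zero total counts")
        self.target_ = float(self.target) if self.target else float(np.median(totals))
        return self

    def transform(self, X: GeneExpressionMatrix) -> sp.csr_matrix:
        totals = X.counts_per_cell()
        if (totals == 0).any():
            raise ValidationError("cannot normalize: cell(s) with zero total counts")
        scale = self.target_ / totals
        norm = sp.csr_matrix(X.counts.astype(float).multiply(scale[None, :]))
        norm.data = np.log1p(norm.data)
        return norm


def normalize_log(matrix: GeneExpressionMatrix, target: float = None) -> sp.csr_matrix:
    """Median-library (or explicit-target) scaling followed by log1p.

    Returns a sparse float matrix aligned with the input's gene/cell order.
    """
    return LogNormalizer(target=target).fit(matrix).transform(matrix)


# ---------------------------------------------------------------------------
# embedding


class PCAEmbedder(BaseEstimator, TransformerMixin):
    """Standardized variable-gene PCA embedding of cells.

    Selects the ``n_variable_genes`` most variable genes of the normalized
    matrix, standardizes each gene, and projects cells onto the top
    ``n_components`` principal axes. Deterministic for a fixed ``seed``.
    """

    def __init__(self, n_components=14, n_variable_genes=2000, seed=0):
        self.n_components = n_components
        self.n_variable_genes = n_variable_genes
        self.seed = seed

    def fit(self, X: sp.spmatrix, y=None):
        X = sp.csr_matrix(X)
        n_genes, n_cells = X.shape
        if n_cells < self.n_components:
            raise ValidationError(
                f"need at least n_components={self.n_components} cells, got {n_cells}"
            )
        mean = np.asarray(X.mean(axis=1)).ravel()
        sq = np.asarray(X.power(2).mean(axis=1)).ravel()
        var = np.maximum(sq - mean**2, 0.0)
        n_var = min(self.n_variable_genes, n_genes)
        self.variable_genes_ = np.sort(np.argsort(var)[::-1][:n_var])
        self.mean_ = mean[self.variable_genes_]
        std = np.sqrt(var[self.variable_genes_])
        self.scale_ = np.where(std > 0, std, 1.0)
        dense = np.asarray(X[self.variable_genes_].todense()).T  # cells x genes
        dense = (dense - self.mean_) / self.scale_
        self.pca_ = PCA(
            n_components=min(self.n_components, min(dense.shape)),
            svd_solver="randomized",
            random_state=self.seed,
        ).fit(dense)
        return self

    def transform(self, X: sp.spmatrix) -> np.ndarray:
        dense = np.asarray(sp.csr_matrix(X)[self.variable_genes_].todense()).T
        dense = (dense - self.mean_) / self.scale_
        return self.pca_.transform(dense)


def embed_cells(normalized: sp.spmatrix, params: AnalysisParams = None, seed: int = 0) -> np.ndarray:
    """Cells x n_components principal-component embedding."""
    params = params or AnalysisParams()
    params.validate()
    emb = PCAEmbedder(params.n_components, params.n_variable_genes, seed=seed)
    return emb.fit(normalized).transform(normalized)


# ---------------------------------------------------------------------------
# clustering


class GraphClusterer(BaseEstimator, ClusterMixin):
    """Leiden community detection on a kNN graph of the embedding.

    The partition optimizes resolution-parameterized modularity
    (RBConfiguration), so larger ``resolution`` yields more communities.
    """

    def __init__(self, n_neighbors=20, resolution=0.5, seed=0):
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.seed = seed

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        n_cells = X.shape[0]
        if self.n_neighbors >= n_cells:
            raise ValidationError(
                f"n_neighbors={self.n_neighbors} must be < number of cells ({n_cells})"
            )
        adj = kneighbors_graph(X, self.n_neighbors, mode="connectivity", include_self=False)
        adj = adj.maximum(adj.T).tocoo()
        edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
        graph = ig.Graph(n=n_cells, edges=edges)
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=self.resolution,
            seed=abs(int(self.seed)) % (2**31 - 1),
            n_iterations=2,
        )
        membership = np.asarray(part.membership)
        # contiguous ids ordered by first occurrence for determinism
        remap, labels = {}, np.empty_like(membership)
        for i, m in enumerate(membership):
            if m not in remap:
                remap[m] = len(remap)
            labels[i] = remap[m]
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_cells(embedding: np.ndarray, params: AnalysisParams = None, seed: int = 0) -> np.ndarray:
    """Cluster ids (contiguous from 0), one per embedded cell."""
    params = params or AnalysisParams()
    params.validate()
    return GraphClusterer(params.n_neighbors, params.resolution, seed=seed).fit_predict(embedding)


# ---------------------------------------------------------------------------
# annotation


def marker_positive_fractions(matrix: GeneExpressionMatrix, cell_idx: np.ndarray,
                              genes, threshold: int = 1) -> dict:
    """Fraction of the given cells with raw count >= threshold per gene."""
    out = {}
    for g in genes:
        counts = matrix.gene_counts(g)[cell_idx]
        out[g] = float((counts >= threshold).mean())
    return out


def annotate_clusters(matrix: GeneExpressionMatrix, clusters: np.ndarray,
                      panel: MarkerPanel = None) -> pd.DataFrame:
    """Label each cluster by marker-panel positivity.

    A cluster's score for a panel is the mean, over the panel's markers, of
    the fraction of cluster cells positive for the marker. The cluster takes
    the top-scoring label when the score reaches ``predominance_fraction``;
    otherwise it falls back to the strongest score outright. Clusters
    predominant for both the germline (GSC&SG) and Cyst panels are flagged
    ``mixed`` (suspected doublets). Ties break to the lexicographically
    smallest label.

    Returns a DataFrame indexed by cluster id with ``label``, ``mixed``,
    ``predominant`` and one ``score_<panel>`` column per panel.
    """
    panel = panel or MarkerPanel()
    panel.validate()
    clusters = np.asarray(clusters)
    if len(clusters) != matrix.n_cells:
        raise ValidationError("cluster assignment length must equal number of cells")
    for label, genes in panel.panels.items():
        for g in genes:
            if g not in matrix.gene_ids:
                raise ValidationError(f"marker gene {g!r} (panel {label!r}) absent from matrix")

    rows = []
    for cid in sorted(set(clusters.tolist())):
        idx = np.flatnonzero(clusters == cid)
        scores = {}
        for label, genes in panel.panels.items():
            fr = marker_positive_fractions(matrix, idx, genes, panel.positivity_threshold)
            scores[label] = float(np.mean(list(fr.values())))
        best = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        predominant = best[1] >= panel.predominance_fraction
        mixed = (
            scores.get("GSC&SG", 0.0) >= panel.predominance_fraction
            and scores.get("Cyst", 0.0) >= panel.predominance_fraction
        )
        row = {"cluster": cid, "label": best[0], "predominant": bool(predominant),
               "mixed": bool(mixed), "n_cells": int(len(idx))}
        row.update({f"score_{k}": v for k, v in scores.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")
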