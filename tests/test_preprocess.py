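"""QC windows, normalization, embedding, graph clustering, annotation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from rdnamag import (
    AnalysisParams,
    MarkerPanel,
    QCParams,
    ValidationError,
    annotate_clusters,
    cluster_cells,
    embed_cells,
    normalize_log,
    qc_filter_cells,
)
from conftest import small_matrix


def matrix_with_totals(specs):
    """Build cells with exact (total counts, feature counts) from specs."""
    n_genes = max(f for _, f in specs) + 1
    cols = []
    for total, features in specs:
        col = np.zeros(n_genes, dtype=int)
        base, extra = divmod(total - features + 1, 1)
        col[: features - 1] = 1
        col[features - 1] = total - (features - 1)
        assert col.sum() == total and (col > 0).sum() == features
        cols.append(col)
    return small_matrix(np.stack(cols, axis=1))


class TestQC:
    def test_boundary_cells_inclusive(self):
        m = matrix_with_totals([(5500, 300), (100, 50)])
        kept = qc_filter_cells(m)
        assert kept.cell_barcodes == ["c1"]

    def test_enumerated_window_fixture(self):
        """Eight cells against both windows: exactly the three inside
        [5500, 250000] counts x [200, 9000] features survive."""
        specs = [
            (100, 50),        # below both
            (5499, 300),      # counts one short
            (5500, 300),      # at lower count bound -> kept
            (10000, 150),     # features too few
            (10000, 500),     # inside -> kept
            (260000, 5000),   # counts too high
            (250000, 9000),   # at both upper bounds -> kept
            (250001, 9001),   # features (and counts) above
        ]
        m = matrix_with_totals(specs)
        kept = qc_filter_cells(m)
        assert kept.cell_barcodes == ["c3", "c5", "c7"]

    def test_idempotent(self, default_experiment):
        matrix, _ = default_experiment
        once = qc_filter_cells(matrix)
        twice = qc_filter_cells(once)
        assert once.equals(twice)

    def test_metadata_carried_over(self):
        meta = pd.DataFrame({"condition": ["low_rDNA", "normal_rDNA"]}, index=["c1", "c2"])
        m = matrix_with_totals([(6000, 300), (100, 50)])
        m = small_matrix(np.asarray(m.counts.todense()), meta=meta)
        kept = qc_filter_cells(m)
        assert list(kept.cell_meta["condition"]) == ["low_rDNA"]


class TestNormalizeLog:
    def test_closed_form(self):
        """Cell [10, 30] scaled to target 40 gives [ln 11, ln 31]."""
        m = small_matrix([[10], [30]])
        norm = np.asarray(normalize_log(m, target=40).todense()).ravel()
        assert norm == pytest.approx([np.log(11), np.log(31)])

    def test_proportional_cells_identical(self):
        m = small_matrix([[10, 30], [20, 60], [0, 0]])
        norm = np.asarray(normalize_log(m).todense())
        assert norm[:, 0] == pytest.approx(norm[:, 1])
        assert (norm[2] == 0).all()  # all-zero gene stays zero

    def test_preserves_zero_pattern(self, default_experiment):
        matrix, _ = default_experiment
        sub = matrix.subset_cells(matrix.cell_barcodes[:200])
        norm = normalize_log(sub)
        assert (norm.todense() != 0).sum() == sub.counts.nnz

    def test_zero_total_cell_rejected(self):
        m = small_matrix([[1, 0], [2, 0]])
        with pytest.raises(ValidationError, match="zero total"):
            normalize_log(m)


class TestEmbedCells:
    def test_duplicate_cells_identical_rows(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(3.0, size=(50, 30)).astype(float)
        X = sp.csr_matrix(np.concatenate([base, base[:, :1]], axis=1))
        emb = embed_cells(X, AnalysisParams(n_components=5, n_neighbors=5))
        assert emb[-1] == pytest.approx(emb[0])

    def test_planar_data_has_rank_two(self):
        """Points on a 2-D plane leave no variance for components >= 3."""
        rng = np.random.default_rng(1)
        loadings = rng.integers(0, 4, size=(20, 2))
        coords = rng.integers(0, 6, size=(2, 100))
        plane = loadings @ coords  # integer counts of exact rank 2
        emb = embed_cells(sp.csr_matrix(plane),
                          AnalysisParams(n_components=6, n_variable_genes=20))
        var = emb.var(axis=0)
        assert var[2:].max() < 1e-6 * max(var[0], 1e-12)

    def test_separates_planted_programs(self):
        """Three synthetic programs: within-type embedding distances are
        smaller than between-type distances."""
        rng = np.random.default_rng(2)
        means = np.full((60, 3), 1.0)
        for t in range(3):
            means[t * 20:(t + 1) * 20, t] = 20.0
        X = rng.poisson(np.repeat(means, 40, axis=1))
        labels = np.repeat(np.arange(3), 40)
        emb = embed_cells(sp.csr_matrix(X), AnalysisParams(n_components=5))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(emb))
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        assert D[same & off_diag].mean() < D[~same].mean()

    def test_too_few_cells_rejected(self):
        X = sp.csr_matrix(np.ones((10, 3)))
        with pytest.raises(ValidationError, match="n_components"):
            embed_cells(X, AnalysisParams(n_components=5))


class TestClusterCells:
    def two_blob_embedding(self, seed=0, n=100, sep=10.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=(n, 3))
        b = rng.normal(0.0, 1.0, size=(n, 3)) + sep * np.sqrt(3)
        return np.concatenate([a, b])

    def test_two_separated_blobs_two_communities(self):
        emb = self.two_blob_embedding()
        labels = cluster_cells(emb, AnalysisParams(n_neighbors=15, resolution=0.5))
        assert len(set(labels.tolist())) == 2
        assert len(set(labels[:100].tolist())) == 1 and len(set(labels[100:].tolist())) == 1

    def test_single_cloud_one_community_at_low_resolution(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(200, 3))
        labels = cluster_cells(emb, AnalysisParams(n_neighbors=15, resolution=0.1))
        assert len(set(labels.tolist())) == 1

    def test_permutation_invariant_up_to_relabeling(self):
        emb = self.two_blob_embedding(seed=4)
        labels = cluster_cells(emb, AnalysisParams(n_neighbors=15))
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(emb))
        labels_perm = cluster_cells(emb[perm], AnalysisParams(n_neighbors=15))
        assert adjusted_rand_score(labels[perm], labels_perm) == 1.0

    def test_too_many_neighbors_rejected(self):
        with pytest.raises(ValidationError, match="n_neighbors"):
            cluster_cells(np.zeros((10, 2)), AnalysisParams(n_neighbors=10))


class TestAnnotateClusters:
    def panel(self):
        return MarkerPanel(panels={"GSC&SG": ("vas", "nos", "ovo"),
                                   "Cyst": ("tj", "zfh1")})

    def build(self, gsc_frac, cyst_frac, n=100, seed=0):
        """One cluster with given marker-positive fractions."""
        rng = np.random.default_rng(seed)
        genes = ["vas", "nos", "ovo", "tj", "zfh1"]
        counts = np.zeros((5, n), dtype=int)
        for i in range(3):
            counts[i, : int(gsc_frac * n)] = 1 + rng.poisson(2, int(gsc_frac * n))
        for i in (3, 4):
            counts[i, : int(cyst_frac * n)] = 1
        import scipy.sparse as sp
        from rdnamag import GeneExpressionMatrix
        return GeneExpressionMatrix(genes, [f"c{j}" for j in range(n)], sp.csr_matrix(counts))

    def test_clear_germline_cluster(self):
        m = self.build(0.9, 0.04)
        ann = annotate_clusters(m, np.zeros(100, dtype=int), self.panel())
        assert ann.loc[0, "label"] == "GSC&SG" and not ann.loc[0, "mixed"]

    def test_double_positive_cluster_flagged_mixed(self):
        m = self.build(0.8, 0.8)
        ann = annotate_clusters(m, np.zeros(100, dtype=int), self.panel())
        assert bool(ann.loc[0, "mixed"])

    def test_fallback_to_strongest_score(self):
        """Below predominance everywhere, the best score still labels."""
        m = self.build(0.3, 0.1)
        ann = annotate_clusters(m, np.zeros(100, dtype=int), self.panel())
        assert ann.loc[0, "label"] == "GSC&SG" and not ann.loc[0, "predominant"]

    def test_missing_marker_gene_named(self):
        m = small_matrix(np.ones((3, 4), dtype=int))
        with pytest.raises(ValidationError, match="vas"):
            annotate_clusters(m, np.zeros(4, dtype=int), self.panel())

    def test_labels_match_majority_truth_on_experiment(self, default_experiment, pipeline_result):
        """Every non-doublet cluster's label equals its majority true type
        (at the marker panel's GSC&SG resolution)."""
        _, truth = default_experiment
        res = pipeline_result
        cells = truth.cells.loc[res.matrix.cell_barcodes]
        coarse = cells["cell_type"].replace(
            {"GSC": "GSC&SG", "SG": "GSC&SG", "cyst": "Cyst"}
        ).to_numpy()
        for cid, row in res.annotation.iterrows():
            idx = np.flatnonzero(res.clusters == cid)
            majority = pd.Series(coarse[idx]).mode()[0]
            if majority == "doublet" or row["mixed"]:
                continue
            assert row["label"] == majority
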