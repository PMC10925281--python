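"""End-to-end discovery pipeline.

QC -> normalize -> embed -> cluster -> annotate -> dual GSC selection ->
four DE analyses (GSC by each selection, spermatogonia, somatic Cyst cells;
low vs normal rDNA copy number) -> intersection -> ambient-artifact filter
-> SG-specificity filter -> candidate table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidates import build_candidate_table
from .config import PipelineConfig
from .containers import CONDITIONS, LOW_RDNA, NORMAL_RDNA, GeneExpressionMatrix, ValidationError
from .de import differential_expression
from .preprocess import annotate_clusters, cluster_cells, embed_cells, normalize_log, qc_filter_cells
from .selection import select_gsc_by_markers, select_gsc_by_subclustering

logger = logging.getLogger("rdnamag")


@dataclass
class PipelineResult:
    matrix: GeneExpressionMatrix           # QC-filtered
    clusters: np.ndarray
    annotation: pd.DataFrame
    gsc_cluster: object                    # CellSelection (cluster-based)
    gsc_expression: object                 # CellSelection (expression-based)
    sg: object                             # CellSelection (SG from sub-clustering)
    de_cluster: pd.DataFrame
    de_expression: pd.DataFrame
    de_sg: pd.DataFrame
    de_somatic: pd.DataFrame
    candidates: pd.DataFrame
    subcluster_calls: dict = field(default_factory=dict)

    @property
    def final_candidates(self) -> set:
        if self.candidates.empty:
            return set()
        return set(self.candidates.loc[self.candidates["final_candidate"], "gene"])


def _split_by_condition(matrix: GeneExpressionMatrix, barcodes) -> tuple:
    cond = matrix.cell_meta["condition"]
    barcodes = [b for b in matrix.cell_barcodes if b in set(barcodes)]
    low = [b for b in barcodes if cond[b] == LOW_RDNA]
    normal = [b for b in barcodes if cond[b] == NORMAL_RDNA]
    if not low or not normal:
        raise ValidationError("selected cell set lacks one of the conditions")
    return low, normal


def run_discovery(matrix: GeneExpressionMatrix, config: PipelineConfig = None) -> PipelineResult:
    """Run the full candidate-discovery cascade on a labelled count matrix.

    ``matrix.cell_meta`` must carry a ``condition`` column with values
    ``low_rDNA`` / ``normal_rDNA``. Deterministic for a fixed config seed.
    """
    config = (config or PipelineConfig()).validate()
    if "condition" not in matrix.cell_meta.columns:
        raise ValidationError("cell_meta must contain a 'condition' column")
    unknown = set(matrix.cell_meta["condition"].dropna()) - set(CONDITIONS)
    if unknown:
        raise ValidationError(f"unknown condition labels: {sorted(unknown)}")
    seed = config.seed

    qc = qc_filter_cells(matrix, config.qc)
    logger.info("QC: %d/%d cells retained", qc.n_cells, matrix.n_cells)

    normalized = normalize_log(qc, target=config.analysis.normalization_target)
    embedding = embed_cells(normalized, config.analysis, seed=seed)
    clusters = cluster_cells(embedding, config.analysis, seed=seed)
    annotation = annotate_clusters(qc, clusters, config.markers)
    logger.info("clustering: %d clusters\n%s", len(annotation),
                annotation[["label", "mixed", "n_cells"]])

    gsc_cluster, sg, calls = select_gsc_by_subclustering(
        qc, clusters, annotation, config.analysis, config.markers, seed=seed
    )
    gsc_expression = select_gsc_by_markers(qc, config.markers)
    logger.info("GSC selections: cluster-based %d, expression-based %d, SG %d",
                len(gsc_cluster.barcodes), len(gsc_expression.barcodes), len(sg.barcodes))

    cyst_clusters = {cid for cid, row in annotation.iterrows()
                     if row["label"] == "Cyst" and not row["mixed"]}
    somatic_barcodes = [b for b, c in zip(qc.cell_barcodes, clusters) if c in cyst_clusters]
    if not somatic_barcodes:
        raise ValidationError("no Cyst-labelled cells for the ambient filter")

    def _de(barcodes):
        low, normal = _split_by_condition(qc, barcodes)
        return differential_expression(qc, low, normal, config.de, normalized=normalized)

    de_cluster = _de(gsc_cluster.barcodes)
    de_expression = _de(gsc_expression.barcodes)
    de_sg = _de(sg.barcodes)
    de_somatic = _de(somatic_barcodes)

    cand = build_candidate_table(de_cluster, de_expression, de_somatic, de_sg)
    logger.info("candidates: %d intersecting, %d final",
                len(cand), int(cand["final_candidate"].sum()) if len(cand) else 0)
    return PipelineResult(
        matrix=qc, clusters=clusters, annotation=annotation,
        gsc_cluster=gsc_cluster, gsc_expression=gsc_expression, sg=sg,
        de_cluster=de_cluster, de_expression=de_expression,
        de_sg=de_sg, de_somatic=de_somatic,
        candidates=cand, subcluster_calls=calls,
    )


def precision_recall(predicted: set, truth: set) -> dict:
    """Set precision/recall of discovered genes against planted truth."""
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    return {
        "precision": tp / len(predicted) if predicted else 0.0,
        "recall": tp / len(truth) if truth else 0.0,
        "n_predicted": len(predicted),
        "n_truth": len(truth),
        "n_true_positive": tp,
    }
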