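"""Germline stem cell selection by two complementary methods.

Male GSCs sit at the top of the spermatogenesis lineage and are the only
germ cells that carry out rDNA copy-number expansion, so the differential
expression analysis must isolate them cleanly. Two methods are used:

* **cluster-based** — cells from GSC&SG-labelled clusters plus one Cyst
  outgroup cluster are re-normalized, re-embedded and re-clustered with the
  same analysis parameters; subclusters rich in nos/vas/ovo-positive cells
  are GSC, vas-positive but nos/ovo-depleted subclusters are SG, and
  subclusters positive for both germline and Cyst panels are excluded as
  mixed (suspected GSC:cyst doublets). This captures cells whose overall
  transcriptome is GSC-like even when a given marker dropped out.
* **expression-based** — cells from any cluster with raw-count-positive
  vas, nos and ovo but zero tj and zfh1. This captures GSCs whose profile
  failed to co-cluster, at the price of stringency.

The SG set from sub-clustering feeds the downstream SG-specificity filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisParams, MarkerPanel
from .containers import GeneExpressionMatrix, ValidationError
from .preprocess import (
    GraphClusterer,
    PCAEmbedder,
    marker_positive_fractions,
    normalize_log,
)

logger = logging.getLogger("rdnamag")


@dataclass
class CellSelection:
    """A selected cell set with per-barcode provenance."""

    method: str  # "cluster_based" | "expression_based"
    barcodes: set
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in ("cluster_based", "expression_based"):
            raise ValidationError(f"unknown selection method {self.method!r}")
        self.barcodes = set(self.barcodes)


def select_gsc_by_markers(matrix: GeneExpressionMatrix, panel: MarkerPanel = None) -> CellSelection:
    """Expression-based selection: positive vas/nos/ovo, zero tj/zfh1.

    Positivity is raw count >= ``positivity_threshold``; "negative" is a raw
    count of exactly zero. Independent of any clustering.
    """
    panel = panel or MarkerPanel()
    panel.validate()
    for g in panel.gsc_positive + panel.gsc_negative:
        if g not in matrix.gene_ids:
            raise ValidationError(f"marker gene {g!r} absent from matrix")
    keep = np.ones(matrix.n_cells, dtype=bool)
    for g in panel.gsc_positive:
        keep &= matrix.gene_counts(g) >= panel.positivity_threshold
    for g in panel.gsc_negative:
        keep &= matrix.gene_counts(g) == 0
    barcodes = {b for b, k in zip(matrix.cell_barcodes, keep) if k}
    reason = (
        f"count>={panel.positivity_threshold} for {'/'.join(panel.gsc_positive)}; "
        f"count==0 for {'/'.join(panel.gsc_negative)}"
    )
    return CellSelection("expression_based", barcodes, {b: reason for b in barcodes})


def classify_subclusters(matrix: GeneExpressionMatrix, cell_idx_by_subcluster: dict,
                         panel: MarkerPanel) -> dict:
    """Call each subcluster GSC / SG / Cyst / mixed / unassigned.

    GSC: mean positive fraction of nos and ovo >= ``gsc_concentration_min``.
    SG: vas-positive fraction >= predominance but nos/ovo mean positive
    fraction < ``sg_depletion_max`` (vas-positive, nos/ovo-devoid).
    Mixed: germline-positive (GSC or SG call) while the Cyst panel is also
    predominant — excluded as suspected doublets.
    """
    calls = {}
    cyst_markers = panel.panels.get("Cyst", ("dlg1", "CadN", "tj", "zfh1"))
    for sid, idx in cell_idx_by_subcluster.items():
        fr = marker_positive_fractions(matrix, idx, ("vas", "nos", "ovo"),
                                       panel.positivity_threshold)
        cyst_fr = marker_positive_fractions(matrix, idx, cyst_markers,
                                            panel.positivity_threshold)
        cyst_score = float(np.mean(list(cyst_fr.values())))
        nos_ovo = (fr["nos"] + fr["ovo"]) / 2.0
        germline = None
        if nos_ovo >= panel.gsc_concentration_min:
            germline = "GSC"
        elif fr["vas"] >= panel.predominance_fraction and nos_ovo < panel.sg_depletion_max:
            germline = "SG"
        if germline and cyst_score >= panel.predominance_fraction:
            calls[sid] = "mixed"
        elif germline:
            calls[sid] = germline
        elif cyst_score >= panel.predominance_fraction:
            calls[sid] = "Cyst"
        else:
            calls[sid] = "unassigned"
    return calls


def select_gsc_by_subclustering(matrix: GeneExpressionMatrix, clusters: np.ndarray,
                                annotation, params: AnalysisParams = None,
                                panel: MarkerPanel = None, seed: int = 0):
    """Cluster-based selection via sub-clustering with a Cyst outgroup.

    ``clusters`` is the full-data cluster id per cell and ``annotation`` the
    table from :func:`rdnamag.preprocess.annotate_clusters`. Returns
    ``(gsc_selection, sg_selection, subcluster_calls)``.
    """
    params = params or AnalysisParams()
    panel = panel or MarkerPanel()
    params.validate()
    panel.validate()
    clusters = np.asarray(clusters)

    germ_ids = [cid for cid, row in annotation.iterrows()
                if row["label"] == "GSC&SG" and not row["mixed"]]
    cyst_rows = annotation[(annotation["label"] == "Cyst") & (~annotation["mixed"])]
    if not germ_ids:
        raise ValidationError("no GSC&SG-labelled cluster available for sub-clustering")
    if cyst_rows.empty:
        raise ValidationError("no Cyst cluster available as sub-clustering outgroup")
    outgroup = int(cyst_rows["n_cells"].idxmax())

    keep_ids = set(germ_ids) | {outgroup}
    mask = np.isin(clusters, list(keep_ids))
    sub = matrix.subset_cells([b for b, m in zip(matrix.cell_barcodes, mask) if m])
    logger.info("sub-clustering %d cells from clusters %s (outgroup %d)",
                sub.n_cells, sorted(keep_ids), outgroup)

    norm = normalize_log(sub)
    emb = PCAEmbedder(params.n_components, params.n_variable_genes, seed=seed)
    embedding = emb.fit(norm).transform(norm)
    sub_labels = GraphClusterer(params.n_neighbors, params.resolution, seed=seed).fit_predict(embedding)

    idx_by_sub = {sid: np.flatnonzero(sub_labels == sid) for sid in sorted(set(sub_labels.tolist()))}
    calls = classify_subclusters(sub, idx_by_sub, panel)

    gsc_barcodes, sg_barcodes = set(), set()
    for sid, call in calls.items():
        bcs = [sub.cell_barcodes[i] for i in idx_by_sub[sid]]
        if call == "GSC":
            gsc_barcodes.update(bcs)
        elif call == "SG":
            sg_barcodes.update(bcs)
    gsc = CellSelection(
        "cluster_based", gsc_barcodes,
        {b: "nos/ovo-rich subcluster" for b in gsc_barcodes},
    )
    sg = CellSelection(
        "cluster_based", sg_barcodes,
        {b: "vas-positive, nos/ovo-depleted subcluster" for b in sg_barcodes},
    )
    return gsc, sg, calls
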