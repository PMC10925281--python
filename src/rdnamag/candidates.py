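"""Candidate-gene filtering: intersection, ambient filter, SG specificity.

A gene becomes a final candidate regulator when it is significantly
differentially expressed, in the same direction, in both GSC selections
(cluster-based and expression-based), is not an ambient-RNA artifact
(up-candidates also significantly up in somatic Cyst cells are removed —
soup from lysed cells leaks into every droplet, so a shared somatic/germline
increase is suspect), and is GSC-specific (no, or opposite, significant
change in spermatogonia). The per-gene reported effect across the two
selections is conservative: the smaller fold-change magnitude and the larger
adjusted p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ValidationError
from .magnification import chi_squared_2x2


def intersect_de(de_method1: pd.DataFrame, de_method2: pd.DataFrame) -> pd.DataFrame:
    """Genes significant in both DE tables with the same direction.

    Keeps per-method effects; ``log2fc`` is the smaller-magnitude estimate
    and ``p_adj`` the larger of the two (conservative reporting).
    """
    sig1 = de_method1[de_method1["significant"]]
    sig2 = de_method2[de_method2["significant"]]
    common = sig1.index.intersection(sig2.index)
    rows = []
    for gene in common:
        d1, d2 = sig1.loc[gene, "direction"], sig2.loc[gene, "direction"]
        if d1 != d2:
            continue
        fc1, fc2 = float(sig1.loc[gene, "log2fc"]), float(sig2.loc[gene, "log2fc"])
        rows.append({
            "gene": gene,
            "direction": d1,
            "log2fc_cluster": fc1,
            "log2fc_expression": fc2,
            "log2fc": fc1 if abs(fc1) <= abs(fc2) else fc2,
            "p_adj": max(float(sig1.loc[gene, "p_adj"]), float(sig2.loc[gene, "p_adj"])),
            "in_both_methods": True,
        })
    cols = ["gene", "direction", "log2fc_cluster", "log2fc_expression",
            "log2fc", "p_adj", "in_both_methods"]
    if not rows:
        empty = pd.DataFrame(columns=cols)
        empty.index.name = "gene"
        return empty
    return pd.DataFrame(rows, columns=cols).set_index("gene", drop=False)


def _lookup(de: pd.DataFrame, gene: str):
    if gene in de.index:
        row = de.loc[gene]
        return float(row["log2fc"]), bool(row["significant"]), str(row["direction"])
    return np.nan, False, "none"


def remove_ambient_artifacts(candidates: pd.DataFrame, somatic_de: pd.DataFrame) -> pd.DataFrame:
    """Flag up-candidates that are also significantly up in somatic cells.

    ``somatic_de`` must be the low-vs-normal DE over Cyst-labelled cells.
    Down-candidates cannot be soup artifacts (the soup only adds counts) and
    are never flagged.
    """
    if somatic_de is None:
        raise ValidationError("somatic DE table required for the ambient filter")
    out = candidates.copy()
    flags, somatic_fc = [], []
    for gene in out["gene"] if "gene" in out.columns else out.index:
        fc, sig, direction = _lookup(somatic_de, gene)
        somatic_fc.append(fc)
        row_dir = out.loc[gene, "direction"]
        flags.append(bool(row_dir == "up" and sig and direction == "up"))
    out["somatic_log2fc"] = somatic_fc
    out["ambient_removed"] = flags
    return out


def filter_sg_specific(candidates: pd.DataFrame, sg_de: pd.DataFrame) -> pd.DataFrame:
    """Keep candidates with no (or opposite) significant change in SG.

    A candidate is SG-specific-to-GSC when, in the spermatogonia DE, it is
    either not significant or significant in the opposite direction. The
    returned table carries all provenance flags and ``final_candidate``.
    """
    if sg_de is None:
        raise ValidationError("SG DE table required for the specificity filter")
    out = candidates.copy()
    sg_fc, specific = [], []
    for gene in out["gene"] if "gene" in out.columns else out.index:
        fc, sig, direction = _lookup(sg_de, gene)
        sg_fc.append(fc)
        same_direction = sig and direction == out.loc[gene, "direction"]
        specific.append(not same_direction)
    out["sg_log2fc"] = sg_fc
    out["sg_specific"] = specific
    if "ambient_removed" not in out.columns:
        out["ambient_removed"] = False
    out["final_candidate"] = out["in_both_methods"] & ~out["ambient_removed"] & out["sg_specific"]
    return out


def build_candidate_table(de_cluster: pd.DataFrame, de_expression: pd.DataFrame,
                          somatic_de: pd.DataFrame, sg_de: pd.DataFrame) -> pd.DataFrame:
    """Full cascade: intersect -> ambient filter -> SG-specificity filter."""
    table = intersect_de(de_cluster, de_expression)
    if table.empty:
        cols = list(table.columns) + ["somatic_log2fc", "ambient_removed",
                                      "sg_log2fc", "sg_specific", "final_candidate"]
        return pd.DataFrame(columns=cols)
    table = remove_ambient_artifacts(table, somatic_de)
    return filter_sg_specific(table, sg_de)


def enrichment_fold(query_set, annotated_set, background_size: int):
    """Fold enrichment of an annotation inside a query gene set.

    ``fold = (|query ∩ annotated| / |query|) / (|annotated| / background)``
    with the Pearson chi-squared test (no continuity correction) on the
    induced 2x2 table. Returns ``(fold, chi2, p)``.
    """
    query = set(query_set)
    annotated = set(annotated_set)
    if not query or not annotated:
        raise ValidationError("query and annotated sets must be nonempty")
    n = int(background_size)
    if len(query) > n or len(annotated) > n:
        raise ValidationError("sets cannot exceed the background size")
    k = len(query & annotated)
    fold = (k / len(query)) / (len(annotated) / n)
    table = [
        [k, len(query) - k],
        [len(annotated) - k, n - len(query) - len(annotated) + k],
    ]
    chi2, p = chi_squared_2x2(table)
    return float(fold), chi2, p
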