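"""Per-gene two-group differential expression.

The test is the two-sided Wilcoxon rank-sum (Mann-Whitney) test on
log-normalized expression — ranks are invariant under the monotone log1p
transform, so this equals testing the normalized counts. Small untied
samples get the exact enumeration p-value; otherwise the normal
approximation with midranks, tie correction and continuity correction is
used. Effect size is the log2 ratio of de-logged normalized group means with
a pseudocount; p-values are Bonferroni corrected over the number of genes
actually tested (genes detected in at least one cell of either group).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator

from .config import DEThresholds
from .containers import GeneExpressionMatrix, ValidationError
from .preprocess import normalize_log


def wilcoxon_rank_sum(values_a, values_b, exact_cutoff: int = 10):
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank-sum statistic of group A
    (midranks for ties). Exact enumeration when ``min(n_a, n_b) <=
    exact_cutoff`` and the pooled sample has no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= exact_cutoff and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return w, float(min(res.pvalue, 1.0))


def log2_fold_change(normalized_a, normalized_b, pseudocount: float = 1.0) -> float:
    """log2((mean_a + pc) / (mean_b + pc)) on de-logged normalized values."""
    a = np.asarray(normalized_a, dtype=float)
    b = np.asarray(normalized_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    mean_a = np.expm1(a).mean()
    mean_b = np.expm1(b).mean()
    return float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))


class WilcoxonDE(BaseEstimator):
    """Two-group Wilcoxon differential expression over all detected genes.

    Fit against a :class:`GeneExpressionMatrix` and two disjoint barcode
    sets (group A over group B); the per-gene records land in ``results_``.
    """

    def __init__(self, log2fc_min=0.25, alpha=0.05, pseudocount=1.0,
                 exact_cutoff=10, normalization_target=None):
        self.log2fc_min = log2fc_min
        self.alpha = alpha
        self.pseudocount = pseudocount
        self.exact_cutoff = exact_cutoff
        self.normalization_target = normalization_target

    def fit(self, X: GeneExpressionMatrix, groups, normalized: sp.spmatrix = None):
        cells_a, cells_b = groups
        cells_a, cells_b = list(cells_a), list(cells_b)
        if not cells_a or not cells_b:
            raise ValidationError("both cell groups must be nonempty")
        overlap = set(cells_a) & set(cells_b)
        if overlap:
            raise ValidationError(f"cell groups overlap on {len(overlap)} barcodes")
        idx_a = X.barcode_positions(cells_a)
        idx_b = X.barcode_positions(cells_b)
        if normalized is None:
            normalized = normalize_log(X, target=self.normalization_target)
        normalized = sp.csc_matrix(normalized)

        raw = sp.csc_matrix(X.counts)
        detected = np.asarray((raw[:, np.concatenate([idx_a, idx_b])] > 0).sum(axis=1)).ravel() > 0
        tested = np.flatnonzero(detected)
        n_tested = len(tested)

        A = np.asarray(normalized[:, idx_a].todense())[tested]
        B = np.asarray(normalized[:, idx_b].todense())[tested]

        if min(len(cells_a), len(cells_b)) <= self.exact_cutoff:
            stats_p = np.array([wilcoxon_rank_sum(A[i], B[i], self.exact_cutoff)[1]
                                for i in range(n_tested)])
        else:
            res = stats.mannwhitneyu(A, B, alternative="two-sided",
                                     method="asymptotic", use_continuity=True, axis=1)
            stats_p = np.minimum(np.atleast_1d(res.pvalue), 1.0)

        mean_a = np.expm1(A).mean(axis=1)
        mean_b = np.expm1(B).mean(axis=1)
        l2fc = np.log2((mean_a + self.pseudocount) / (mean_b + self.pseudocount))
        p_adj = np.minimum(stats_p * n_tested, 1.0)
        significant = (p_adj < self.alpha) & (np.abs(l2fc) > self.log2fc_min)
        direction = np.where(significant, np.where(l2fc > 0, "up", "down"), "none")

        self.n_tested_ = n_tested
        self.results_ = pd.DataFrame({
            "gene": [X.gene_ids[i] for i in tested],
            "log2fc": l2fc,
            "p": stats_p,
            "p_adj": p_adj,
            "pct_expressing_a": np.asarray((raw[:, idx_a] > 0).mean(axis=1)).ravel()[tested],
            "pct_expressing_b": np.asarray((raw[:, idx_b] > 0).mean(axis=1)).ravel()[tested],
            "significant": significant,
            "direction": direction,
        }).set_index("gene", drop=False)
        return self


def differential_expression(matrix: GeneExpressionMatrix, cells_a, cells_b,
                            thresholds: DEThresholds = None,
                            normalized: sp.spmatrix = None) -> pd.DataFrame:
    """One DifferentialExpressionRecord per tested gene (A over B).

    Genes expressed in neither group are skipped and excluded from the
    Bonferroni denominator.
    """
    thresholds = thresholds or DEThresholds()
    thresholds.validate()
    de = WilcoxonDE(
        log2fc_min=thresholds.log2fc_min,
        alpha=thresholds.alpha,
        pseudocount=thresholds.pseudocount,
        exact_cutoff=thresholds.exact_cutoff,
    )
    return de.fit(matrix, (cells_a, cells_b), normalized=normalized).results_
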