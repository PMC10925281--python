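"""Scoring of rDNA magnification crosses and categorical statistics.

In a magnification assay, bobbed fathers (low rDNA copy number) are crossed
so that daughters inherit the paternal rDNA-deficient X chromosome; the
fraction of scored daughters with wild-type (reverted) cuticles rather than
the bobbed phenotype estimates the frequency of germline rDNA copy-number
expansion. Bar-marked siblings carry the balancer chromosome instead and are
excluded from scoring entirely.

Proportions carry the textbook Wald confidence interval
``p_hat +/- z * sqrt(p_hat (1 - p_hat) / n)`` (Wilson available for small
counts); categorical comparisons use the Pearson chi-squared test on a 2x2
table, and families of comparisons are Bonferroni corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ValidationError


@dataclass(frozen=True)
class ProportionEstimate:
    p_hat: float
    n: int
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not self.ci_low <= self.p_hat <= self.ci_high:
            raise ValidationError("CI must contain the point estimate")


def proportion_ci(k: int, n: int, confidence: float = 0.95,
                  method: str = "wald") -> ProportionEstimate:
    """Confidence interval for a population proportion.

    The default is the Wald interval, truncated to [0, 1]. At k=0 or k=n the
    Wald interval degenerates to a point — a documented limitation;
    ``method="wilson"`` avoids it.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValidationError("k must lie in [0, n]")
    p = k / n
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    if method == "wald":
        half = z * math.sqrt(p * (1 - p) / n)
        lo, hi = max(0.0, p - half), min(1.0, p + half)
    elif method == "wilson":
        denom = 1 + z * z / n
        centre = (p + z * z / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
        lo, hi = max(0.0, centre - half), min(1.0, centre + half)
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    # guard against float round-off at the k=0 / k=n boundaries
    lo, hi = min(lo, p), max(hi, p)
    return ProportionEstimate(p_hat=p, n=n, ci_low=lo, ci_high=hi)


def score_cross(counts, confidence: float = 0.95, method: str = "wald") -> ProportionEstimate:
    """Magnification frequency of one cross: wild-type / scored offspring.

    Excluded (Bar) offspring never enter the denominator.
    """
    n = counts.n_wildtype + counts.n_bobbed
    if n < 1:
        raise ValidationError("no scored offspring (n_wildtype + n_bobbed = 0)")
    if counts.n_wildtype < 0 or counts.n_bobbed < 0 or counts.n_excluded < 0:
        raise ValidationError("offspring counts must be >= 0")
    return proportion_ci(counts.n_wildtype, n, confidence=confidence, method=method)


def chi_squared_2x2(table, correction: bool = False) -> tuple:
    """Pearson chi-squared test (1 df) on a 2x2 contingency table.

    No Yates continuity correction by default. Returns ``(chi2, p)``.
    Raises on zero marginals, where expected counts are undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any():
        raise ValidationError("counts must be >= 0")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("chi-squared undefined: zero marginal in table")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(chi2), float(p)


def bonferroni_adjust(p_values) -> list:
    """Bonferroni correction: ``p_adj = min(1, p * m)`` over m comparisons."""
    p = list(p_values)
    m = len(p)
    for x in p:
        if not 0 <= x <= 1:
            raise ValidationError("p-values must lie in [0, 1]")
    return [min(1.0, x * m) for x in p]


def pairwise_cross_tests(crosses, correction: bool = False) -> list:
    """All pairwise chi-squared comparisons of magnification frequencies,
    Bonferroni corrected over the number of pairs. Returns a list of dicts."""
    results = []
    for i in range(len(crosses)):
        for j in range(i + 1, len(crosses)):
            a, b = crosses[i], crosses[j]
            chi2, p = chi_squared_2x2(
                [[a.n_wildtype, a.n_bobbed], [b.n_wildtype, b.n_bobbed]],
                correction=correction,
            )
            results.append({"a": a.label, "b": b.label, "chi2": chi2, "p": p})
    p_adj = bonferroni_adjust([r["p"] for r in results])
    for r, q in zip(results, p_adj):
        r["p_adj"] = q
        r["m"] = len(results)
    return results
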