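"""Droplet digital PCR copy-number estimation and group comparison.

A ddPCR reaction partitions a DNA sample into ~20,000 droplets; each droplet
is read as positive or negative for a fluorescent target probe. Under
Poisson loading, the mean number of template copies per droplet is
``lambda = -ln(1 - k/n)`` where ``k`` of ``n`` droplets are positive.
Relative copy number per genome-equivalent is the ratio of the target
concentration (here the 28S rDNA unit) to single-copy reference genes
(RpL49, Upf1), combined across references by geometric mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ValidationError


class SaturationError(ValueError):
    """All droplets positive: concentration is unbounded."""


@dataclass(frozen=True)
class DdpcrWell:
    """One well of a ddPCR plate."""

    sample_id: str
    target: str
    droplets_total: int
    droplets_positive: int

    def __post_init__(self):
        if self.droplets_total < 1:
            raise ValidationError("droplets_total must be >= 1")
        if not 0 <= self.droplets_positive <= self.droplets_total:
            raise ValidationError(
                f"droplets_positive={self.droplets_positive} outside "
                f"[0, {self.droplets_total}]"
            )


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Target copies per genome-equivalent relative to reference genes."""

    sample_id: str
    lambda_target: float
    lambda_refs: dict
    cn: float
    ci95: tuple

    def __post_init__(self):
        if self.cn < 0:
            raise ValidationError("copy number must be >= 0")
        if not self.ci95[0] <= self.cn <= self.ci95[1]:
            raise ValidationError("CI must contain the point estimate")


def _wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple:
    """Wilson score interval for a binomial proportion (stable at k=0)."""
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def estimate_concentration(well: DdpcrWell, confidence: float = 0.95):
    """Poisson-corrected copies per droplet with a transformed binomial CI.

    Returns ``(lambda, (lo, hi))``. Raises :class:`SaturationError` when
    every droplet is positive (``k == n``), where the correction diverges.
    """
    k, n = well.droplets_positive, well.droplets_total
    if k == n:
        raise SaturationError(
            f"well {well.sample_id}/{well.target}: all {n} droplets positive"
        )
    lam = -math.log(1.0 - k / n)
    lo, hi = _wilson_interval(k, n, confidence)
    ci = (-math.log(1.0 - lo), -math.log(1.0 - hi) if hi < 1 else math.inf)
    return lam, ci


def _mean_lambda(wells) -> float:
    return float(np.mean([estimate_concentration(w)[0] for w in wells]))


def copy_number(target_wells, reference_wells_by_gene: dict,
                ref_copies_per_genome: float = 1.0,
                reference_combine: str = "geometric") -> CopyNumberEstimate:
    """Copies per genome-equivalent of the target locus.

    ``cn = (lambda_target / g) * ref_copies_per_genome`` where ``g`` combines
    the replicate-averaged reference concentrations (geometric mean by
    default; ``reference_combine="arithmetic"`` is available).

    The 95% CI propagates the binomial uncertainty of the target wells'
    pooled droplet counts through the ratio; reference uncertainty is much
    smaller than the target's at typical droplet counts and is folded in on
    the log scale.
    """
    if not target_wells:
        raise ValidationError("at least one target well required")
    if not reference_wells_by_gene or any(not v for v in reference_wells_by_gene.values()):
        raise ValidationError("at least one well per reference gene required")

    lam_t = _mean_lambda(target_wells)
    lam_refs = {g: _mean_lambda(wells) for g, wells in reference_wells_by_gene.items()}
    if any(l == 0 for l in lam_refs.values()):
        zero = [g for g, l in lam_refs.items() if l == 0]
        raise ValidationError(f"reference gene(s) with zero concentration: {zero}")
    vals = np.array(list(lam_refs.values()))
    g = float(np.exp(np.mean(np.log(vals)))) if reference_combine == "geometric" else float(vals.mean())
    cn = lam_t / g * ref_copies_per_genome

    # log-scale variance: Var(ln lambda) ~= Var(k/n) / ((1-k/n) ln(1-k/n))^2
    def _log_var(wells):
        var = 0.0
        for w in wells:
            p = w.droplets_positive / w.droplets_total
            if p == 0:
                return math.inf
            vp = p * (1 - p) / w.droplets_total
            var += vp / ((1 - p) * math.log(1 - p)) ** 2
        return var / len(wells) ** 2

    log_var = _log_var(target_wells)
    ref_var = sum(_log_var(w) for w in reference_wells_by_gene.values())
    log_var += ref_var / max(len(lam_refs), 1) ** 2
    if math.isfinite(log_var):
        half = 1.96 * math.sqrt(log_var)
        ci = (cn * math.exp(-half), cn * math.exp(half))
    else:
        ci = (0.0, math.inf)
    ci = (min(ci[0], cn), max(ci[1], cn))
    return CopyNumberEstimate(
        sample_id=target_wells[0].sample_id,
        lambda_target=lam_t,
        lambda_refs=lam_refs,
        cn=cn,
        ci95=ci,
    )


def compare_copy_number(group_a, group_b, equal_var: bool = False,
                        confidence: float = 0.95) -> dict:
    """Two-sample t comparison of per-individual copy-number values.

    Welch's unequal-variance t by default (``equal_var=True`` pools).
    Returns mean difference (a - b), t statistic, two-sided p, and the
    per-group confidence intervals of the mean.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both groups need n >= 2 for a t-test")

    def _mean_ci(x):
        m = x.mean()
        if np.allclose(x, x[0]):
            return (m, m)
        se = x.std(ddof=1) / math.sqrt(len(x))
        h = stats.t.ppf(0.5 + confidence / 2.0, len(x) - 1) * se
        return (m - h, m + h)

    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and a[0] == b[0]:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "mean_diff": float(a.mean() - b.mean()),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t": float(t_stat),
        "two_sided_p": float(p),
        "ci95_of_means": {"a": _mean_ci(a), "b": _mean_ci(b)},
    }
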