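"""Evaluation arithmetic for variant-prioritisation strategies.

Precision (positive predictive value) is the fraction of variants
surviving a strategy that are part of the confirmed molecular diagnosis;
sensitivity is the fraction of diagnosed individuals whose causal variants
survive.  Sensitivity intervals come from the Bayesian posterior
Beta(a + k, b + n - k) under a Beta(a, b) prior (Jeffreys by default),
reported as a highest-posterior-density or equal-tailed interval.  Paired
strategy comparisons use the Wilcoxon signed-rank test with an exact null
distribution for small n.

Percent rounding is half away from zero throughout (12.5 -> 13), a hard
compatibility rule for clinical reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats


def round_half_up(x: float, digits: int = 0) -> float:
    """Round half away from zero (12.5 -> 13), unlike banker's rounding."""
    factor = 10.0**digits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class CaseResult:
    """Per-case counts for one prioritisation strategy."""

    case_id: str
    n_diagnostic: int  # clinically confirmed causal variants
    n_retained: int  # variants surviving the strategy
    strategy: str = ""
    n_diagnostic_retained: int | None = None  # defaults to n_diagnostic

    def __post_init__(self) -> None:
        k = self.diagnostic_retained
        if not (0 <= k <= min(self.n_diagnostic, self.n_retained)):
            raise ValueError(
                f"{self.case_id}: n_diagnostic_retained {k} outside "
                f"[0, min({self.n_diagnostic}, {self.n_retained})]"
            )

    @property
    def diagnostic_retained(self) -> int:
        if self.n_diagnostic_retained is None:
            return self.n_diagnostic
        return self.n_diagnostic_retained

    @property
    def precision(self) -> float:
        """Unrounded precision in percent."""
        if self.n_retained == 0:
            raise ValueError(f"{self.case_id}: precision undefined for 0 retained")
        return 100.0 * self.diagnostic_retained / self.n_retained


def precision_pct(n_diagnostic_retained: int, n_retained: int) -> int:
    """Precision as an integer percent, rounded half up.

    >>> precision_pct(1, 8)
    13
    """
    if n_retained < 1:
        raise ValueError("precision undefined when no variants are retained")
    if not (0 <= n_diagnostic_retained <= n_retained):
        raise ValueError("numerator must be within [0, n_retained]")
    return int(round_half_up(100.0 * n_diagnostic_retained / n_retained))


def _hpd_interval(a: float, b: float, level: float) -> tuple[float, float]:
    """Highest-posterior-density interval of Beta(a, b) at mass ``level``.

    For a unimodal interior density the HPD is the narrowest interval with
    the given coverage; when the density is monotone the interval hugs the
    corresponding boundary.  A U-shaped posterior (a <= 1 and b <= 1) has
    no single-interval HPD; the equal-tailed interval is returned then.
    """
    dist = stats.beta(a, b)
    if a <= 1.0 and b <= 1.0:
        return dist.ppf((1 - level) / 2), dist.ppf(1 - (1 - level) / 2)
    if a <= 1.0:  # mode at 0
        return 0.0, dist.ppf(level)
    if b <= 1.0:  # mode at 1
        return dist.ppf(1 - level), 1.0

    def width(lower_tail: float) -> float:
        return dist.ppf(lower_tail + level) - dist.ppf(lower_tail)

    res = optimize.minimize_scalar(
        width, bounds=(0.0, 1.0 - level), method="bounded",
        options={"xatol": 1e-13},
    )
    p = float(res.x)
    return dist.ppf(p), dist.ppf(p + level)


def sensitivity_ci(
    k: int,
    n: int,
    level: float = 0.95,
    prior: tuple[float, float] = (0.5, 0.5),
    interval_type: str = "hpd",
) -> tuple[float, float, float]:
    """Point estimate and Bayesian credible interval for a binomial
    proportion, in percent.

    The point estimate is the observed proportion as a one-decimal percent
    (round half up); the interval comes from the Beta(a + k, b + n - k)
    posterior, highest-density by default or equal-tailed.

    >>> sensitivity_ci(1228, 1234)[0]
    99.5
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, {n}]")
    if interval_type not in ("hpd", "equal_tailed"):
        raise ValueError(f"unknown interval_type {interval_type!r}")
    a, b = prior[0] + k, prior[1] + n - k
    if interval_type == "equal_tailed":
        alpha = 1.0 - level
        lower = stats.beta.ppf(alpha / 2, a, b)
        upper = stats.beta.ppf(1 - alpha / 2, a, b)
    else:
        lower, upper = _hpd_interval(a, b, level)
    point = round_half_up(100.0 * k / n, 1)
    return point, 100.0 * float(lower), 100.0 * float(upper)


def summarize_cases(cases: Sequence[CaseResult]) -> dict[str, int]:
    """Median / min / max of per-case unrounded precision, reported as
    integer percents (round half up)."""
    if not cases:
        raise ValueError("no cases")
    precisions = [c.precision for c in cases]
    return {
        "median": int(round_half_up(float(np.median(precisions)))),
        "min": int(round_half_up(min(precisions))),
        "max": int(round_half_up(max(precisions))),
        "n_cases": len(cases),
    }


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def signed_rank_p(differences: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped.  For n <= 25 the exact null distribution
    of the positive rank sum is built by dynamic programming over sign
    assignments (midranks doubled to integers, so ties are exact too);
    above that a normal approximation with tie correction is used.
    p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    d = np.asarray([x for x in differences if x != 0], dtype=float)
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1 by convention")
        return 1.0
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # integer rank weights: midranks are multiples of 1/2
        weights = np.rint(2 * ranks).astype(int)
        total = int(weights.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for wt in weights:
            shifted = np.zeros_like(dist)
            shifted[wt:] = dist[: total + 1 - wt]
            dist = 0.5 * (dist + shifted)
        w2 = int(round(2 * w_plus))
        p_le = float(dist[: w2 + 1].sum())
        p_ge = float(dist[w2:].sum())
        return min(1.0, 2.0 * min(p_le, p_ge))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts) / 48.0).sum()
    )
    z = (w_plus - mean) / math.sqrt(var)
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


def paired_precision_test(
    precisions_a: Sequence[float], precisions_b: Sequence[float]
) -> float:
    """Two-sided paired signed-rank comparison of per-case precisions.

    The test is the Wilcoxon *signed-rank* test (the paired analogue of
    the rank-sum test), applied to per-case differences.
    """
    if len(precisions_a) != len(precisions_b):
        raise ValueError("precision vectors must be paired (equal length)")
    if len(precisions_a) < 6:
        raise ValueError("need at least 6 paired cases")
    diffs = [a - b for a, b in zip(precisions_a, precisions_b)]
    return signed_rank_p(diffs)
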