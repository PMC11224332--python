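"""Steiger directionality filtering.

Guards against reverse causation: instruments for a true exposure -> outcome
effect should explain more variance in the exposure than in the outcome.
Variance explained is recovered from a variant's association p-value and
sample size through the F(1, n-2) quantile, r^2 = F / (F + n - 2), summed over
clumped (near-independent) instruments; the two r^2 values are compared with
a Fisher-z test on the implied correlations.

Binary outcomes use the same observational pseudo-r^2 with total N; no
liability-scale adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SteigerResult", "variance_explained", "variance_explained_total", "steiger_test"]


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction: str  # "correct" | "reverse"
    z_stat: float
    pvalue: float


def variance_explained(pvalue, n):
    """r^2 implied by a single variant's p-value at sample size n.

    F is the 1 - p quantile of F(1, n - 2); r^2 = F / (F + n - 2). Accepts
    scalars or arrays (n > 3 required).
    """
    pvalue = np.asarray(pvalue, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 3):
        raise ValueError("n must be > 3")
    if np.any((pvalue <= 0) | (pvalue > 1)):
        raise ValueError("p must be in (0, 1]")
    # F(1, d) quantile == squared t(d) quantile; the t form stays finite far
    # into the tail where scipy's F inverse overflows.
    f = stats.t.isf(pvalue / 2.0, n - 2) ** 2
    r2 = f / (f + n - 2)
    return float(r2) if r2.ndim == 0 else r2


def variance_explained_total(pvalues, n) -> float:
    """Summed r^2 over clumped instruments (independence assumption)."""
    return float(np.sum(variance_explained(np.asarray(pvalues, float), n)))


def steiger_test(r2_exp: float, n_exp: float, r2_out: float, n_out: float) -> SteigerResult:
    """Fisher-z comparison of exposure vs outcome variance explained.

    z = (atanh sqrt(r2_exp) - atanh sqrt(r2_out)) /
        sqrt(1/(n_exp - 3) + 1/(n_out - 3));
    direction is 'correct' iff r2_exp > r2_out; p is two-sided normal on z.
    """
    for r2 in (r2_exp, r2_out):
        if not 0 <= r2 < 1:
            raise ValueError("r^2 must be in [0, 1)")
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("n must be > 3")
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    direction = "correct" if r2_exp > r2_out else "reverse"
    return SteigerResult(float(r2_exp), float(r2_out), direction, float(z), float(p))
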