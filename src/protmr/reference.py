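"""Straightforward reference implementations for cross-validation.

Each function here recomputes a quantity the main modules produce, by a
different and deliberately naive route (explicit loops, linear-space sums,
textbook normal equations). They exist so that the optimized implementations
can be checked against an independent path in the test suite and the
acceptance evaluation; none of them is used by the pipeline itself.
"""

from __future__ import annotations

import numpy as np

from .coloc import ColocDataset, wakefield_log_abf
from .estimators import MRInput
from .instruments import Instrument
from .sumstats import LDMatrix

__all__ = [
    "ivw_wls_origin",
    "egger_normal_equations",
    "brute_force_clump",
    "coloc_linear_space",
    "weighted_median_two_pass",
]


def ivw_wls_origin(input: MRInput) -> tuple[float, float]:
    """IVW as weighted least squares of by on bx through the origin.

    Weights 1/sy^2 (first-order weights): theta = sum(w bx by)/sum(w bx^2),
    se = 1/sqrt(sum(w bx^2)). Algebraically identical to the inverse-variance
    weighted mean of Wald ratios with delta SEs.
    """
    w = 1.0 / input.sy**2
    sxx = float(np.sum(w * input.bx**2))
    theta = float(np.sum(w * input.bx * input.by)) / sxx
    return theta, sxx**-0.5


def egger_normal_equations(input: MRInput) -> tuple[float, float]:
    """Egger intercept and slope by explicitly solved 2x2 normal equations."""
    sign = np.where(input.bx < 0, -1.0, 1.0)
    x = input.bx * sign
    y = input.by * sign
    w = 1.0 / input.sy**2
    sw, swx, swx2 = np.sum(w), np.sum(w * x), np.sum(w * x**2)
    swy, swxy = np.sum(w * y), np.sum(w * x * y)
    det = sw * swx2 - swx**2
    intercept = (swx2 * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    return float(intercept), float(slope)


def brute_force_clump(
    instruments: list[Instrument],
    ld: LDMatrix,
    r2_threshold: float = 0.2,
    window_kb: float = 10_000,
) -> list[str]:
    """Greedy clumping transcribed directly from its textual rule.

    Scans the full candidate list on every round instead of maintaining a
    shrinking pool; returns kept variant IDs in selection order.
    """
    idx = {v: i for i, v in enumerate(ld.variant_ids)}
    remaining = {
        ins.record.variant_id: ins for ins in instruments if ins.selected
    }
    kept: list[str] = []
    while remaining:
        best = min(
            remaining.values(), key=lambda ins: (ins.record.pvalue, ins.record.variant_id)
        )
        kept.append(best.record.variant_id)
        i = idx[best.record.variant_id]
        for vid in list(remaining):
            ins = remaining[vid]
            if vid == best.record.variant_id:
                del remaining[vid]
                continue
            close = abs(ins.record.pos - best.record.pos) <= window_kb * 1000.0
            if close and ld.r[i, idx[vid]] ** 2 >= r2_threshold:
                del remaining[vid]
    return kept


def coloc_linear_space(
    d1: ColocDataset,
    d2: ColocDataset,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> np.ndarray:
    """Five colocalization posteriors by direct linear-space enumeration.

    Loops over SNPs (and SNP pairs for H3) summing raw Bayes factors; only
    usable for small regions with moderate |z|, which is exactly its role as
    an oracle.
    """
    bf1 = np.exp(wakefield_log_abf(d1.beta, d1.se, d1.sd_prior))
    bf2 = np.exp(wakefield_log_abf(d2.beta, d2.se, d2.sd_prior))
    m = len(bf1)
    s1 = sum(bf1[j] for j in range(m))
    s2 = sum(bf2[k] for k in range(m))
    s12 = sum(bf1[j] * bf2[j] for j in range(m))
    s_cross = 0.0
    for j in range(m):
        for k in range(m):
            if j != k:
                s_cross += bf1[j] * bf2[k]
    weights = np.array([
        1.0,
        p1 * s1,
        p2 * s2,
        p1 * p2 * s_cross,
        p12 * s12,
    ])
    return weights / weights.sum()


def weighted_median_two_pass(
    ratios: np.ndarray, weights: np.ndarray, penalty: float | None = None
) -> float:
    """Weighted (optionally penalized) median by scalar loops.

    Sorts ratios, walks the breakpoints s_j = cumsum(w') - w'_j/2 and
    interpolates at 0.5; with ``penalty`` it first computes the unpenalized
    median, down-weights each instrument by min(1, penalty * p_j) from its
    chi-square(1) heterogeneity tail, and recomputes.
    """
    from scipy.stats import chi2

    ratios = np.asarray(ratios, float)
    weights = np.asarray(weights, float)

    def wm(r, w):
        order = np.argsort(r)
        r, w = r[order], w[order]
        w = w / w.sum()
        s = np.cumsum(w) - w / 2.0
        if 0.5 <= s[0]:
            return float(r[0])
        if 0.5 >= s[-1]:
            return float(r[-1])
        for j in range(len(r) - 1):
            if s[j] <= 0.5 <= s[j + 1]:
                frac = (0.5 - s[j]) / (s[j + 1] - s[j])
                return float(r[j] + frac * (r[j + 1] - r[j]))
        raise AssertionError("unreachable")

    if penalty is None:
        return wm(ratios, weights)
    theta0 = wm(ratios, weights)
    qj = weights * (ratios - theta0) ** 2
    pj = chi2.sf(qj, 1)
    return wm(ratios, weights * np.minimum(1.0, penalty * pj))
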