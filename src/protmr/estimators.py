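"""Two-sample Mendelian randomization estimators on harmonized summary statistics.

All estimators consume an :class:`MRInput` — per-instrument exposure and outcome
effects (``bx``, ``by``) with standard errors (``sx``, ``sy``) expressed on the
exposure's effect-allele convention — and return an :class:`MREstimate` holding
the causal effect ``theta`` on the log-odds scale together with its OR/CI
reporting form and diagnostics (Cochran's Q heterogeneity, Egger intercept).

Per-instrument Wald ratios use the first-order delta standard error
``sy/|bx|``; instruments are treated as independent (inputs are expected to be
LD-clumped upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MRInput",
    "MREstimate",
    "wald_ratio",
    "cochran_q",
    "ivw",
    "mr_egger",
    "weighted_median",
    "penalized_weighted_median",
    "max_likelihood",
    "run_mr_suite",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class MRInput:
    """Harmonized per-instrument effect pairs for one exposure (protein)."""

    protein_id: str
    variant_ids: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    n_exposure: int
    n_outcome: int
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, dtype=float)
        self.sx = np.asarray(self.sx, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        k = len(self.variant_ids)
        if not (self.bx.shape == self.sx.shape == self.by.shape == self.sy.shape == (k,)):
            raise ValueError("bx, sx, by, sy must all have one entry per variant")
        if k < 1:
            raise ValueError("MRInput requires at least one instrument")
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    def subset(self, variant_ids: list[str]) -> "MRInput":
        """Restrict to the given variants, preserving their requested order."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in variant_ids if v not in index]
        if missing:
            raise KeyError(f"variants not in MRInput: {missing}")
        idx = np.array([index[v] for v in variant_ids], dtype=int)
        return replace(
            self,
            variant_ids=list(variant_ids),
            bx=self.bx[idx],
            sx=self.sx[idx],
            by=self.by[idx],
            sy=self.sy[idx],
        )


@dataclass
class MREstimate:
    """A causal-effect estimate with reporting transforms and diagnostics."""

    method: str
    theta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    n_snps: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    model: str | None = None
    primary: bool = False


def _estimate(
    method: str,
    theta: float,
    se: float,
    n_snps: int,
    pvalue: float | None = None,
    **extra,
) -> MREstimate:
    theta = float(theta)
    se = float(se)
    if pvalue is None:
        pvalue = 2.0 * stats.norm.sf(abs(theta) / se) if se > 0 else float("nan")
    pvalue = max(float(pvalue), 1e-300)  # keep p strictly positive under extreme z
    return MREstimate(
        method=method,
        theta=theta,
        se=se,
        pvalue=float(pvalue),
        or_=float(np.exp(theta)),
        ci_low=float(np.exp(theta - Z95 * se)),
        ci_high=float(np.exp(theta + Z95 * se)),
        n_snps=n_snps,
        **extra,
    )


def _ratios(input: MRInput) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument Wald ratios and their first-order delta SEs."""
    if np.any(input.bx == 0):
        raise ValueError("degenerate instrument with bx = 0")
    return input.by / input.bx, input.sy / np.abs(input.bx)


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MREstimate:
    """Single-instrument causal estimate ``by/bx`` with delta SE ``sy/|bx|``."""
    if bx == 0:
        raise ValueError("degenerate instrument: bx = 0")
    if sy <= 0 or sx <= 0:
        raise ValueError("standard errors must be positive")
    theta = by / bx
    se = sy / abs(bx)
    return _estimate("wald_ratio", theta, se, n_snps=1)


def cochran_q(
    ratios: np.ndarray, ratio_ses: np.ndarray, theta_ref: float
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of per-instrument ratios around ``theta_ref``."""
    ratios = np.asarray(ratios, dtype=float)
    ratio_ses = np.asarray(ratio_ses, dtype=float)
    if ratios.size < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    w = 1.0 / ratio_ses**2
    q = float(np.sum(w * (ratios - theta_ref) ** 2))
    df = ratios.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(input: MRInput, model: str = "auto", het_p_switch: float = 0.05) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of per-instrument Wald ratios.

    ``model='auto'`` uses fixed effects unless Cochran's Q is significant at
    ``het_p_switch``, in which case the SE is inflated multiplicatively by
    ``max(1, sqrt(Q / (k-1)))`` (multiplicative random effects).
    """
    if input.k < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio for k = 1")
    if model not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown IVW model: {model!r}")
    ratios, rse = _ratios(input)
    w = 1.0 / rse**2
    theta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q, df, qp = cochran_q(ratios, rse, theta)
    chosen = model if model != "auto" else ("random" if qp < het_p_switch else "fixed")
    se = se_fixed * max(1.0, np.sqrt(q / df)) if chosen == "random" else se_fixed
    return _estimate(
        "ivw", theta, se, n_snps=input.k, q_stat=q, q_df=df, q_pvalue=qp, model=chosen
    )


def mr_egger(input: MRInput) -> MREstimate:
    """MR-Egger: weighted regression of ``by`` on ``bx`` with an intercept.

    Instruments are oriented so every exposure effect is non-negative (signs of
    ``bx`` and ``by`` flipped jointly). The intercept estimates the average
    directional pleiotropic effect; its two-sided t test (k-2 df) is the Egger
    intercept test. The residual variance factor is floored at 1 so SEs are
    never deflated below the fixed-effect level.
    """
    if input.k < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    sign = np.where(input.bx < 0, -1.0, 1.0)
    bx = input.bx * sign
    by = input.by * sign
    w = 1.0 / input.sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], by * sw, rcond=None)
    intercept, slope = coef
    resid = by - X @ coef
    df = input.k - 2
    q = float(np.sum(w * resid**2))
    sigma2 = max(1.0, q / df)
    cov = sigma2 * np.linalg.inv(X.T @ (w[:, None] * X))
    se_int, se_slope = np.sqrt(np.diag(cov))
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, df)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, df)
    return _estimate(
        "mr_egger",
        slope,
        se_slope,
        n_snps=input.k,
        pvalue=p_slope,
        q_stat=q,
        q_df=df,
        q_pvalue=float(stats.chi2.sf(q, df)),
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_p=float(p_int),
    )


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by breakpoint interpolation.

    Breakpoints ``s_j = cumsum(w') - w'_j/2`` with normalized weights ``w'``;
    the estimate interpolates the sorted ratios linearly at ``s = 0.5``.
    """
    order = np.argsort(ratios, axis=-1)
    r = np.take_along_axis(ratios, order, axis=-1)
    w = np.take_along_axis(weights, order, axis=-1)
    w = w / w.sum(axis=-1, keepdims=True)
    s = np.cumsum(w, axis=-1) - w / 2.0
    # index of first breakpoint >= 0.5 per row
    hi = np.sum(s < 0.5, axis=-1)
    k = ratios.shape[-1]
    hi_c = np.clip(hi, 0, k - 1)
    lo_c = np.clip(hi - 1, 0, k - 1)
    r_lo = np.take_along_axis(r, lo_c[..., None], axis=-1)[..., 0]
    r_hi = np.take_along_axis(r, hi_c[..., None], axis=-1)[..., 0]
    s_lo = np.take_along_axis(s, lo_c[..., None], axis=-1)[..., 0]
    s_hi = np.take_along_axis(s, hi_c[..., None], axis=-1)[..., 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(s_hi > s_lo, (0.5 - s_lo) / (s_hi - s_lo), 0.0)
    out = r_lo + frac * (r_hi - r_lo)
    out = np.where(hi == 0, r.take(0, axis=-1), out)  # 0.5 below first breakpoint
    out = np.where(hi == k, r.take(k - 1, axis=-1), out)  # 0.5 above last
    return out


def _penalized_weights(
    ratios: np.ndarray, weights: np.ndarray, penalty: float
) -> np.ndarray:
    """Down-weight instruments by their chi-square(1) heterogeneity tail."""
    theta = _weighted_median_rows(ratios, weights)
    qj = weights * (ratios - theta[..., None]) ** 2
    pj = stats.chi2.sf(qj, 1)
    return weights * np.minimum(1.0, penalty * pj)


def _median_bootstrap_se(
    input: MRInput, n_boot: int, seed: int, penalty: float | None
) -> float:
    """Parametric bootstrap SE: resample bx, by from their sampling normals.

    Outcome noise is drawn in antithetic pairs (eps, -eps) so the bootstrap
    SE is exactly invariant under negating every by (sign equivariance of the
    estimator then holds to machine precision, not just in distribution).
    """
    rng = np.random.default_rng(seed)
    half = (n_boot + 1) // 2
    delta = rng.standard_normal((half, input.k))
    eps = rng.standard_normal((half, input.k))
    bxb = input.bx + input.sx * np.vstack([delta, delta])
    byb = input.by + input.sy * np.vstack([eps, -eps])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = byb / bxb
        weights = (bxb / input.sy) ** 2
    bad = ~np.isfinite(ratios)
    if bad.any():  # bx resampled to exactly 0: give that draw no weight
        ratios = np.where(bad, 0.0, ratios)
        weights = np.where(bad, 0.0, weights)
    if penalty is not None:
        weights = _penalized_weights(ratios, weights, penalty)
    thetas = _weighted_median_rows(ratios, weights)
    return float(np.std(thetas, ddof=1))


def weighted_median(
    input: MRInput, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median MR estimate, consistent when <50% of weight is invalid."""
    if input.k < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    ratios, rse = _ratios(input)
    w = 1.0 / rse**2
    theta = float(_weighted_median_rows(ratios[None, :], w[None, :])[0])
    se = _median_bootstrap_se(input, n_boot, seed, penalty=None)
    return _estimate("weighted_median", theta, se, n_snps=input.k)


def penalized_weighted_median(
    input: MRInput, penalty: float = 20.0, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median with outlying instruments down-weighted.

    Each instrument's contribution ``Q_j = w_j (ratio_j - theta_wm)^2`` is
    referred to a chi-square(1) tail ``p_j`` and its weight multiplied by
    ``min(1, penalty * p_j)`` before the median is recomputed.
    """
    if input.k < 3:
        raise ValueError("penalized weighted median needs >= 3 instruments")
    ratios, rse = _ratios(input)
    w = 1.0 / rse**2
    w_pen = _penalized_weights(ratios[None, :], w[None, :], penalty)
    theta = float(_weighted_median_rows(ratios[None, :], w_pen)[0])
    se = _median_bootstrap_se(input, n_boot, seed, penalty=penalty)
    return _estimate("penalized_weighted_median", theta, se, n_snps=input.k)


def _ml_profile_objective(input: MRInput):
    bx, sx2 = input.bx, input.sx**2
    by, sy2 = input.by, input.sy**2

    def objective(theta: float) -> float:
        xi = (bx / sx2 + theta * by / sy2) / (1.0 / sx2 + theta**2 / sy2)
        return float(np.sum((bx - xi) ** 2 / sx2 + (by - theta * xi) ** 2 / sy2))

    return objective


def max_likelihood(input: MRInput) -> MREstimate:
    """Joint-normal maximum-likelihood estimate of the causal effect.

    Maximizes the likelihood over (theta, xi) where xi are the true exposure
    effects; xi is profiled out in closed form and theta found by 1-D
    minimization started at the IVW (or Wald) estimate. The SE comes from the
    numerical curvature of the profile log-likelihood at the optimum.
    """
    if input.k >= 2:
        theta0 = ivw(input).theta
    else:
        theta0 = wald_ratio(input.bx[0], input.sx[0], input.by[0], input.sy[0]).theta
    f = _ml_profile_objective(input)
    span = 10.0 * (1.0 + abs(theta0))
    res = optimize.minimize_scalar(
        f, bounds=(theta0 - span, theta0 + span), method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"maximum-likelihood MR did not converge: {res.message}")
    theta = float(res.x)
    h = 1e-5 * max(1.0, abs(theta))
    curv = (f(theta + h) - 2.0 * f(theta) + f(theta - h)) / h**2
    if curv <= 0:
        raise RuntimeError(
            f"maximum-likelihood MR: non-positive curvature {curv:.3g} at optimum"
        )
    se = float(np.sqrt(2.0 / curv))  # -logL = f/2, information = curv/2
    return _estimate("max_likelihood", theta, se, n_snps=input.k)


def run_mr_suite(
    input: MRInput, n_boot: int = 1000, seed: int = 0
) -> list[MREstimate]:
    """Run the estimators applicable at the input's instrument count.

    k = 1: Wald ratio only. k = 2: IVW and maximum likelihood. k >= 3: IVW,
    maximum likelihood, MR-Egger, weighted median and penalized weighted
    median. The first entry (Wald for k = 1, otherwise IVW) is flagged as the
    primary analysis.
    """
    if input.k == 1:
        est = wald_ratio(input.bx[0], input.sx[0], input.by[0], input.sy[0])
        est.primary = True
        return [est]
    estimates = [ivw(input), max_likelihood(input)]
    if input.k >= 3:
        estimates += [
            mr_egger(input),
            weighted_median(input, n_boot=n_boot, seed=seed),
            penalized_weighted_median(input, n_boot=n_boot, seed=seed),
        ]
    estimates[0].primary = True
    return estimates
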