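"""Bayesian colocalization of two traits over a cis region.

Per-SNP evidence is the Wakefield approximate Bayes factor computed from an
effect estimate and its variance against a normal effect prior N(0, W):
with V = se^2, r = W/(V+W) and z = beta/se,

    log ABF = 0.5 * [log(1 - r) + r * z^2].

Assuming at most one causal variant per trait, the five regional hypotheses
are H0 (no association), H1/H2 (association with one trait only), H3 (both
traits, distinct causal variants) and H4 (both traits, one shared causal
variant). Their unnormalized weights combine the per-SNP ABFs with priors
p1, p2 (per-SNP causal for each trait) and p12 (per-SNP shared causal); all
sums are carried in log space for numerical safety and the posteriors follow
by normalization. Strong colocalization is declared when PPH4 exceeds 75%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .sumstats import IntegrityError

__all__ = ["ColocDataset", "ColocResult", "wakefield_log_abf", "coloc_posteriors", "classify_coloc"]

# Conventional effect-prior SDs: per-SD effects for quantitative traits,
# log-odds effects for binary traits.
DEFAULT_SD_PRIOR = {"quantitative": 0.15, "binary": 0.2}


@dataclass
class ColocDataset:
    """Per-SNP regional evidence for one trait."""

    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "quantitative"
    sd_prior: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        m = len(self.variant_ids)
        if m < 1 or self.beta.shape != (m,) or self.se.shape != (m,):
            raise ValueError("beta and se must have one entry per variant")
        if np.any(self.se <= 0):
            raise ValueError("se must be positive")
        if self.trait_type not in DEFAULT_SD_PRIOR:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.sd_prior is None:
            self.sd_prior = DEFAULT_SD_PRIOR[self.trait_type]
        if self.sd_prior <= 0:
            raise ValueError("sd_prior must be positive")


@dataclass
class ColocResult:
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    p1: float
    p2: float
    p12: float
    colocalized: bool


def wakefield_log_abf(beta, se, sd_prior: float):
    """Log approximate Bayes factor for one SNP (vectorized over SNPs)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if sd_prior <= 0:
        raise ValueError("sd_prior must be positive")
    v = se**2
    w = sd_prior**2
    r = w / (v + w)
    z = beta / se
    labf = 0.5 * (np.log1p(-r) + r * z**2)
    return float(labf) if labf.ndim == 0 else labf


def coloc_posteriors(
    d1: ColocDataset,
    d2: ColocDataset,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    threshold: float = 0.75,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""
    if d1.variant_ids != d2.variant_ids:
        raise IntegrityError("colocalization requires identical variant lists in order")
    l1 = wakefield_log_abf(d1.beta, d1.se, d1.sd_prior)
    l2 = wakefield_log_abf(d2.beta, d2.se, d2.sd_prior)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered pairs j != k: (sum_j)(sum_k) - sum_j(both at j)
    diff = s12 - (s1 + s2)  # <= 0, exactly 0 for a single SNP
    if diff >= -1e-14 or len(d1.variant_ids) == 1:
        s_cross = -np.inf
    else:
        s_cross = s1 + s2 + np.log1p(-np.exp(diff))

    def _log(p: float) -> float:
        return np.log(p) if p > 0 else -np.inf

    log_weights = np.array([
        0.0,
        _log(p1) + s1,
        _log(p2) + s2,
        _log(p1) + _log(p2) + s_cross,
        _log(p12) + s12,
    ])
    post = softmax(log_weights)
    return ColocResult(
        pph0=float(post[0]), pph1=float(post[1]), pph2=float(post[2]),
        pph3=float(post[3]), pph4=float(post[4]),
        n_snps=len(d1.variant_ids), p1=p1, p2=p2, p12=p12,
        colocalized=bool(post[4] > threshold),
    )


def classify_coloc(result: ColocResult, threshold: float = 0.75) -> bool:
    """Strong evidence of colocalization: PPH4 strictly above the threshold."""
    return result.pph4 > threshold
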