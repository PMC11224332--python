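"""FUSION-style proteome-wide association.

Genetically predicted protein abundance is associated with a trait by
combining GWAS z-scores with cis predictive weights under the local LD
structure:

    z_PWAS = (w' z) / sqrt(w' R w)

where R is the LD correlation over the weight-supported SNPs. Under the null
(z ~ MVN(0, R)) the statistic is standard normal. A small ridge on R's
diagonal stabilizes the variance term for near-collinear weights. Weight
training from individual-level data is out of scope; weights are consumed as
input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import LDMatrix

__all__ = ["WeightSet", "pwas_association"]


@dataclass
class WeightSet:
    """Per-SNP predictive weights for one protein's cis-regulated abundance."""

    protein_id: str
    variant_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.variant_ids),):
            raise ValueError("one weight per variant required")
        if not np.any(self.weights != 0):
            raise ValueError("at least one nonzero weight required")


def pwas_association(
    weights: WeightSet,
    gwas_z: np.ndarray,
    ld: LDMatrix,
    ridge: float = 1e-6,
) -> tuple[float, float]:
    """PWAS z-score and two-sided p for one protein.

    ``gwas_z`` is ordered as ``weights.variant_ids``; ``ld`` must cover those
    variants (only the weight-supported submatrix enters the denominator).
    """
    z = np.asarray(gwas_z, dtype=float)
    w = weights.weights
    if z.shape != w.shape:
        raise ValueError("gwas_z must align with the weight vector")
    r = ld.submatrix(weights.variant_ids) + ridge * np.eye(len(w))
    denom = float(w @ r @ w)
    if denom <= 0:
        raise ValueError(f"degenerate weights: w'Rw = {denom:.3g}")
    z_pwas = float(w @ z / np.sqrt(denom))
    return z_pwas, float(2.0 * stats.norm.sf(abs(z_pwas)))
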