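"""Synthetic paired cis-region summary statistics with known causal structure.

Summary statistics are simulated directly at the marginal-effect level, the
standard device for testing summary-statistic methods: no individual-level
genotypes are drawn. For a region of ``m`` SNPs with AR(1) LD correlation
``R`` (``r[i,j] = rho^|i-j|``), sparse per-allele causal effects ``gamma`` on
the protein produce true marginal effects ``b_x = R @ gamma``; observed
exposure effects are ``b_x + se_x * L @ z`` with ``L`` the Cholesky factor of
``R`` and ``se_x = 1/sqrt(n_exposure)`` (effects per SD of protein abundance,
standardized genotypes). The binary outcome's standard error uses the
case-fraction variance inflation ``se_y = 1/sqrt(n * cf * (1-cf))``, so
outcome effects are log-odds per allele and the causal effect ``theta`` is a
log-OR per SD of protein.

Scenarios
---------
causal_shared     b_y = theta * b_x (the protein causes the outcome)
distinct_variants b_y driven by a separate causal SNP, theta = 0
null              b_y = 0
pleiotropy        b_y = theta * b_x + R @ alpha, alpha ~ N(pleiotropy_mean,
                  pleiotropy_sd^2) per SNP (InSIDE-style: alpha independent
                  of gamma)

Causal exposure effects are positive (the effect allele is oriented to the
protein-increasing allele) with magnitude ``exposure_effect_sd * U(1 - j,
1 + j)`` where ``j = exposure_effect_jitter``: a wide spread of instrument
strengths (the default j = 0.9) keeps regression-dilution bias in MR-Egger
negligible relative to sampling error, while ``j = 0`` gives fixed-magnitude
effects for controlled single-causal-variant scenarios. All-positive effects
also make a directional pleiotropic mean identifiable by the Egger intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (
    GeneAnnotation,
    LDMatrix,
    SNPRecord,
    SummaryStatSet,
    write_ld_matrix,
    write_sumstats,
)

__all__ = [
    "ScenarioConfig",
    "SimulatedRegion",
    "simulate_ld_ar1",
    "simulate_region",
    "simulate_proteome_benchmark",
    "write_region",
]

SCENARIOS = ("causal_shared", "distinct_variants", "null", "pleiotropy")

_P_FLOOR = 1e-300  # keep p-values strictly positive under extreme z


@dataclass
class ScenarioConfig:
    """One region's generating conditions.

    Defaults emulate a deCODE-scale protein exposure (n = 30,000, effects per
    SD of abundance) against a suicide-attempt-scale binary outcome GWAS
    (n = 500,000, ~5% cases) with a GLRX5-scale protective effect
    (theta = -0.17 log-odds per SD) and a handful of independent cis signals.
    """

    scenario: str = "causal_shared"
    m_snps: int = 200
    ld_rho: float = 0.6
    theta: float = -0.17
    n_exposure: int = 30_000
    n_outcome: int = 500_000
    case_fraction: float = 0.05
    pleiotropy_mean: float = 0.02
    pleiotropy_sd: float = 0.01
    n_causal_exposure: int = 3
    exposure_effect_sd: float = 0.25
    exposure_effect_jitter: float = 0.9
    outcome_direct_effect: float = 0.05
    seed: int = 0
    protein_id: str = "PROT"
    chrom: str = "1"
    region_start: int = 500_000
    snp_spacing: int = 5_000

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.m_snps < 2:
            raise ValueError("m_snps must be >= 2")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.n_causal_exposure > self.m_snps:
            raise ValueError("n_causal_exposure cannot exceed m_snps")
        if self.n_causal_exposure < 1:
            raise ValueError("n_causal_exposure must be >= 1")
        if not 0 <= self.exposure_effect_jitter < 1:
            raise ValueError("exposure_effect_jitter must be in [0, 1)")


@dataclass
class SimulatedRegion:
    """Paired exposure/outcome summary stats, LD, gene anchor and ground truth."""

    exposure: SummaryStatSet
    outcome: SummaryStatSet
    ld: LDMatrix
    gene: GeneAnnotation
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.ld.variant_ids
        if self.exposure.variant_ids != ids or self.outcome.variant_ids != ids:
            raise ValueError("exposure, outcome and LD must share one variant order")


def simulate_ld_ar1(m: int, rho: float) -> LDMatrix:
    """AR(1) LD: r[i,j] = rho^|i-j|, the standard decaying-LD stand-in."""
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    idx = np.arange(m)
    r = np.power(float(rho), np.abs(idx[:, None] - idx[None, :]), dtype=float)
    ids = [f"rs{i + 1}" for i in range(m)]
    return LDMatrix(ids, r)


# Cholesky factors are reused across regions of identical (m, rho).
_CHOL_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _cholesky_ar1(m: int, rho: float) -> np.ndarray:
    key = (m, float(rho))
    if key not in _CHOL_CACHE:
        if len(_CHOL_CACHE) > 32:
            _CHOL_CACHE.clear()
        _CHOL_CACHE[key] = np.linalg.cholesky(simulate_ld_ar1(m, rho).r)
    return _CHOL_CACHE[key]


def _two_sided_p(beta: np.ndarray, se: float) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), _P_FLOOR)


def _build_set(
    cfg: ScenarioConfig,
    trait_id: str,
    trait_type: str,
    ids: list[str],
    pos: np.ndarray,
    eaf: np.ndarray,
    beta: np.ndarray,
    se: float,
    n: int,
    **binary_kw,
) -> SummaryStatSet:
    p = _two_sided_p(beta, se)
    records = {
        v: SNPRecord(v, cfg.chrom, int(pos[i]), "A", "G", float(eaf[i]),
                     float(beta[i]), se, float(p[i]), n)
        for i, v in enumerate(ids)
    }
    return SummaryStatSet(trait_id, trait_type, records, **binary_kw)


def simulate_region(config: ScenarioConfig) -> SimulatedRegion:
    """Draw one region's paired summary statistics, reproducibly from the seed."""
    cfg = config
    m = cfg.m_snps
    rng = np.random.default_rng(cfg.seed)
    ld = simulate_ld_ar1(m, cfg.ld_rho)
    L = _cholesky_ar1(m, cfg.ld_rho)
    R = ld.r

    causal_idx = np.sort(rng.choice(m, size=cfg.n_causal_exposure, replace=False))
    gamma = np.zeros(m)
    j = cfg.exposure_effect_jitter
    gamma[causal_idx] = cfg.exposure_effect_sd * rng.uniform(1 - j, 1 + j, cfg.n_causal_exposure)
    b_x = R @ gamma

    theta = cfg.theta if cfg.scenario in ("causal_shared", "pleiotropy") else 0.0
    causal_out_idx = causal_idx if cfg.scenario in ("causal_shared", "pleiotropy") else np.array([], int)
    if cfg.scenario == "causal_shared":
        b_y = theta * b_x
    elif cfg.scenario == "null":
        b_y = np.zeros(m)
    elif cfg.scenario == "distinct_variants":
        # direct outcome variant placed as far (in LD) from the exposure signals as possible
        dist = np.min(np.abs(np.arange(m)[:, None] - causal_idx[None, :]), axis=1)
        j = int(np.argmax(dist))
        alpha = np.zeros(m)
        alpha[j] = cfg.outcome_direct_effect
        b_y = R @ alpha
        causal_out_idx = np.array([j])
    else:  # pleiotropy
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, m)
        b_y = theta * b_x + R @ alpha

    se_x = 1.0 / np.sqrt(cfg.n_exposure)
    se_y = 1.0 / np.sqrt(cfg.n_outcome * cfg.case_fraction * (1.0 - cfg.case_fraction))
    bhat_x = b_x + se_x * (L @ rng.standard_normal(m))
    bhat_y = b_y + se_y * (L @ rng.standard_normal(m))

    ids = ld.variant_ids
    pos = cfg.region_start + cfg.snp_spacing * np.arange(m)
    eaf = rng.uniform(0.05, 0.5, m)
    n_cases = int(round(cfg.n_outcome * cfg.case_fraction))
    exposure = _build_set(cfg, cfg.protein_id, "quantitative", ids, pos, eaf,
                          bhat_x, se_x, cfg.n_exposure)
    outcome = _build_set(cfg, "outcome", "binary", ids, pos, eaf, bhat_y, se_y,
                         cfg.n_outcome, n_cases=n_cases,
                         n_controls=cfg.n_outcome - n_cases)
    gene = GeneAnnotation(cfg.protein_id, cfg.chrom,
                          int(pos[m // 2]), int(pos[m // 2]) + 20_000)
    truth = {
        "theta": float(theta),
        "causal_exposure_ids": [ids[i] for i in causal_idx],
        "causal_outcome_ids": [ids[i] for i in causal_out_idx],
        "scenario": cfg.scenario,
    }
    return SimulatedRegion(exposure, outcome, ld, gene, truth)


def simulate_proteome_benchmark(
    p_proteins: int,
    fraction_causal: float,
    base_config: ScenarioConfig | None = None,
    seed: int = 0,
    theta_magnitude_range: tuple[float, float] = (0.15, 0.35),
) -> tuple[list[SimulatedRegion], pd.DataFrame]:
    """A desk-scale proteome: mostly null regions plus a causal minority.

    ``round(p_proteins * fraction_causal)`` regions are causal_shared with
    theta of random sign and magnitude ~ U(theta_magnitude_range); the rest
    are null. Per-region seeds are fixed substreams of ``seed`` so any region
    is independently reproducible. Returns the regions and a truth table.
    """
    if not 0 <= fraction_causal <= 1:
        raise ValueError("fraction_causal must be in [0, 1]")
    base = base_config or ScenarioConfig(m_snps=60)
    n_causal = int(round(p_proteins * fraction_causal))
    rng = np.random.default_rng(seed)
    causal_set = set(rng.choice(p_proteins, size=n_causal, replace=False).tolist())
    region_seeds = np.random.SeedSequence(seed).generate_state(p_proteins) % (2**31)

    regions, rows = [], []
    for i in range(p_proteins):
        pid = f"P{i + 1:04d}"
        if i in causal_set:
            theta = float(rng.choice([-1.0, 1.0]) * rng.uniform(*theta_magnitude_range))
            cfg = replace(base, scenario="causal_shared", theta=theta,
                          protein_id=pid, seed=int(region_seeds[i]))
        else:
            cfg = replace(base, scenario="null", theta=0.0,
                          protein_id=pid, seed=int(region_seeds[i]))
        region = simulate_region(cfg)
        regions.append(region)
        rows.append((pid, region.truth["theta"], region.truth["scenario"],
                     len(region.truth["causal_exposure_ids"])))
    truth = pd.DataFrame(rows, columns=["protein_id", "theta", "scenario", "n_causal"])
    return regions, truth


def write_region(region: SimulatedRegion, out_dir) -> None:
    """Write one region in the package's on-disk formats plus a truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sumstats(region.exposure, out / "exposure.tsv")
    write_sumstats(region.outcome, out / "outcome.tsv")
    write_ld_matrix(region.ld, out / "ld.tsv")
    g = region.gene
    pd.DataFrame([(g.gene_id, g.chrom, g.start, g.end)],
                 columns=["gene_id", "CHR", "START", "END"]).to_csv(
        out / "gene.tsv", sep="\t", index=False)
    truth = dict(region.truth)
    truth["causal_exposure_ids"] = ",".join(truth["causal_exposure_ids"])
    truth["causal_outcome_ids"] = ",".join(truth["causal_outcome_ids"])
    pd.DataFrame([truth]).to_csv(out / "truth.tsv", sep="\t", index=False)
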