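"""Proteome-level orchestration: per-protein MR -> Steiger -> colocalization,
FDR tiering, cross-tissue comparison and the tabular reporting surface.

Each protein region is analysed independently (one failing region never
aborts the proteome): cis instruments are selected and LD-clumped, exposure
and outcome are harmonized, the applicable MR estimators run (Wald for a
single instrument, IVW and the robust complements otherwise), Steiger
filtering checks the causal direction, and Bayesian colocalization asks
whether the protein and the outcome share a causal variant. The primary MR
p-values are FDR-adjusted within tissue and every protein is tiered:
significant (FDR < 0.05), suggestive (p < 0.001 without surviving FDR) or
null. A protein carries overall causal evidence only when it is significant,
directionally correct and colocalized.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coloc import ColocDataset, coloc_posteriors
from .estimators import MREstimate, run_mr_suite
from .instruments import greedy_clump, select_cis_instruments
from .simulate import SimulatedRegion
from .steiger import SteigerResult, steiger_test, variance_explained_total
from .sumstats import harmonize_pair

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "ProteinResult",
    "fdr_adjust",
    "assign_tier",
    "analyze_region",
    "run_pipeline",
    "results_to_frame",
    "brain_blood_correlation",
    "replication_consistency",
    "evaluate_against_truth",
]

REPORT_COLUMNS = [
    "tissue", "protein_id", "method", "n_snps", "or_", "ci_low", "ci_high",
    "pvalue", "fdr_q", "q_pvalue", "egger_intercept_p",
    "steiger_r2_exposure", "steiger_r2_outcome", "steiger_direction", "steiger_p",
    "pph4", "colocalized", "tier", "causal_evidence",
]


@dataclass
class StudyConfig:
    """Every threshold and seed the pipeline uses, in one place."""

    p_threshold: float = 5e-8
    f_threshold: float = 10.0
    cis_window_bp: int = 10_000_000
    clump_r2: float = 0.2
    clump_window_kb: float = 10_000
    fdr_alpha: float = 0.05
    suggestive_p: float = 0.001
    fdr_method: str = "bh"  # "bh" | "empirical_null"
    pph4_threshold: float = 0.75
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("p_threshold", 0, 1), ("fdr_alpha", 0, 1), ("suggestive_p", 0, 1),
            ("pph4_threshold", 0, 1), ("clump_r2", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} must be in ({lo}, {hi}]")
        if self.fdr_method not in ("bh", "empirical_null"):
            raise ValueError(f"unknown fdr_method {self.fdr_method!r}")


@dataclass
class ProteinResult:
    """One row of the per-protein reporting surface."""

    tissue: str
    protein_id: str
    method: str
    n_snps: int
    or_: float
    ci_low: float
    ci_high: float
    pvalue: float
    fdr_q: float
    q_pvalue: float | None
    egger_intercept_p: float | None
    steiger: SteigerResult
    pph4: float
    colocalized: bool
    tier: str
    causal_evidence: bool
    estimates: list[MREstimate] = field(default_factory=list, repr=False)


def fdr_adjust(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment across a proteome.

    'bh' is Benjamini-Hochberg step-up q-values. 'empirical_null' is a
    Storey-type two-component tail-area FDR: the null proportion pi0 is
    estimated from the p-value mass above 0.5 and scales the BH tail area.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method != "empirical_null":
        raise ValueError(f"unknown FDR method {method!r}")
    lam = 0.5
    pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam)) if p.size else 1.0
    pi0 = max(pi0, 1.0 / p.size)  # never exactly 0
    return np.minimum(pi0 * q, 1.0)


def assign_tier(
    pvalue: float, fdr_q: float, alpha: float = 0.05, suggestive_p: float = 0.001
) -> str:
    """significant (q < alpha) / suggestive (p < suggestive_p) / null."""
    if fdr_q < alpha:
        return "significant"
    if pvalue < suggestive_p:
        return "suggestive"
    return "null"


def _exposure_pvalues(mr_input) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(mr_input.bx / mr_input.sx)), 1e-300)


def analyze_region(
    region: SimulatedRegion, config: StudyConfig, tissue: str = "brain",
    boot_seed: int | None = None,
) -> ProteinResult | None:
    """Instrument selection through colocalization for one protein region.

    Returns None (with a log line) when no valid instrument survives.
    fdr_q and tier are placeholders until proteome-level FDR is applied.
    """
    protein_id = region.exposure.trait_id
    candidates = select_cis_instruments(
        region.exposure, region.gene, window_bp=config.cis_window_bp,
        p_threshold=config.p_threshold, f_threshold=config.f_threshold,
    )
    kept = greedy_clump(
        candidates, region.ld, r2_threshold=config.clump_r2,
        window_kb=config.clump_window_kb,
    )
    if not kept:
        logger.info("%s: no instrument passed selection; skipped", protein_id)
        return None
    harmonized = harmonize_pair(region.exposure, region.outcome)
    kept_ids = [i.record.variant_id for i in kept if i.record.variant_id in set(harmonized.variant_ids)]
    if not kept_ids:
        logger.info("%s: all instruments lost in harmonization; skipped", protein_id)
        return None
    mr_input = harmonized.subset(kept_ids)

    seed = config.seed if boot_seed is None else boot_seed
    estimates = run_mr_suite(mr_input, n_boot=config.n_boot, seed=seed)
    primary = estimates[0]
    egger = next((e for e in estimates if e.method == "mr_egger"), None)

    out_p = np.maximum(2.0 * stats.norm.sf(np.abs(mr_input.by / mr_input.sy)), 1e-300)
    # summed single-SNP r^2 assumes independent instruments and can overshoot
    # 1 for very strong signals; cap just below 1 to keep the Fisher-z defined
    cap = 1.0 - 1e-9
    r2_exp = min(variance_explained_total(_exposure_pvalues(mr_input), mr_input.n_exposure), cap)
    r2_out = min(variance_explained_total(out_p, mr_input.n_outcome), cap)
    steiger = steiger_test(r2_exp, mr_input.n_exposure, r2_out, mr_input.n_outcome)

    exp_df = region.exposure.to_frame()
    out_df = region.outcome.to_frame()
    coloc = coloc_posteriors(
        ColocDataset(list(exp_df["SNP"]), exp_df["BETA"].to_numpy(),
                     exp_df["SE"].to_numpy(), region.exposure.trait_type),
        ColocDataset(list(out_df["SNP"]), out_df["BETA"].to_numpy(),
                     out_df["SE"].to_numpy(), region.outcome.trait_type),
        p1=config.coloc_p1, p2=config.coloc_p2, p12=config.coloc_p12,
        threshold=config.pph4_threshold,
    )

    return ProteinResult(
        tissue=tissue,
        protein_id=protein_id,
        method=primary.method,
        n_snps=primary.n_snps,
        or_=primary.or_,
        ci_low=primary.ci_low,
        ci_high=primary.ci_high,
        pvalue=primary.pvalue,
        fdr_q=float("nan"),
        q_pvalue=primary.q_pvalue,
        egger_intercept_p=egger.egger_intercept_p if egger else None,
        steiger=steiger,
        pph4=coloc.pph4,
        colocalized=coloc.pph4 > config.pph4_threshold,
        tier="null",
        causal_evidence=False,
        estimates=estimates,
    )


def results_to_frame(results: list[ProteinResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = asdict(r)
        d.pop("estimates", None)
        st = d.pop("steiger")
        d["steiger_r2_exposure"] = st["r2_exposure"]
        d["steiger_r2_outcome"] = st["r2_outcome"]
        d["steiger_direction"] = st["direction"]
        d["steiger_p"] = st["pvalue"]
        rows.append(d)
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df


def run_pipeline(
    regions_by_tissue: dict[str, list[SimulatedRegion]],
    config: StudyConfig | None = None,
    out_dir=None,
) -> dict:
    """Run the full per-protein analysis and tier the proteome.

    FDR is computed within tissue over the primary MR p-values. Returns a
    dict with the report frame ('results'), per-protein estimate objects
    ('protein_results') and a run log ('log'); writes results.tsv and
    run_log.json when ``out_dir`` is given. Deterministic for a fixed config
    and input.
    """
    config = config or StudyConfig()
    all_results: list[ProteinResult] = []
    log: dict = {"config": asdict(config), "tissues": {}}
    for tissue, regions in regions_by_tissue.items():
        tissue_results: list[ProteinResult] = []
        skipped = []
        for i, region in enumerate(regions):
            boot_seed = (config.seed * 1_000_003 + i) % (2**31)
            try:
                res = analyze_region(region, config, tissue=tissue, boot_seed=boot_seed)
            except Exception as exc:  # protein-level isolation
                logger.warning("%s: failed (%s); skipped", region.exposure.trait_id, exc)
                skipped.append({"protein_id": region.exposure.trait_id, "reason": str(exc)})
                continue
            if res is None:
                skipped.append({"protein_id": region.exposure.trait_id,
                                "reason": "no valid instruments"})
                continue
            tissue_results.append(res)
        if tissue_results:
            q = fdr_adjust([r.pvalue for r in tissue_results], method=config.fdr_method)
            for r, qi in zip(tissue_results, q):
                r.fdr_q = float(qi)
                r.tier = assign_tier(r.pvalue, r.fdr_q, config.fdr_alpha, config.suggestive_p)
                r.causal_evidence = (
                    r.tier == "significant"
                    and r.steiger.direction == "correct"
                    and r.colocalized
                )
        log["tissues"][tissue] = {
            "n_regions": len(regions),
            "n_analyzed": len(tissue_results),
            "skipped": skipped,
        }
        all_results.extend(tissue_results)
    if not all_results:
        logger.warning("run_pipeline: no protein produced a result")
    report = results_to_frame(all_results)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "results.tsv", sep="\t", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    return {"results": report, "protein_results": all_results, "log": log}


def brain_blood_correlation(
    brain: pd.DataFrame, blood: pd.DataFrame, mode: str = "all"
) -> tuple[float, float, int]:
    """Pearson correlation of log-OR MR estimates over shared proteins.

    ``mode`` restricts the shared set: 'all' (no filter), 'either_p05'
    (MR p < 0.05 in at least one tissue) or 'both_p05' (in both).
    """
    merged = brain.merge(blood, on="protein_id", suffixes=("_brain", "_blood"))
    if mode == "either_p05":
        merged = merged[(merged["pvalue_brain"] < 0.05) | (merged["pvalue_blood"] < 0.05)]
    elif mode == "both_p05":
        merged = merged[(merged["pvalue_brain"] < 0.05) & (merged["pvalue_blood"] < 0.05)]
    elif mode != "all":
        raise ValueError(f"unknown mode {mode!r}")
    n = len(merged)
    if n < 3:
        raise ValueError(f"insufficient overlap: {n} shared proteins after filtering")
    r, p = stats.pearsonr(np.log(merged["or__brain"]), np.log(merged["or__blood"]))
    return float(r), float(p), n


def replication_consistency(
    discovery: pd.DataFrame, replication: pd.DataFrame
) -> pd.DataFrame:
    """Per-protein replication flags against an independent outcome dataset.

    direction_consistent: sign of the discovery and replication log-OR agree;
    replicated: additionally replication p < 0.05. Proteins absent from the
    replication set are recorded as not available.
    """
    rep = replication.set_index("protein_id")
    rows = []
    for r in discovery.itertuples(index=False):
        theta_d = float(np.log(r.or_))
        if r.protein_id not in rep.index:
            rows.append((r.protein_id, theta_d, np.nan, np.nan, False, False, "not_available"))
            continue
        rr = rep.loc[r.protein_id]
        theta_r = float(np.log(rr["or_"]))
        consistent = bool(np.sign(theta_d) == np.sign(theta_r))
        replicated = bool(consistent and rr["pvalue"] < 0.05)
        status = "replicated" if replicated else (
            "direction_consistent" if consistent else "inconsistent")
        rows.append((r.protein_id, theta_d, theta_r, float(rr["pvalue"]),
                     consistent, replicated, status))
    return pd.DataFrame(rows, columns=[
        "protein_id", "theta_discovery", "theta_replication", "replication_p",
        "direction_consistent", "replicated", "status",
    ])


def evaluate_against_truth(results: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Compare tiered calls with the generator's ground truth.

    Empirical FDR is the fraction of tier=significant calls whose true theta
    is 0; power is the fraction of truly causal proteins called significant.
    """
    merged = results.merge(truth, on="protein_id", how="left")
    sig = merged[merged["tier"] == "significant"]
    causal = merged[merged["theta"] != 0]
    n_sig = len(sig)
    false_pos = int((sig["theta"] == 0).sum())
    evidence = merged[merged["causal_evidence"]]
    return {
        "n_analyzed": len(merged),
        "n_significant": n_sig,
        "empirical_fdr": false_pos / n_sig if n_sig else 0.0,
        "power": float((causal["tier"] == "significant").mean()) if len(causal) else float("nan"),
        "causal_evidence_count": len(evidence),
        "causal_evidence_precision": (
            float((evidence["theta"] != 0).mean()) if len(evidence) else float("nan")
        ),
        "causal_evidence_recall": (
            float(causal["causal_evidence"].mean()) if len(causal) else float("nan")
        ),
    }
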