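# protmr

Proteome-wide causal inference from GWAS summary statistics: does genetically
predicted protein abundance (brain or blood cis-pQTLs) causally influence a
complex outcome such as suicide attempt? `protmr` implements the full
screening pipeline — cis-instrument selection, two-sample Mendelian
randomization with five estimators, Steiger directionality filtering,
Bayesian colocalization, FUSION-style PWAS, FDR tiering and cross-tissue
comparison — together with a synthetic summary-statistics generator so every
stage is testable against known ground truth. It is written for
statistical-genetics practitioners who work with summary-level pQTL and GWAS
data rather than individual-level genotypes.

## The statistics in brief

For each protein, instruments are cis variants (within ±10 Mb of the coding
gene) with p < 5×10⁻⁸ and F = (β/se)² > 10, greedily LD-clumped (r² < 0.2
within 10,000 kb; a strict r² < 0.001 mode gives effectively independent
instruments). After aligning exposure and outcome effect alleles (palindromic
A/T and C/G variants dropped), the causal log-odds per SD of protein
abundance θ is estimated by:

- **Wald ratio** (k = 1): θ̂ = β_gy/β_gx, se = se_gy/|β_gx|;
- **IVW** (k ≥ 2): inverse-variance weighted mean of Wald ratios, fixed
  effects unless Cochran's Q is significant, then multiplicative random
  effects with inflation max(1, √(Q/(k−1)));
- **maximum likelihood**: joint-normal likelihood with the per-instrument
  true exposure effects profiled out;
- **MR-Egger** (k ≥ 3): weighted regression with an intercept; the intercept
  estimates directional pleiotropy;
- **weighted and penalized weighted median**: robust to a minority of
  invalid instruments, the penalized form down-weighting outliers by their
  χ²₁ heterogeneity tail.

Steiger filtering checks that instruments explain more variance in the
protein than in the outcome (r² = F/(F+n−2) from the association p-value,
compared by Fisher-z). Colocalization uses per-SNP Wakefield approximate
Bayes factors, lABF = ½[log(1−r) + r·z²] with r = W/(V+W), combined into
posterior probabilities of the five standard hypotheses (H4 = shared causal
variant; "colocalized" means PPH4 > 75%). PWAS combines GWAS z-scores with
cis protein weights as z = wᵀz/√(wᵀRw) under the local LD matrix R. Proteins
are tiered significant (FDR < 0.05), suggestive (p < 0.001) or null, and a
protein carries full causal evidence only when it is significant,
directionally correct and colocalized.

## Worked example

```python
from protmr import (ScenarioConfig, StudyConfig, simulate_proteome_benchmark,
                    run_pipeline, evaluate_against_truth)

regions, truth = simulate_proteome_benchmark(
    100, 0.05, ScenarioConfig(m_snps=60), seed=1)
out = run_pipeline({"brain": regions}, StudyConfig(seed=1, clump_r2=0.001))
sig = out["results"][out["results"]["tier"] == "significant"]
print(sig[["protein_id", "n_snps", "or_", "pvalue", "fdr_q",
           "steiger_direction", "pph4", "causal_evidence"]].to_string())
print(evaluate_against_truth(out["results"], truth))
```

prints (seed 1):

```
   protein_id  n_snps       or_        pvalue         fdr_q steiger_direction      pph4  causal_evidence
3       P0004       3  0.778230  2.443233e-46  1.221617e-44           correct  1.000000             True
45      P0046       2  0.822653  1.518219e-31  5.060730e-30           correct  1.000000             True
49      P0050       3  1.309976  1.547024e-66  1.547024e-64           correct  0.999999             True
74      P0075       3  0.740160  2.732663e-08  5.465327e-07           correct  1.000000             True
94      P0095       3  0.809354  5.734443e-19  1.433611e-17           correct  1.000000             True
{'n_analyzed': 100, 'n_significant': 5, 'empirical_fdr': 0.0, 'power': 1.0, 'causal_evidence_count': 5, 'causal_evidence_precision': 1.0, 'causal_evidence_recall': 1.0}
```

All five truly causal proteins (and nothing else) are recovered: protective
proteins (OR < 1) and risk proteins (OR > 1) match the simulated signs, every
call is Steiger-correct and colocalized (PPH4 ≈ 1), and the empirical FDR is
zero at this seed.

The numbered scripts under `analysis/` run this study end to end — benchmark
generation, instrument audit, the relaxed vs strict clumping contrast, truth
scoring, and cross-tissue/replication comparison — writing their tables under
`results/`.

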