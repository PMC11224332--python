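# Methods

This note documents the statistical model behind `protmr`, the conventions
and numerical choices its estimators use, what the synthetic-data generator
does and does not emulate, and the problem sizes of the evaluation studies.

## Two-sample MR model and conventions

Per instrument j the observed summary statistics are the marginal exposure
effect β̂_gx,j (per SD of protein abundance) with SE s_x,j and the marginal
outcome effect β̂_gy,j (log-odds per allele) with SE s_y,j, both on the
exposure's effect-allele convention after harmonization. Under the
instrumental-variable assumptions the causal effect θ (log-OR per SD of
protein) satisfies β_gy = θ·β_gx.

- **Ratio SEs** use the first-order delta approximation se_j = s_y,j/|β̂_gx,j|
  (second-order term omitted); all oracle tests and reference
  implementations assume the same convention.
- **IVW** is the 1/se² -weighted mean of Wald ratios, algebraically identical
  to weighted least squares of β̂_gy on β̂_gx through the origin with weights
  1/s_y². `model='auto'` switches from fixed to multiplicative random
  effects when Cochran's Q has p < 0.05 (the switch point is a config knob);
  the random-effects SE is the fixed SE times max(1, √(Q/(k−1))), never
  deflated below the fixed-effects level.
- **MR-Egger** orients instruments so β̂_gx ≥ 0 (flipping both signs jointly),
  regresses with weights 1/s_y², and floors the residual variance factor at
  1. Slope and intercept p-values use the t distribution with k−2 df.
- **Weighted median** sorts ratios, forms breakpoints s_j = Σ_{k≤j} w′_k −
  w′_j/2 from normalized weights, and interpolates linearly at 0.5. The
  penalized variant multiplies each weight by min(1, 20·p_j) where p_j is
  the upper χ²₁ tail of Q_j = w_j(ratio_j − θ_wm)², then recomputes the
  median. SEs come from a parametric bootstrap (default 1000 replicates,
  seed-deterministic) that resamples β̂_gx and β̂_gy from their sampling
  normals; outcome noise is drawn in antithetic pairs so the bootstrap SE is
  exactly invariant under negating all outcome effects.
- **Maximum likelihood** maximizes the joint normal likelihood over (θ, ξ)
  with the true exposure effects ξ profiled out in closed form,
  ξ_j = (β̂_gx,j/s_x,j² + θβ̂_gy,j/s_y,j²)/(1/s_x,j² + θ²/s_y,j²); θ is found
  by bounded 1-D minimization started at the IVW estimate (xatol 1e-12) and
  the SE is the inverse square root of the numerically differentiated
  profile information. A single instrument is permitted and reduces to the
  Wald ratio.
- **Dispatch**: k=1 → Wald only; k=2 → IVW + ML; k≥3 adds Egger and the two
  medians. The primary estimate (entering FDR) is Wald/IVW.
- Instruments are treated as independent after clumping; correlated-
  instrument IVW is deliberately out of scope (see Limitations).

## Instrument selection

Cis windows are closed intervals gene_start − 10 Mb .. gene_end + 10 Mb on
1-based coordinates. Selection requires p < 5×10⁻⁸ (strict) and F > 10
(strict), with F = (β/se)², the standard single-SNP strength proxy. Greedy
clumping iterates candidates by ascending p (ties broken by variant ID),
keeps the best as an index SNP and removes candidates within the 10,000 kb
window whose r² with the index is ≥ the threshold, so the surviving set
satisfies r² < threshold; the distance window is anchored on the index SNP.
The default threshold is 0.2 (the screening setting); 0.001 gives
effectively independent instruments (the replication setting). Variants
significantly associated with more than five proteins are excluded as
pleiotropy risks; the offline confounder screen annotates instruments with
trait hits but never removes them (a screening-then-judgement step).

## Steiger directionality

Variance explained per instrument is recovered from the association p-value
as r² = F/(F + n − 2) with F the 1−p quantile of F(1, n−2) (computed as a
squared t quantile, which stays finite far into the tail where the direct F
inverse overflows), summed over clumped instruments under the independence
approximation; the sum is capped just below 1 because very strong
multi-signal regions can overshoot. Binary outcomes use the same pseudo-r²
with total N — no liability-scale adjustment. The exposure and outcome r²
are compared with a Fisher-z test on the implied correlations; direction is
"correct" iff r²_exposure strictly exceeds r²_outcome.

## Colocalization

Per-SNP Wakefield log-ABFs use effect estimates and variances directly
(never p-value+MAF reconstruction). Prior effect SDs default to 0.15 for
quantitative traits and 0.2 for binary traits; hypothesis priors default to
p1 = p2 = 1e-4, p12 = 1e-5. All hypothesis sums are carried in log space;
the distinct-variant sum uses Σ_{j≠k} = (Σ_j)(Σ_k) − Σ_j(both) evaluated
stably with log1p, exactly zero for single-SNP regions. Posteriors are a
softmax of the five log weights and sum to one to machine precision.
Colocalization is declared at PPH4 > 0.75 (strict inequality).

## PWAS

z_PWAS = wᵀz/√(wᵀRw) over the weight-supported SNPs, with a 1e-6 ridge on
R's diagonal to stabilize near-collinear weights (configurable). Weight
training is out of scope; weights are inputs.

## FDR tiering and reporting

The primary MR p-values are adjusted within tissue. The default is
Benjamini–Hochberg (deterministic, well-behaved at proteome sizes of a few
hundred); an empirical-null option estimates the null proportion π₀ from the
p-value mass above 0.5 (Storey-type) and scales the BH tail area —
two-component mixture fitting is unstable for small proteomes, hence the
deterministic default. Tiers: significant iff FDR < 0.05, else suggestive
iff p < 0.001, else null. A protein has `causal_evidence` only when it is
significant, Steiger-correct and colocalized; this conjunction is asserted
on every report row.

## The synthetic-data generator

Summary statistics are simulated at the marginal-effect level (no
genotypes). A region has m SNPs with AR(1) LD r_ij = ρ^|i−j|; sparse causal
per-allele effects γ (all positive — the effect allele is oriented to the
protein-increasing allele — with magnitudes s·U(1−j, 1+j)) give true
marginal exposure effects b_x = Rγ, and observed effects add correlated
noise se·L·z with L the Cholesky factor of R, so simulated z-scores
reproduce R across replicates. Outcome effects are θ·b_x (causal_shared),
zero (null), driven by a separate variant (distinct_variants, θ = 0), or
θ·b_x + Rα with α ~ N(μ_α, σ_α²) independent of γ (pleiotropy, an
InSIDE-style violation). Binary-outcome SEs use the case-fraction variance
inflation 1/√(n·cf·(1−cf)); exact logistic sampling is not attempted.

Default conditions: n_exposure = 30,000 (a deCODE-scale plasma pQTL study),
n_outcome = 500,000 with 5% cases (a suicide-attempt-scale GWAS),
θ = −0.17 (a GLRX5-scale protective log-OR), s = 0.25 with jitter j = 0.9
(per-allele effects 0.025–0.475 SD; the wide spread keeps MR-Egger's
regression-dilution bias negligible while the weakest instruments remain
relevant at z ≈ 4), three causal cis signals per region, ρ = 0.6,
pleiotropy μ_α = 0.02, σ_α = 0.01, distinct-variant direct effect 0.05.
Setting jitter = 0 gives fixed-magnitude effects for controlled
single-causal-variant colocalization scenarios. One global seed drives
everything; per-region substreams are fixed offsets so each region is
independently reproducible.

What the generator does **not** emulate: realistic MAF spectra (genotypes
are implicitly standardized), population stratification, sample overlap
between studies, multi-population LD, allele-frequency mismatch between
datasets, and liability-scale effects. Passing tests therefore demonstrate
the statistical machinery is correct under its stated assumptions, not that
those assumptions hold in any particular real dataset.

## Evaluation studies and problem sizes

All studies live in `protmr.evaluation` and are driven by one seed; the test
suite asserts on them at seed 0 and `scripts/acceptance.py` reports them.

- **Oracle equivalence**: 300 random instrument sets (IVW vs WLS through the
  origin; Egger vs explicit normal equations; vectorized medians vs a scalar
  two-pass loop), 1000 random ≤8-SNP clumping instances vs a direct
  transcription of the rule, 200 random ≤20-SNP regions (|z| ≤ 6) for
  log-space vs linear-space colocalization. Agreement to 1e-10.
- **Parameter recovery**: 500 replicates of 50 independent instruments at
  the default sample sizes, θ = −0.17. IVW/ML/weighted-median means are
  required to sit within 2× the Monte-Carlo SE of θ. The Egger intercept is
  compared to its analytic first-order expectation under noisy exposure
  effects, θ·x̄·s_x²/(var(b_x)+s_x²) ≈ −8×10⁻⁵ (and μ_α plus that offset
  under directional pleiotropy) within 3× MC-SE, plus an absolute bound of
  0.05·μ_α — the attenuation term is a property of finite instrument
  strength (NOME violation), two orders of magnitude below the pleiotropy
  signal the intercept test exists to detect.
- **Calibration**: 2000 null Wald p-values (KS uniformity at α = 0.01), 1000
  IVW replicates for 95% CI coverage (0.95 ± 0.02), 2000 null PWAS draws
  (KS normality at α = 0.01).
- **Scenario discrimination**: 500 strong shared-variant replicates
  (single causal variant, jitter 0, θ = 0.3) require PPH4 > 0.9 in ≥ 90%;
  500 distinct-variant replicates require H3 dominant; posteriors sum to 1
  to 1e-10.
- **Steiger**: 500 causal regions at default sizes; direction correct in
  > 95%.
- **End-to-end benchmark**: 20 proteomes of 100 proteins (5 causal each,
  |θ| ~ U(0.15, 0.35)), analysed at the strict r² < 0.001 instrument
  setting; pooled empirical FDR ≤ 0.10, power ≥ 0.8, and the
  causal-evidence conjunction on every row.
- **Worked examples**: the bundled per-protein candidate table
  (`protmr/data/candidate_proteins.tsv`) is re-classified with the
  package's own PPH4 and FDR rules, reproducing its marginal counts
  (3 colocalized; 10 brain and 1 blood significant; 8 protective vs 2 risk
  brain proteins; 3 proteins with full causal evidence).

## Design choices made where the design was open

- Palindromic variants are always dropped rather than frequency-aligned;
  consequently harmonization never needs allele frequencies.
- Non-palindromic variants are matched allowing complement-strand codings.
- No allele-frequency concordance filter is applied between datasets.
- The confounder screen annotates rather than deletes.
- FDR is computed within tissue, and the p-value entering FDR is always the
  primary (Wald/IVW) p.
- The FDR/power benchmark uses the strict independent-instrument setting:
  relaxed r² < 0.2 clumping leaves residual LD (pairwise |r| up to ~0.45)
  that inflates null IVW z-scores by ~20% under ρ = 0.6, a known cost of
  relaxed clumping that the strict replication setting exists to remove
  (`analysis/03_mr_screen.py` shows the contrast: at one seed the relaxed
  screen makes 10 significant calls of which 5 are truly null, the strict
  screen exactly the 5 causal proteins).

## Known limitations

- Instruments are assumed independent after clumping; no generalized
  (correlated-instrument) IVW, MR-PRESSO, mode-based or multivariable MR.
- The colocalization model assumes at most one causal variant per trait per
  region (no SuSiE-style multi-signal decomposition).
- Steiger r² for binary outcomes ignores the liability scale.
- The bootstrap SE for medians is parametric; no LD-aware resampling.
- Synthetic data only; see the generator caveats above for what green tests
  do and do not establish about real pQTL/GWAS data.
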