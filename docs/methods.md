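# Methods note

This note records the statistical model, the generator's design and
parameter choices, what the simulation emulates of a sequence-scale
livestock heritability-partitioning study and what it deliberately does not,
and the numerical decisions embedded in the estimators. It is the companion
to the test suite: every analytic claim here has a corresponding oracle or
property test in `tests/`.

## 1. Model

Phenotypes follow the standard multi-component animal model

    y = 1 μ + Σ_s g_s + e,     g_s ~ N(0, G_s σ²_s),     e ~ N(0, I σ²_e)

with one genetic component per annotation group `s` of a disjoint,
exhaustive variant partition. The estimand is the percentage of SNP
heritability per group, `%h²(s) = 100 σ²_s / Σ_t σ²_t`, and its heritability
enrichment, `(%h²(s)/100) / (m_s/m)` where `m_s/m` is the group's variant
fraction.

Two partition **designs** are supported: MC (one component per functional
class) and TC (focal class vs everything else), each in **noLDMS** (classes
only) or **LDMS** form (each class further split by MAF bin × LD-score
quartile, up to 4 × 3 cells per class, empty cells dropped — at most 24
groups for a TC design).

## 2. Population generator (`synthpop`)

**Founder haplotypes.** Variant positions are uniform on the chromosomes;
per-variant allele frequencies are drawn from a Beta(α, α) spectrum
(default α = 1). LD is induced by a copy-with-mutation chain along each
haplotype: a latent uniform U is carried from the previous variant with
probability exp(−d / scale) (d = bp distance, scale from an exponential
with mean `ld_block_mean_kb` = 50 kb) and redrawn otherwise; the allele is
`U < p_j`. This yields block-structured LD whose decay matches the carry
probability (verified against a two-site closed-form oracle in
`tests/test_synthpop.py`). Regional LD-scale heterogeneity — log-normal
multipliers (log10 SD 0.6) per ~5 Mb region — makes LD-score quartiles
reflect genuine regional structure rather than pure sampling noise, which
is a premise of any LD-stratified analysis; it was added as structural
realism, not tuned to any result.

**Pedigree.** Gene dropping through a half-sib-heavy livestock design:
per generation `n_sires` (default 25) and `n_dams` (default 500) are drawn
from the previous generation, each dam has `offspring_per_dam` (default 3)
offspring with a randomly assigned sire; meioses place Poisson crossovers
at 1 cM/Mb. Default two generations from 1,100 founders give ~1,500
genotyped individuals with the strong paternal half-sib blocks
characteristic of cattle populations (mean half-sib GRM entry ≈ 0.25,
verified in tests). Variants with MAF < 0.01 in the final panel are removed
(default), as is standard before GRM construction.

**Genome layout.** Genes (with CDS/UTR exon structure and UDR flanks) and
open-chromatin peaks are placed to match target genome-proportion table
{OCR 0.1061, IGR 0.5335, IOR 0.3014, UDR 0.0529, CDS 0.0056, UTR 0.0005};
peak placement uses a Poisson-coverage correction (λ = −ln(1 − target
fraction)) so realized OCR span matches the target despite overlaps.
Variant classes follow the precedence OCR > CDS > UTR > UDR > IOR > IGR.

**What is emulated, what is not.** The generator reproduces, at desk scale
(~1,500 × ~18,000 rather than 14,762 × 965k): half-sib pedigree structure,
block LD with regional heterogeneity, a realistic class-proportion
annotation, and exact-variance phenotype architectures. It does **not**
reproduce: sequence-level marker density, class-specific MAF/LD composition
(peaks and genes are placed independently of the allele-frequency and LD
landscape, so e.g. OCR variants have the same LD-score distribution as IGR
variants), selection signatures, or real recombination maps. Consequences
of the symmetric layout are discussed in §6.

## 3. Annotation (`annotate`)

LD scores are Σ r² over variants within ±200 kb on the same chromosome,
**including the self term** (so an isolated variant scores 1.0); r is the
Pearson correlation of dosages. Monomorphic neighbors contribute 0. MAF
bins are (0.01, 0.05], (0.05, 0.10], (0.10, 0.50] (panel entry requires the
MAF > 0.01 filter; rarer input raises). LD quartile bins are
`1 + (s > q25) + (s > q50) + (s > q75)` with quantiles from
`np.quantile` — ties at a boundary all fall in the lower bin, and a
degenerate all-equal score vector collapses to bin 1.

## 4. GRMs (`grm`)

Two scaling rules: "yang" (equal contribution), `w_ij = (x_ij − 2p_j) /
sqrt(2 p_j (1−p_j))`, `G = W W' / m`; and "vanraden1" (proportional
contribution), `G = C C' / Σ 2 p_j (1−p_j)` with `C` the centered dosages.
Allele frequencies are always re-estimated from the panel being used.
Zero-variance dosage columns (including the monomorphic p ∈ {0,1} case and
the pathological all-heterozygote column) are dropped as uninformative.
Additivity across a partition (weighted average of group GRMs equals the
all-variant GRM) is verified to 1e-8.

## 5. Phenotype simulator (`phenosim`)

Causal counts per class are proportional to target variance shares
(`m_s ∝ t_s`). Effects are drawn either with equal per-variant variance
after standardization (`N(0, [2p(1−p)]⁻¹)` on the dosage scale, the "yang"
rule's implicit architecture) or MAF-independent `N(0,1)`. Genetic values
use centered dosages (centered at 2p̂ from the panel). Every replicate is
**exactly** rescaled: each class's realized genetic variance is set to
`t_s/100` and the residual is rescaled so the realized h² equals the target
exactly — so the simulation truth is never subject to Monte-Carlo error in
the architecture itself, only in which variants are causal. MAF/LD
enrichment scenarios put 60% of each class's causal variants inside the
stratum (low-MAF ≤ 0.05, high-MAF > 0.20, low-LD = quartile 1, high-LD =
quartile 4) and 40% outside, mirroring a 3000/2000 split at full scale.

Built-in scenarios: `ocr50_scenario` (OCR share 50%, rest 50%),
`complex_scenario("I"|"II"|"III")` with six-class share tables (e.g. III:
CDS 50, IOR 20, UDR 10, OCR 20), `single_class_scenario`, and
`no_enrichment_scenario` (shares equal to variant fractions). Defaults
h² = 0.5 (0.7 for complex scenarios) and causal counts scaled to panel size
(200 for OCR-50, 100 for complex) are study conditions, fixed before any
estimator was run on them.

## 6. GREML (`greml`)

REML with the intercept profiled out: the objective is
`−½ [log|V| + log(1'V⁻¹1) + y'Py]` with `P = V⁻¹ − V⁻¹1(1'V⁻¹1)⁻¹1'V⁻¹`.
This equals the error-contrast likelihood up to an additive constant
(verified against an independent QR-null-space oracle to 1e-8).

Optimization: variance components are initialized by equal split of the
sample variance; one EM step opens the fit (EM is globally stable),
then average-information Newton steps — AI matrix `½ y'P G_k P G_l P y`,
gradient `−½ [tr(P G_k) − y'P G_k P y]` — with step-halving (max 10) when a
step would leave the positive region or decrease the likelihood, and a
variance floor of `1e-6 × var(y)`. Convergence: relative log-likelihood
change `< 1e-4` (default). If AI fails to converge within `max_ai = 100`
iterations, the fit restarts with pure EM (`max_em = 500`, monotone). A fit
never raises on non-convergence; it returns `converged=False` with the full
likelihood trace. Small-problem fits are verified against dense grid
searches of the restricted likelihood.

## 7. BayesRR-RC (`bayesrrc`)

Per annotation group: a spike at zero plus three Gaussian components with
variances (0.0001, 0.001, 0.01) · σ²_s, mixture probabilities with a
Dirichlet(1,…,1) prior, group variances σ²_s and residual σ²_e with
scaled-inverse-χ² priors (ν₀ = 4, scale s₀ = 0.5·var(y)/S for groups,
0.5·var(y) for the residual). Columns are standardized; monomorphic columns
are dropped and mapped back as permanent spikes. The Gibbs kernel (numba
`njit`, single `np.random.seed` stream inside the kernel — the variant
update order is a fresh permutation per sweep drawn from that same stream,
rather than from a separate order seed; one stream keeps the kernel bitwise
reproducible with a single integer) maintains the residual incrementally
and per-group genetic values. Component indicators are drawn from log
weights `log π_l − ½ log1p(x'x ω_l/σ²_e) + r̃²/(2σ²_e(x'x + σ²_e/ω_l))`.
Posterior %h² is computed per draw from the realized variance of each
group's genetic value (`Var(X_s β_s)`), not from σ²_s — the hyper-parameter
overstates the contribution of groups whose non-spike mass is rare. The
sampler is verified against the closed-form single-variant conjugate
posterior (mean and second moment within 2% over 20,000 draws) and against
degenerate-prior exact behaviors. Numerical floors: variances clipped at
1e-12.

## 8. Evaluation (`evalsuite`)

Replicate seeds derive from `SeedSequence([master, rep])` reduced mod
2³¹−1 (all derived seeds fit the 32-bit kernels). `run_scenario` caches
GRM sets per (mode, design, focal, rule, method) and fits each replicate
independently; summaries (mean, median, SD, quantiles, bias, RMSE,
convergence counts) are computed over converged replicates, with
non-convergence tallied rather than silently dropped. For TC designs the
"rest" truth is `100 − truth[focal]`.

## 9. Reduced scale and the directional-bias findings

Desk scale (~1,500 × ~18k, replicate counts 20–50) keeps the full
acceptance run inside a ~25-minute single-CPU budget. Three directional
findings were checked at this scale:

- **Overcounting in TC designs**: the sum of focal shares across TC fits of
  the six classes exceeds 100% with positive mean bias (measured sums
  109–112% across the complex scenarios) — reproduced, driven by the same
  GRM confounding as at full scale (off-diagonal GRM correlations between
  class GRMs measured at 0.54–0.97).
- **Small classes have the noisiest enrichment**: reproduced (the smallest
  class shows the largest enrichment SD under a no-enrichment architecture).
- **LD-stratification rescuing low-LD enrichment bias** does **not**
  reproduce at this scale and its test is expected to fail: with the layout
  placing annotations independently of the LD landscape, low-LD causal
  enrichment applies symmetrically inside and outside the focal class, so
  the unstratified two-component share is already unbiased (measured
  bias ≈ 0 ± 3.4 SE), while the 24-component LDMS fit at n = 1,500 is
  itself downward-biased because tiny focal × MAF × LD sub-GRMs are
  noise-dominated and their variance leaks to the large pedigree-correlated
  rest groups. Reproducing the full-scale pattern would require
  class-specific LD/MAF composition at sequence density; we declined to
  engineer that asymmetry into the generator after seeing the test outcome,
  and the test is kept at its stated conditions, failing honestly.
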