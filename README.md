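# hpart — heritability partitioning by functional annotation, evaluated by simulation

`hpart` is a self-contained simulation laboratory for asking a question that
matters in livestock (and human) genetics: **when we partition SNP
heritability across functional genome annotations, can we trust the
estimates?** Functional classes such as open chromatin regions (OCRs) or
coding sequence (CDS) cover small fractions of the genome; if variants in
those classes explain a disproportionate share of a trait's genetic variance
("heritability enrichment"), that is evidence of regulatory or coding
causality. But the estimators used to measure this — multi-component GREML
and Bayesian mixture regressions — face strong linkage disequilibrium (LD)
and close pedigree relationships in livestock populations, which can bias or
destabilize the partition. This package simulates populations with known
architecture and measures how well the estimators recover it.

## What the package does

1. **Simulate a livestock-like population** (`hpart.synthpop`): founder
   haplotypes are generated by a copy-with-mutation chain that produces
   block-structured LD with regionally heterogeneous LD scale, then dropped
   through a half-sib-heavy pedigree (few sires, many dams) with Poisson
   recombination. A genome layout places genes and open-chromatin peaks and
   assigns every variant one of six functional classes — OCR, CDS, UTR, UDR
   (up/downstream gene flanks), IOR (introns), IGR (intergenic) — by
   precedence OCR > CDS > UTR > UDR > IOR > IGR, with class genome
   proportions matching a cattle-like annotation (OCR ≈ 10.6%, CDS ≈ 0.6%,
   …).
2. **Annotate** (`hpart.annotate`): per-variant LD scores (sum of r² within
   ±200 kb, including the self term), MAF bins ((0.01,0.05], (0.05,0.10],
   (0.10,0.50]), LD-score quartile bins, and partition builders for every
   estimator design: MC (one component per class) or TC (focal class vs
   rest), each optionally LD-and-MAF-stratified (LDMS, up to 4 LD × 3 MAF
   cells per class).
3. **Genomic relationship matrices** (`hpart.grm`): per-partition-group GRMs
   under the equal-contribution ("yang", centered and per-variant
   standardized) or proportional-contribution ("vanraden1") scaling rules.
4. **Simulate phenotypes with known partition** (`hpart.phenosim`): causal
   variants drawn per class in proportion to target variance shares
   (optionally concentrated in low-MAF or low/high-LD variants), effect sizes
   under either an equal-per-variant-variance or MAF-independent rule, with
   exact per-replicate rescaling so every class's genetic variance and the
   total h² hit their targets exactly.
5. **Estimate** with two method families:
   - `hpart.greml`: multi-component REML via average-information (AI)
     updates with an EM opener and EM fallback; profiled intercept; returns
     variances, %SNP heritabilities, the likelihood trace and convergence
     status.
   - `hpart.bayesrrc`: BayesRR-RC — a spike plus three Gaussian mixture
     components per annotation group, variances (0.0001, 0.001, 0.01)·σ²_s,
     fit by conjugate Gibbs sampling (numba-compiled kernel, bitwise
     reproducible). Posterior %SNP heritability is computed from the
     realized genetic variance of each group per draw, not from the
     hyper-parameters.
6. **Evaluate** (`hpart.evalsuite`): replicate runners with seeded,
   independent replicates; bias/RMSE/coverage-style summaries; heritability
   enrichment (share divided by variant fraction); estimated-vs-true
   regressions.
7. **I/O + CLI** (`hpart.io`, `hpart.cli`): PLINK bed/bim/fam and GCTA
   binary GRM codecs, GTF/BED interval readers and writers, annotation and
   phenotype tables, and a `hpart` command-line pipeline
   (`simulate-genotypes`, `annotate`, `simulate-phenotypes`, `fit-greml`,
   `fit-bayes`, `run-scenario`, `report`) with provenance JSON next to every
   output.

The model in standard notation: phenotypes follow

```
y = 1μ + Σ_s g_s + e,   g_s ~ N(0, G_s σ²_s),   e ~ N(0, I σ²_e)
```

where `G_s` is the GRM built from the variants of annotation group `s`. The
quantity of interest is the percentage of SNP heritability attributed to
class `s`:

```
%h²_SNP(s) = 100 · σ²_s / Σ_t σ²_t
```

and its enrichment is `%h²_SNP(s) / 100` divided by the fraction of variants
in `s`.

## Worked example

A small end-to-end run — simulate a half-sib population, annotate it, plant
a phenotype in which OCR causal variants carry 50% of the genetic variance,
and ask the two-component GREML to find it:

```python
import numpy as np
from hpart import synthpop as sp, annotate as an, grm as gm, greml as gr, phenosim as ps
from hpart.evalsuite import class_shares_from_fit

# 1. simulate a half-sib-heavy population with LD-structured variants
pool = sp.simulate_founder_haplotypes(
    n_founders=330, n_variants=6000, chrom_lengths=[30_000_000, 30_000_000],
    seed=11,
)
panel = sp.gene_drop(pool, n_generations=2, n_sires=8, n_dams=150,
                     offspring_per_dam=3, seed=12)
print(f"panel: {panel.n_individuals} individuals x {panel.n_variants} variants")

# 2. lay out a genome annotation and classify every variant
layout, classes = sp.layout_genome(panel, seed=13)
annotation = an.annotate_panel(panel, functional_class=classes)
fracs = annotation.class_fractions()
print("class fractions:", {k: round(float(v), 3) for k, v in sorted(fracs.items())})

# 3. simulate a phenotype where OCR causal variants carry 50% of genetic variance
scenario = ps.ocr50_scenario(m_causal=120, h2=0.5)
y, causal = ps.assemble_phenotypes(panel, annotation, scenario, seed=14)

# 4. fit the two-component GREML (OCR vs rest)
partition = an.make_partition(annotation, mode="noLDMS", design="TC", focal="OCR")
grms = gm.build_grms(panel, partition, rule="yang")
fit = gr.fit_greml(y, grms)
shares = class_shares_from_fit(partition, fit.variances)
print(f"converged: {fit.converged} ({fit.algorithm}), h2 = {fit.h2:.3f}")
print("estimated %SNP-h2:", {k: round(v, 1) for k, v in shares.items()})
```

Output (exactly as printed):

```
panel: 450 individuals x 4809 variants
class fractions: {'CDS': 0.007, 'IGR': 0.542, 'IOR': 0.285, 'OCR': 0.112, 'UDR': 0.053, 'UTR': 0.001}
converged: True (AI), h2 = 0.513
estimated %SNP-h2: {'OCR': 53.7, 'rest': 46.3}
```

The true OCR share is 50%; a single replicate lands within sampling noise of
it, and replicate averages (see below) converge on the truth. With ~11% of
variants in OCR, an estimated 53.7% share corresponds to a ~4.8-fold
heritability enrichment.

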