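# Methods

## Model

The prediction engine is single-trait GBLUP: `y = Xb + u + e` with
`u ~ N(0, G σu²)`, `e ~ N(0, I σe²)`, fixed effects restricted to an
intercept plus contemporary-group (CG) dummies (first level, sorted, as
reference). `G` is the VanRaden method-1 relationship matrix built from
0/1/2 dosages centered at twice the allele frequency and scaled by
`k = 2 Σ p(1−p)`; missing calls are imputed to `2p` (zero contribution to
relationships). Whenever animals outside the training set are scored,
centering uses *training* frequencies — SNP effects are estimated on the
training scale and must be applied on it.

Assumptions worth keeping in mind: purely additive gene action, equal
prior variance for every marker (`D = I`; no weighted GRM), homogeneous
residual variance, and a single round of estimation (no iterated SNP
weighting).

### REML

Variance components are estimated by AI-REML in the eigenbasis of `G`
(one `O(n³)` decomposition, then `O(n p²)` per iteration). Each iteration
proposes the average-information Newton step; if the step leaves the
parameter space or lowers the restricted likelihood, a multiplicative
fixed-point (EM-style) update is tried, then damped AI steps. Accepted
iterations never decrease the likelihood; the path is recorded.
Convergence: relative change of both components `< 1e-8` or score norm
`< 1e-6`, max 200 iterations. A `σu²` proposal below `1e-8·Var(y)` is
pinned at that floor; persisting there sets `boundary=True` and reports
`h² = 0`. Standard errors come from the inverse AI matrix at the optimum,
`se(h²)` by the delta method — internally consistent, but not guaranteed
to match any other package's AI matrix to the digit.

### SNP effects, GWAS, prediction

Backsolving `â = (1/k) M′G⁻¹û` is the exact dual of ridge (SNP-BLUP) with
penalty `kλ`, `λ = σe²/σu²`, when `G` is unregularized and full rank; a
test pins this equivalence at 1e-6 relative error. Per-SNP sampling
variances use `Var(û) = σu²G − σe²C²²` (`C²²` = u-block of the inverse
mixed-model coefficient matrix) pushed through the backsolving transform;
two-sided normal p-values follow. Non-positive variances after numerical
error yield `p = 1` plus a per-SNP warning flag. Rankings order by
−log₁₀(P) with ties broken by (chromosome, position, id), so they are
platform-reproducible. GEBVs for new animals are `Σ (x − 2p) â` over the
panel, matching SNPs by (id, allele pair); swapped alleles flip the
dosage, anything else is rejected rather than guessed. Fixed effects are
never added to external GEBVs: all metrics operate on centered GEBVs
versus adjusted phenotypes.

The mixed-model equations are solved densely (Cholesky); the GRM is
blended `0.99 G + 0.01 I` by default before inversion. The blend
guarantees positive definiteness with negligible shrinkage; set it to 0
only on instances known to be full rank.

## Study design

Cross-validation stratifies folds by CG (shuffle within CG, deal
round-robin with a rotating starting fold), guaranteeing per-CG fold
loads within 1 of each other. Per replicate × fold, REML, the GWAS
ranking, and all SNP-effect refits use training folds only — a dedicated
test corrupts held-out phenotypes and asserts the training artifacts are
bit-identical. For each panel (full, top-k, random-k replicates) the
SNP effects are refit on the training folds with the fold's variance
components and the fold-training allele frequencies; panel SNPs
monomorphic in training are dropped with a warning and the realized size
recorded.

Choices made where the design was genuinely open:

- **Accuracy denominator**: training-fold ĥ² for CV cells, full-training
  ĥ² for external validation. When a fold's REML lands on the `σu² = 0`
  boundary the accuracy is undefined and the cell is flagged (the slope,
  which needs no h², is still reported).
- **Phenotype adjustment**: CG residuals are fitted once on the whole CV
  population (CG is shared nuisance structure); `adjust_scope="per_fold"`
  switches to training-fold-estimated CG solutions. External phenotypes
  are adjusted for harvest year on the external cohort.
- **Correlation type**: Spearman everywhere (Pearson by option), for
  symmetry between CV and external validation.
- **Random panels** are redrawn per (replicate, fold) from the same
  post-QC SNP universe as the ranked panels; every draw's seed derives
  from the master seed by a fixed spawn-key scheme, so any single cell
  can be re-run independently and reproduces its record bit-identically
  (`run_cv_cell`).
- **Accuracy values** beyond ±1 are reported unclipped — the estimator
  permits them at finite sample size.
- **QC order**: samples first (call rate < 0.90), then SNPs (non-autosomal,
  call rate < 0.90, MAF < 0.05, in that priority) computed on the retained
  samples; MAF exactly at the threshold is kept (strict "less than"). One
  pass each, no iteration.

## The synthetic generator

`simulate_dataset` emulates the study populations rather than any real
genotypes. Two founder breeds get Balding–Nichols allele frequencies
around `p0 ~ U(0.05, 0.95)` at differentiation `fst = 0.2` (divergent
*taurus/indicus*-like founders). Each animal draws an admixture
proportion α uniformly from its cohort's range — training (0.6, 0.8),
emulating a composite breed with a narrow admixture spectrum; external
(0, 1), a broad resource population — and genotypes are
`Binomial(2, α p_A + (1−α) p_B)` per SNP, 10 chromosomes of contiguous
positions. Defaults: 1000 training / 300 external animals, 5000 SNPs,
32 CGs (contiguous blocks ≥ 5 animals), CG and year effects
`N(0, 0.5²)` in phenotypic-SD units.

Traits: background effects iid normal on `n_causal` random SNPs
(polygenic: 500 causal, h² 0.52; major-QTL: 300 causal plus one locus
with sample MAF ≥ 0.15 sized to carry 30% of the genetic variance at
h² 0.34 — large enough that the architecture contrast is visible at
n = 1000, while single-locus estimates for the real tenderness genes sit
near 4–5%). Noise is calibrated against the *realized* genetic variance,
then everything is rescaled to unit phenotypic variance, so `cg_sd` reads
in phenotypic SDs and realized h² tracks the target within ±0.05 at
n ≥ 1000. The same effects generate external phenotypes.

The `ld_flip` option models a marker whose LD with a causal QTL is
population-specific: the causal locus is hidden (ungenotyped) and a
genotyped tag at an *ancestry-neutral* site (minimal founder-frequency
difference) copies its gamete with probability 0.9 in the training
cohort but 0.0 externally. The ancestry-neutral site matters: a
frequency-divergent tag would keep predicting externally through
ancestry alone, masking the phase failure the option exists to produce.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: haplotype-scale LD (the only inter-marker
correlation is admixture-induced), so causal variants are directly
genotyped instead of tagged; pedigree/family structure; genotyping error;
selection; sex chromosomes; real map positions. Two consequences are
documented as known limitations below.

## Numerical notes

- PLINK I/O is a bit-exact v1.00 SNP-major 2-bit codec (00 hom-A1,
  01 missing, 10 het, 11 hom-A2); dosages count A1. Truncated payloads
  and id/count mismatches error out before any partial matrix escapes.
- Degenerate inputs raise rather than return sentinels: all-missing SNPs,
  monomorphic MAS markers, markers aliased with CG, constant GEBV or
  adjusted-phenotype vectors in the metrics, `k = 0` GRM scales.
- Chromosome labels are strings ordered naturally (numeric labels first,
  in numeric order).
- Experiment scales in tests and the acceptance script (5 replicates × 5
  folds, random panels at k ≤ 500 with 3 draws) are the package's chosen
  desk-scale conditions; the library defaults are 10 × 10 with 10 random
  draws.

## Known limitations

- With all causal variants genotyped and no haplotype LD, GWAS-ranked
  panels of a few hundred SNPs can *beat* the full panel for the
  polygenic trait: accuracy rises steeply to k ≈ 250 and then plateaus
  near the full-panel value instead of increasing monotonically through
  k = 5000. The monotone rise seen in real data depends on causal loci
  being tagged through LD, which this generator deliberately omits.
- Whether the external cohort's dispersion slope falls below the matched
  CV slope varies from seed to seed here: effects transfer to the
  external cohort exactly and additively, so the direction of the gap is
  set by the realized estimation error of the trait's ancestry contrast
  rather than by a systematic mechanism.
- A trait with ~30% of genetic variance at one locus misspecifies the
  equal-weight GRM model badly enough that fold-level REML can land on
  the `σu² = 0` boundary (verified as the true restricted-likelihood
  optimum by grid search); such folds are flagged, not patched.
- Accuracy's `1/√h²` scale uses an *estimated* h², so cell accuracies
  inherit its sampling noise; boundary folds drop out of accuracy means.
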