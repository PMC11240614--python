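# Methods

## Model

The phenotype model is the standard two-kernel animal model

    y = Xb + u_a + u_d + e
    u_a ~ N(0, Ga σ²_a),   u_d ~ N(0, Gd σ²_d),   e ~ N(0, I σ²_e)

with one record per genotyped individual, so the incidence matrices linking
records to individuals are identities and the partial genetic values (PGVs)
are y_a = u_a and y_d = u_d.  X defaults to an intercept (intercept + sex
when a sex column is available); anything richer is the caller's job.

### Codings and kinships

From counted-allele dosages m ∈ {0,1,2} and sample frequencies p estimated
on the analysis panel after imputation:

* additive coding  Z = m − 2p  (centered, **not** variance-scaled: the GRM
  denominators absorb the scale, and doing both would double-normalize);
* dominance coding W = h − 2p(1−p), h the heterozygosity indicator,
  centered by the Hardy–Weinberg expected heterozygosity H = 2p(1−p).
  W columns have exactly zero mean only at Hardy–Weinberg proportions.

Kinships are Ga = ZZ′/ΣH and Gd = WW′/ΣH².  Note a deliberate property of
this Gd variant (0/1/0 coding with the ΣH² denominator): its expected
diagonal is Σ H(1−H)/Σ H², about 1.45 for MAF ~ U(0.05, 0.5), not 1.  The
alternative "breeding-value-orthogonal" coding {−2q², 2pq, −2p²} would give
diagonal 1; we keep the genotypic 0/1/0 parameterization, which is the
convention this analysis chain is defined around.  For the same reason the
off-diagonal entries of Ga and Gd retain a small positive correlation
(≈ Σ H²(1−2p)² / √(Σ H² Σ H²(1−H)²), about 0.25 under the default MAF
distribution); the two kernels are still separately identifiable because
the correlation of the *matrices* is far from 1.  The stored GRM is exactly
the formula; solvers add a 1e−6 relative ridge internally when factorizing.

### Estimation backends

**AI-REML** (default): average-information updates with step-halving and an
EM fallback whenever an AI step would lower the restricted likelihood;
components floored at 1e−8·var(y); components pinned at the floor whose
score is negative are frozen (active set), which prevents oscillation at
the boundary.  Convergence is declared when the restricted log-likelihood
moves by < 1e−6.  Standard errors come from the inverse AI matrix at the
converged estimates, BLUPs from û_a = σ̂²_a Ga V̂⁻¹(y − Xb̂).

**Gibbs sampler**: each genetic effect is sampled in the eigenbasis of its
GRM, where its full conditional is diagonal; variance components get
scaled-inverse-χ² updates (prior df 5, prior scales splitting var(y)
equally across the three components — deliberately weak; both hyperpriors
are arguments).  Defaults: 12 000 iterations, 2 000 burn-in, thinning 5,
all driven by one seed.  The sampler reports both the ratio of posterior
means and the posterior mean of per-iteration ratios (h²_a, h²_d, dominance
share): with wide posteriors the two conventions differ, and published
tables of Bayesian fits typically print the latter.

### PGVs as responses

Because BLUP/posterior-mean effects are shrunken, var(y_a)/var(y) is
noticeably *below* h²_a even when the model is exactly right (≈ 0.27 at
n = 2000, m = 5000 under h² = 0.5 additive simulation, with
corr(y_a, u_a^true) ≈ 0.75).  PGVs are therefore validated by correlation
with the simulated truth and by their exact algebraic identity y_a = Z_a u_a,
not by naive variance ratios.

## Association scans

* `mlm`: P3D single-locus mixed model.  The ratio λ = σ²_g/σ²_e is profiled
  once under the null by restricted likelihood in the GRM eigenbasis (grid
  over log λ ∈ [−10, 10] then bounded refinement), after which every SNP
  column is tested by whitened regression — algebraically identical to full
  GLS with V fixed, and reduced to OLS when the kinship is the identity.
  Tests are two-sided t-tests with n − p − 1 degrees of freedom.  Setting
  `p3d=False` re-estimates λ per SNP; it is retained as an exactness check.
* `mlmm`: forward inclusion of the most significant SNP as a fixed-effect
  cofactor with λ re-estimated each step, stopping at pseudo-heritability
  < 0.01 or `max_cofactors` (10); the reported model minimizes the extended
  BIC −2·logL + k(ln n + 2γ ln m), γ = 1.  Cofactors are re-tested against
  the other cofactors for their reported p-values.  `max_cofactors=0`
  reproduces `mlm` exactly.
* Dominance scans test W columns and use Gd for the variance structure
  (switchable to Ga for sensitivity analysis).
* Thresholds are Bonferroni only: 0.05/N genome-wide significant, 1/N
  suggestive (ratio exactly 20).
* Ensemble rule: a SNP is reported when ≥ `min_support` (2) engines give
  p below the chosen tier (default: suggestive).  When scoring simulations,
  single engines are counted at the *significant* threshold and the
  ensemble at its own two-engine suggestive rule; the ensemble trades a
  looser per-engine threshold for cross-engine replication.  An
  intersection at a common threshold could never beat its best member, so
  this is the only reading under which an ensemble-vs-engine comparison is
  meaningful with two engines.
* Nearest-gene annotation reports the signed distance: 0 inside the gene,
  positive when the gene sits at a higher genomic coordinate than the SNP,
  negative when lower; ties go to the smaller gene start and the gene
  strand is carried alongside (the convention is not strand-aware).

## Synthetic data = study conditions

* Panels: biallelic SNPs spread over 18 autosomes, MAF ~ U(0.05, 0.5) with
  the counted allele randomized (so counted-allele frequency spans both
  sides of 0.5, as on a real array), genotypes Binomial(2, p) at HWE;
  optional AR(1) latent-Gaussian LD.
* F1 cross: ancestral frequencies U(0.1, 0.9) drifted apart by a
  Balding–Nichols draw with divergence 0.2; 6 sires × 24 dams (4 dams per
  sire) → 171 offspring, each receiving one gamete per parent with free
  recombination.  Trait values = breed baseline (sire pool 100, dam pool
  80, offspring mid-parent) + additive effects + positive dominance
  (d = 0.5|a|) at 300 loci + residual noise with SD equal to the genic SD.
  Offspring excess heterozygosity times positive d produces true mid-parent
  heterosis by construction.
* QTN phenotypes: 20 QTNs drawn uniformly from the polymorphic SNPs,
  effects ~ N(0,1) applied to the dosage (additive mode) or heterozygosity
  (dominance mode); the residual is explicitly decorrelated from the
  genetic values and rescaled so realized h² = 0.5 exactly.  In dominance
  mode h² is broad-sense (only dominance variance exists there).  QTNs stay
  in the tested panel (exact-match detection counting needs them);
  coding-contrast checks plant the causal heterozygote-advantage locus at
  allele frequency 0.5, the only frequency at which the additive contrast
  is exactly orthogonal to the dominance deviation.

## Problem sizes and numerical choices

Validation studies run at: component recovery 50 replicates on one fixed
2000 × 5000 panel (phenotypes redrawn per replicate, as when simulating on
a real genotype panel); scan calibration 20 null replicates at n = 500,
m = 2000; coding contrast 50 replicates at the same size; the simulation
study 20 additive + 20 dominance replicates at n = 171, m = 5000 with the
ensemble and both engines scored per replicate; heterosis rate over 100
cross seeds.  Unit tests exercise the same machinery at smaller sizes.

Degenerate inputs: monomorphic SNPs become zero design columns (warning);
an all-monomorphic panel is a hard error (zero GRM denominator); SNP
columns collinear with the fixed effects get missing p-values (warning);
an all-zero W yields a zero Gd with a warning; a SNP with no observed
genotypes cannot be imputed and raises.  Mode imputation breaks ties toward
the smaller genotype code.  QC order is fixed: autosome filter, then call
rate (< 0.95 removed, strictly), then imputation, then MAF (< 0.01 removed,
folded to minor).

## Limitations

* The generators make no attempt at realistic recombination maps, mutation,
  selection, or multi-generation pedigrees; LD is a one-parameter AR(1)
  caricature.  Passing tests show the estimators are correct under the
  stated model, not that real pig data meet its assumptions.
* Imputation is marginal (mode / frequency draw), not haplotype-based;
  retained-SNP counts after QC on real data will differ slightly from
  pipelines that impute with a phasing model.
* The ensemble wraps two in-package engines; it is an integration rule over
  a pluggable interface, not a re-implementation of any published
  five-model ensemble.
* Heritability conventions differ between backends (plug-in ratio for REML,
  both conventions for Gibbs); compare like with like.
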