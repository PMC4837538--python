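# Methods

`pedgwas` reproduces, at desk scale, a head-to-head comparison of SNP-based
and haplotype-based association mapping in a closed, multigenerational
purebred pig line: a synthetic population stands in for the (non-deposited)
genotypes, and a replicated simulation experiment measures each method's
power to localise a planted QTL.

## Population model

**Pedigree.** The default pedigree is a seven-generation closed line of 836
animals with per-generation (male, female) counts
(16, 22), (19, 40), (42, 47), (67, 86), (73, 86), (71, 86), (80, 101).
Generation 1 animals are founders; every later animal has both parents in
the previous generation. Mates are paired at random except that full-sib
and parent-offspring pairs are avoided whenever an alternative sire exists.
This is a stand-in for inbreeding-aware mate allocation in a real nucleus
herd: it reproduces the qualitative structure (one large interconnected
family, mean inbreeding rising to ~0.05 by generation 7) without modelling
selection on breeding values, which is out of scope.

**Founder haplotypes and LD.** Founder chromosomes are mosaics of a small
pool of `n_anc` ancestral haplotypes. Pool alleles are independent Bernoulli
draws per locus (target frequencies Beta(0.6, 0.6)); mosaic switch points
follow a Poisson process of rate `switch_rate` per Morgan, and each segment
copies a pool haplotype drawn with geometric weights `weight_decay**i`.
Short-range r^2 is governed by the effective pool size, the decay length by
the switch rate, and further LD accumulates through drift in the closed
pedigree. The defaults `n_anc = 5`, `weight_decay = 0.65`,
`switch_rate = 15` per Morgan were frozen after a pilot sweep
(`pedgwas.popsim.calibrate_pool`) so that the chromosome-averaged r^2 in
the 1.0 Mb distance bins is ~0.20 (observed 0.197-0.204 across seeds),
matching the target population's reported LD extent; the unequal weights
also populate the low-MAF class (typically ~300 of ~2,200 QC-passed SNPs
with MAF in [0.01, 0.10]).

**Genetic map and gene drop.** 1 Mb = 1 cM everywhere; meioses follow the
Haldane model (Poisson crossovers, no interference). The default marker
panel is 2 chromosomes x 100 Mb with 2,000 uniformly placed SNPs each
(~1 per 50 kb), of which ~2,200 survive QC; this keeps the 100-replicate
power grids and the cluster-HMM fit at desk scale while preserving local
LD. Genotypes are dosages of the alternate allele; missing calls are masked
independently at 1% so that the 95% call-rate filters are exercised without
removing animals.

## Quality control and kinship

SNP filters are the standard chip trio - MAF < 0.01, call rate < 0.95,
Hardy-Weinberg exact test p < 0.001 - applied after dropping animals with
call rate < 0.95. The HWE test is the exact conditional test (the PLINK
default family) rather than chi-square, because it behaves correctly at the
MAF 0.01 boundary. Inbreeding coefficients use the Meuwissen-Luo L-and-D
recursion (no full A required); the numerator relationship matrix A is
built by the tabular method when needed (REML, BLUP), and the two agree
identically on random pedigrees (property-tested). Pairwise r^2 is the
squared Pearson correlation of dosages with pairwise-complete handling;
decay curves bin intra-chromosomal pairs at 1 kb up to 10 Mb, average per
chromosome, then across chromosomes without pair-count weighting.

## Animal model REML

The adjustment model is y = Xb + u + e with u ~ N(0, A sigma_u^2),
e ~ N(0, I sigma_e^2), X = intercept + sex + generation (treatment coded),
one record per animal. Variance components are found by maximising the
restricted likelihood profiled over h^2 = sigma_u^2 / (sigma_u^2 +
sigma_e^2) on the eigendecomposition of A: a 21-point grid brackets the
optimum and bounded Brent refines it to 1e-8. For this two-component model
the profile is one-dimensional, so this finds the same optimum an
average-information iteration would converge to, is immune to
out-of-parameter-space steps, and - because the eigendecomposition is
computed once per pedigree - makes each replicate fit cost milliseconds,
which the 100-replicate power grids and the 50-replicate heritability check
depend on. Boundary estimates (h^2 -> 0) are reported, not raised.
Adjusted phenotypes are the exact affine residual y_adj = y - X b-hat and
are invariant to the fixed-effect coding (property-tested).

## SNP-based association

Each SNP is tested in y_adj = beta_i w_i + u + e'_i with an intercept
column (the adjusted phenotype has mean near but not exactly zero). One
eigendecomposition of A is shared across SNPs; by default the variance
ratio is re-optimised per SNP on the profiled restricted likelihood (the
exact-LMM construction), with a fast mode that freezes the null ratio.
Missing dosages are mean-imputed per SNP. The Wald statistic
(beta-hat / se)^2 is referred to chi-square with 1 df - at n > 800 the
difference from the t reference is negligible. The per-SNP variance
fraction is 2 p (1 - p) beta^2 / V_P with V_P the variance of the adjusted
phenotype (the definition is a choice; the source quantity is named only as
"adjusted phenotypic variance"). Null calibration on the pedigree
population gives pooled genomic-control lambda within [0.9, 1.1]
(per-replicate lambda is noisy because a single family supports few
effectively independent tests).

## Haplotype-based association

**Cluster HMM.** Each gamete is a mosaic of K = 20 ancestral haplotype
states with locus-specific emission probabilities, a single per-interval
switch probability, and a state-weight vector used for both the initial
state and switch targets. Diploid genotypes are handled exactly as the
product of two independent gamete chains: the K x K pair-state
forward-backward uses the rank-1 structure of the jump-move transition
((1-j) I + j 1 a') so each locus costs O(K^2), implemented in a numba
kernel. Emissions, weights and the switch probability are all fitted by EM
(25 sweeps by default, seeded random initialisation, no restarts by
default); the log-likelihood trace is monotone up to a 1e-8 symmetric
pseudocount on the emission update. Per-position output is the ancestral
dosage H_i (posterior expected state copies per animal, rows summing to 2);
hard Viterbi-style copies were considered but expected copies are the
default because the states are unobserved. Missing genotypes are imputed by
the posterior-mode count, which beats a major-genotype baseline on masked
entries (tested).

**Score test.** The two-step construction: fit the intercept-only animal
model on y_adj once, form r = y_adj - 1 mu-hat - u-hat, then at each
position T = 0.5 ||H_i' r||^2. The null of T is approximated by a gamma
distribution per position. Two estimators of the gamma parameters are
provided:

* *analytic* (default): under sigma_h^2 = 0, r = sigma_e^2 V^{-1} Q y_adj
  is Gaussian with Cov(r) = sigma_e^4 (V^{-1} - V^{-1} 1 c 1' V^{-1}),
  so T is a quadratic form with exact mean 0.5 tr(S) and variance
  0.5 tr(S^2), S = H_i' Cov(r) H_i (a K x K matrix, cheap per position in
  the eigenbasis of A);
* *permutation*: moment matching to T over permutations of r.

The analytic null is the default because permuting residuals breaks the
alignment between r (which the mixed model has partially orthogonalised
against family structure) and the cluster dosages (which track that same
structure): the permutation null overstates the null moments and the
resulting p-values are conservative (fraction below 0.05 was 0.013 in 300
null simulations, KS uniformity rejected), while the analytic null is
calibrated (KS p = 0.69 in the same design). p-values are floored at the
smallest positive double, never 0. The null model is fitted once per
phenotype, not re-estimated per position.

## Power study

Per replicate: (1) simulate the null base phenotype by gene-dropping
breeding values down the pedigree - founders u ~ N(0, 0.30), non-founders
around the midparent with Mendelian-sampling variance
0.5 (1 - 0.5 (F_S + F_D)) sigma_u^2, residuals N(0, 0.70), so h^2 = 0.30
and V_P = 1; (2) draw one QTL uniformly from the requested MAF class
(low: [0.01, 0.10], high: (0.10, 0.5], frequencies taken on the imputed
panel) and give it effect +/- sqrt(qtl_h2 / 2p(1-p)) with a random sign;
(3) rebuild the phenotype as y = u + beta w + e* with e* drawn fresh at
variance 0.70, so the polygenic heritability relative to the non-QTL
variance stays exactly 0.30 (the literal additive reading
y_base + beta w is available as `injection_mode="additive"`; the source
description admits both); (4) mask the QTL from both scans - its SNP
column from the mixed-model scan and its tested position from the
haplotype scan - while the cluster dosages remain those fitted once on the
full panel, mirroring a single phasing pass before the replicate loop;
(5) run both methods and record the minimum p inside the distance windows
+/-0.5, 0.5-1.0 and 1.0-2.0 Mb (annuli) around the QTL.

Power in a window is the fraction of replicates whose window minimum beats
the genome-wide threshold 1.31e-6 (0.05 Bonferroni-corrected for the
full-size 38,128-SNP panel; kept at that value on the reduced panel so
powers are comparable to the full-scale design). Because power depends only
on p-values within +/-2 Mb of the QTL, each replicate's scans are
restricted to that neighbourhood by default - an exact shortcut, not an
approximation (`scan_window_mb=None` scans everything). The default grid is
six QTL heritabilities {0.01, 0.03, 0.05, 0.07, 0.10, 0.15} x two MAF
classes x 100 replicates; replicate r of every cell reuses base-phenotype
seed `seed + r` with cell-specific offsets for the QTL draw, so grids are
bit-reproducible. Region calling merges sub-threshold SNPs within 1 Mb and
labels each region significant (p < 1.31e-6) or suggestive (p < 5e-5) by
its top SNP.

## What the synthetic data does and does not emulate

The generator matches the stated population properties: pedigree shape and
census sizes, rising inbreeding under closed-line mating, ~0.20 mean r^2 at
1 Mb, a MAF spectrum spanning both QTL classes, and missingness compatible
with the call-rate filters. It does **not** emulate selection on an index,
sex chromosomes, genotyping batch structure, or - importantly - the
haplotype architecture of rare variants in the real population. In the
pool-mosaic model a low-MAF allele usually descends from one rare ancestral
haplotype, so a K = 20 cluster model tags it almost perfectly and the
haplotype score test retains substantial power for low-MAF QTL
(~0.5-0.8 at qtl_h2 = 0.15). In the real population that power was bounded
by 0.03, implying rare alleles there are not coherent with any ancestral
cluster. The same feature acts, more mildly, on the SNP scan: because a
masked low-MAF QTL is well tagged by flanking markers on the same rare
ancestral haplotype, low-MAF SNP-scan power on this panel sits level with
or slightly above the high-MAF value (~0.50-0.60 at qtl_h2 = 0.05 across
panel seeds) instead of slightly below it (0.45 vs 0.50 in the study).
Conclusions about *relative* method behaviour on low-MAF QTL therefore do
not transfer from this synthetic panel to real data; the high-MAF power
levels and all calibration/threshold results do not depend on this
feature.

## Numerical choices and limitations

* Eigendecomposition ridge 1e-8 on A; REML h^2 searched in
  [1e-6, 1 - 1e-6]; emission probabilities clipped to [1e-6, 1 - 1e-6].
* HWE exact test returns 1.0 for monomorphic input; r^2 is flagged
  undefined (NaN) for monomorphic or <2 complete pairs rather than
  zero-filled; empty LD bins are NaN, not 0.
* Region tie-breaks: the most significant SNP labels a region, ties going
  to the smaller coordinate.
* Single record per animal; half-known parentage unsupported (the target
  pedigree has none); autosomes 1-18 only.
* The K^2 pair chain is exact but O(m n K^2); fits with K = 20 on the
  default panel take a few minutes, so the test suite's shared fit uses 12
  EM sweeps (the dosage panel is visually indistinguishable from the
  25-sweep fit) while the acceptance pipeline uses the 25-sweep default.
* Gamma is an approximation to the weighted-chi-square null of T; extreme
  tail probabilities (beyond ~1e-8) inherit its error in both estimators.
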