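# Methods

## The generative model

The synthetic cohorts are the package's test bed; they are built so that
every downstream estimator has a closed-form expectation to be checked
against.

**Reference panel.** Each SNP draws an ancestral frequency
p ~ U(0.05, 0.95); each of the K source ancestries then drifts away from it
under the Balding–Nichols model, p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k),
where F_k is a per-ancestry drift parameter interpretable as the Fst between
ancestry k and the common ancestor (default F = 0.1, a continental-scale
divergence). Frequencies are clipped to [1e-4, 1−1e-4] so that admixture
log-likelihoods stay finite.

**Individuals.** A sampling site is configured with per-ancestry female
(f_f) and male (f_m) contribution fractions, each summing to 1. Under equal
parental autosomal contribution and one-generation equilibrium X
transmission (two of every three X copies pass through females), the
expected ancestry vectors are

- autosomes: m_auto = (f_f + f_m)/2
- X chromosome: m_X = (2·f_f + f_m)/3  (both sexes)

Individual vectors are drawn as q_auto ~ Dirichlet(c·m_auto) and
q_X ~ Dirichlet(c·m_X). The concentration c controls within-site
variability; c = 30 (default, exposed in config) gives per-component
standard deviations of roughly 0.09 at m = 0.5, comparable to the spread of
ancestry proportions seen within admixed cohorts. Genotypes are
Binomial(ploidy, Σ_k q_k p_kj) draws — ploidy 2 everywhere except the
hemizygous male X (ploidy 1). Mitochondrial ancestry labels are drawn from
f_f and, for males, Y labels from f_m.

**What the generator does not emulate.** A single admixture generation with
no ancestry-tract structure (no linkage): none of the implemented statistics
uses LD except the f4 block jackknife, which is robust to, not dependent on,
linkage. No genotyping-batch effects, no strand issues, no relatedness.
Passing tests therefore demonstrate correctness of the estimators under the
model, not robustness to those real-data artefacts.

## Supervised ancestry estimation

With panel frequencies fixed, the per-individual log-likelihood is

l(q) = Σ_j [ g_j log(Σ_k q_k p_kj) + (c_j − g_j) log(Σ_k q_k (1−p_kj)) ],

g_j the counted-allele dosage, c_j the ploidy. We maximise by EM over latent
per-allele ancestry assignments; the update is monotone in l and the
problem is concave in q, so the uniform start suffices and no multistart is
used. Convergence: max_k |Δq_k| < 1e-6 (default) or 2000 iterations. Rows of
a batched cohort run are frozen individually the moment they converge, which
makes batched results bit-identical to per-individual runs. Missing
genotypes contribute nothing (ignorable missingness). Verified against a
0.001-step grid search on K = 2 instances and by parameter recovery
(per-individual RMSE < 0.03 at 5,000 SNPs, K = 3, F = 0.1).

The "genome-wide" proportion F_total of an ancestry can be read either from
a single all-SNP run (scope `genomewide`) or as the mean of per-chromosome
runs (scope `auto:mean`); both are provided and `auto:mean` is the default
used by the sex-bias stage.

## ΔAdmix and its bootstrap

Chromosome matching: chromosomes longer than the X are restricted to the
SNPs within 180 cM of their first mapped position (configurable to a
centred window); chromosomes of roughly X length are taken whole; each
candidate set is downsampled without replacement to the number of X SNPs,
which is always computed from the input. F_X weights female vectors twice
(two X copies per female); F_auto averages each individual's mean over the
matched subsets, then over individuals.

The bootstrap resamples individuals with replacement, recomputing pooled
F_X, F_auto, F_total and ΔAdmix per replicate from the precomputed
per-individual proportions — the EM is not re-run inside replicates, whose
cost would be three orders of magnitude larger for no change in the
resampling distribution of the pooled means. The CI is the percentile
interval at α = 0.05; "significant" means the CI excludes zero. Per-site
tables are always emitted; the pooled estimate is the unweighted mean of
per-site values (bootstrap within sites), so a sample-size-weighted pooling
can be reconstructed from the per-site rows if wanted. When an ancestry is
absent (F_X + F_auto = 0) the ratio is defined as 0 rather than NaN so site
tables stay complete.

Null calibration is checked on cohorts with f_f = f_m using the generator's
true ancestry vectors (200 cohorts of 150 individuals, 500 bootstrap
replicates): the quantity under test there is the CI machinery itself, and
the check runs in seconds instead of hours.

## Study configurations

The default study is 3 sites × 200 individuals, K = 3, with 6,000 autosomal
and 1,500 X SNPs and contribution fractions f_f = (0.6, 0.2, 0.2),
f_m = (0.2, 0.6, 0.2) — one female-biased, one male-biased, one unbiased
ancestry. Six thousand autosomal SNPs cannot supply nine matched subsets of
1,500 SNPs each, so this configuration places them on the three X-length
chromosomes (chr7/10/12, 2,000 SNPs each); the long-chromosome trimming
path is exercised by the unit tests and the smoke pipeline, which use
denser maps relative to their X. A second, six-site configuration adds a
west-to-east gradient in the contribution fractions for the cline, Mantel
and leave-one-out analyses.

## Other statistics

**f4.** f4(A,B,C,D) = mean_j (p_Aj − p_Bj)(p_Cj − p_Dj) over SNPs non-missing
in all four populations. Standard errors by weighted delete-one block
jackknife over contiguous blocks of 500 SNPs (SNP-count blocks, since
simulated maps are unit-agnostic; block size configurable). With fewer than
two blocks the SE is reported as NaN. Sign interpretation follows the
outgroup layout: a significantly negative f4(Outgroup, Test, P1, P2) means
excess sharing between Test and P1. The simulated ancestral frequencies
double as a convenient outgroup in the pipeline.

**Fst.** Weir & Cockerham (1984) two-population variance components a, b, c
per SNP, combined as Σa / Σ(a+b+c) across SNPs (ratio-of-sums, the
convention of the standard command-line tools; mean-of-ratios is biased at
low per-SNP information). Negative aggregates are clamped to 0 in the
matrix; the raw values are retained and are what the Mantel stage uses,
recorded in its output metadata. The components assume diploid genotypes,
so the pipeline computes Fst on autosomes.

**Mantel.** Pearson correlation of upper-triangle entries, null built by
jointly permuting rows and columns of the second matrix, one-sided
(greater) by default to match the directional isolation-by-distance
question; p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1). When the full
permutation group is smaller than the requested permutation count (n ≤ 7 at
the default 9,999), the group is enumerated exhaustively and the p-value is
exact. Geographic distances are great-circle (Haversine, R = 6,371 km),
coordinates in decimal degrees with southern latitudes negative.

**Clines.** OLS of unweighted per-site mean ancestry on one coordinate;
two-sided t-test on the slope with n − 2 df. Sites with fewer than a
minimum count (default 10) are dropped before fitting. Leave-one-out refits
the cline without each site in turn and flags removals that cross α = 0.05
in either direction; with only three sites remaining the row is flagged
"undefined" (a 1-df fit is reported but too fragile to call).

**Uniparental concordance.** MT and Y haplogroup-to-ancestry assignments
are inputs, never inferred; unmapped haplogroups raise an error rather than
being dropped, since silent drops would bias the frequencies. The
comparison flags an ancestry female-leaning when f_MT > f_auto > f_Y and
male-leaning on the reverse ordering.

## QC

Filter order is fixed: individuals with missingness > 15 %, then SNPs with
missingness > 10 %, then autosomal SNPs failing a 1-df chi-square HWE test
at p < 1e-5. The chi-square approximation (not the exact test some tools
use) is documented as a deliberate divergence; SNPs with any expected
genotype-class count below 5 are exempted, where the approximation is
unreliable. Missingness uses the ploidy-appropriate denominator (one
observation per male X genotype). Filtering is idempotent and never alters
surviving genotype values. SNP-level missingness is applied once
(relatedness pruning, after which some workflows re-apply it, is out of
scope).

## Reproducibility

All randomness flows from one master seed: each pipeline stage derives its
own child seed through a fixed stage-offset table via numpy's SeedSequence,
so any stage can be re-run independently and reruns are byte-identical. The
run manifest records package and library versions, the stage seeds, and a
SHA-256 digest of every output file.

## Known limitations

- The supervised EM assumes the panel frequencies are the true source
  frequencies; panel misspecification biases q̂, and no correction is
  attempted.
- A single admixture generation is simulated; timing of admixture and
  tract-length methods are out of scope.
- The HWE filter is approximate at low minor-allele counts (hence the
  expected-count exemption).
- The ΔAdmix bootstrap treats per-individual proportions as fixed data;
  EM estimation noise widens the CIs slightly rather than being modelled.
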