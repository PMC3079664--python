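# Methods

## The enrichment model

For a SNP set S (a pathway's genes resolved to SNPs by position) the test
statistic is the indicator count

    y(S) = #{ i in S : P_i <= alpha },

where `P_i` is the single-marker association p-value. Two sources of
randomness are neutralized:

* **Set-membership randomness.** If S's `m` members had been drawn uniformly
  from the `n` post-QC SNPs, `y ~ Hyp(m, d, n)` with `d` the genome-wide
  significant count. The score is standardized analytically,

      z = (y - mu) / sigma,  mu = m d / n,
      sigma^2 = m (d/n)(1 - d/n)(n - m)/(n - 1),

  with the convention `z = 0` when `sigma^2 = 0` (which happens exactly when
  `d ∈ {0, n}` or `m ∈ {0, n}` or `n = 1` — all cases where `y` is forced to
  equal its mean). Using the closed-form hypergeometric moments is what makes
  the set-randomization null free: it never has to be simulated.

* **Genotype–phenotype dependence.** Case/control labels are permuted `Pi`
  times, preserving the `l1/l2` split. Each permutation recomputes all `n`
  single-SNP p-values, its own `d_pi`, and `z_pi` standardized by
  `Hyp(m, d_pi, n)` — the standardization tracks each permutation's own
  significant-SNP yield. Genotype columns are never touched, so each
  subject's multilocus genotype, and with it all LD, is preserved under the
  null.

Only over-representation is tested (large `z`). The per-set p-value is
`P = (1/Pi) * sum_pi I(z_pi >= z_obs)`; the non-strict inequality guarantees
the identity permutation yields `P = 1` rather than 0 in the degenerate
all-ties case. An add-one smoothed variant `(1 + sum I)/(1 + Pi)` that never
returns exactly zero is available (`--smooth-p`).

Multiplicity over the `T` sets uses the permutation score matrix itself:

* `FDR(S) = mean_pi[#{S': z_pi(S') >= z(S)}/T] / [#{S': z_obs(S') >= z(S)}/T]`,
  clamped to [0, 1]; the denominator counts S itself, so it is never 0.
* `FWER(S) = (1/Pi) * sum_pi I(max_S' z_pi(S') >= z(S))`, which dominates the
  per-set p-value by construction.

Because the score is an indicator count, every significant marker weighs the
same: changing a member's p-value from 1e-10 to 1e-3 (both below alpha)
changes nothing downstream. Enrichment therefore reflects many moderate
signals, not one strong one, and the per-permutation restandardization makes
the null distribution of `z` comparable across set sizes.

## Single-SNP association

Five genetic models on the per-SNP 2x3 (class x dosage) table: general
(2-df Pearson chi-square), dominant ({1,2} vs {0}), recessive ({2} vs {0,1}),
multiplicative (2x2 allele-count table), and additive — the Cochran–Armitage
trend test with weights (0, 1, 2), the pipeline default since it targets the
per-allele risk model most GWAS assume. The trend statistic is the score-test
form

    D = N (N Σt r − R Σt n)^2 / [R (N − R)(N Σt² n − (Σt n)^2)],

invariant under affine reweighting of the dosage scores. The three 2x2
models switch from chi-square to a two-sided Fisher exact test when any
expected cell is below 5 (the classic rule); the Fisher test is implemented
in-package as a vectorized hypergeometric enumeration because the permutation
loop re-tests every SNP for every relabeling, and per-table library calls
dominate runtime at that scale (agreement with `scipy.stats.fisher_exact` is
checked in the test suite). No continuity corrections anywhere, keeping the
chi-square family internally consistent. Degenerate tables drop empty
genotype columns and reduce the degrees of freedom; a table reduced to one
column, or a monomorphic SNP under the trend test, scores `D = 0, P = 1`.
Missing genotypes are handled per marker by complete-case tables; no
imputation is attempted.

## Marker quality control

Three filters, in this order (the first failing rule is the recorded
reason): Hardy–Weinberg exact test in the pooled controls (`p < 5.7e-7`
removes), a 1-df trend and/or 2-df chi-square test between the two control
cohorts where the design provides them (`p < 5.7e-7`; the default takes the
minimum of both tests, configurable to either alone since published usage of
the dual-df rule is ambiguous), and minor allele frequency (`MAF < 1%`).
Thresholds are strict: a marker exactly at a threshold is kept. The HWE test
is the exact conditional test — all heterozygote counts compatible with the
observed allele totals are enumerated through a numerically stable
probability recurrence, and the p-value sums the configurations no more
probable than the observed one (plain, not mid-p). Sample-level QC is left
to the user as an exclusion list applied before the pipeline.

## SNP-set construction

A SNP maps to a gene when it lies within `window` kb of the gene body on the
same chromosome, boundary inclusive ("within 5 kb" reads as `<= 5000` bp);
the default window is 5 kb. A SNP inside the shared span of overlapping
genes maps to all of them. An optional closest-gene mode assigns each SNP to
its nearest gene(s) at any distance. A gene set's SNP set is the union over
its member genes; set sizes below 2 are excluded by default because a 1-SNP
set makes the standardized score degenerate. SNPs mapping to no gene stay in
the universe `n` by default — they still contribute to `d`, and removing
them is a different null; `--restrict-universe` drops them for users who
want the mapped-only universe.

## Synthetic data generator

The generator emulates the structure of a two-cohort case/control SNP-array
study at desk scale: 2,000 biallelic SNPs in 200 genes (10 SNPs per gene,
genes tiled over 22 synthetic chromosomes with 60 kb intergenic gaps, so the
5 kb window maps each SNP to exactly one gene), 40 disjoint 5-gene sets, 250
cases and 250 controls with the controls split into two cohorts. Per SNP a
minor-allele frequency is drawn uniformly from (0.05, 0.5) and genotypes
follow Hardy–Weinberg proportions, independent across SNPs and samples.
Planted association is additive: in chosen sets, a configurable fraction of
SNPs (default 30%) has case genotypes drawn proportional to
`HWE(k) * RR^k` with per-allele relative risk `RR` (default 1.5), matching
the alternative the trend test targets. Each randomness source (MAF, genotype
draws, missingness, planted-SNP selection) uses its own child stream of the
seed, so setting `RR = 1` reproduces the null dataset bit-for-bit.

What the generator does *not* emulate: linkage disequilibrium (SNPs are
independent; an optional copy-with-flip block mode provides maximal
within-block dependence to exercise the label-permutation argument, not a
realistic LD map), population structure, genotyping error, differential
missingness, and realistic MAF spectra (no rare-variant tail). Passing tests
therefore demonstrate correctness of the statistical machinery under its own
assumptions — calibration and power claims about real array data with LD do
not follow from them, although the permutation construction is exactly the
argument for why LD does not invalidate the set p-values.

## Numerical and design choices

* **Restandardization form.** The per-permutation procedure (recompute
  `d_pi`, standardize by `Hyp(m, d_pi, n)` moments) is the implemented
  definition of the restandardized score; no additional rescaling by
  permutation-model moments is applied.
* **Inequalities.** `>=` uniformly for the p-value indicator and the
  FDR/FWER exceedance counts, so ties never produce anti-conservative
  p-values and the identity permutation gives `P = 1`, never 0.
* **Boundary conventions.** Significance is `P <= alpha` (inclusive); QC
  removal is strict `<`; the mapping window is inclusive; coordinates are
  1-based inclusive; chromosome labels are normalized by stripping a leading
  `chr`.
* **PLINK dosage.** The minor allele is determined per SNP from the data; on
  an exact 50/50 tie the lexicographically first allele is taken as the
  major (reference) allele. Strand is ignored — the method consumes counts
  only.
* **Fisher tie handling.** Support members whose conditional probability is
  within 1e-11 relative of the observed table's count as ties; truly
  distinct hypergeometric pmf values of the affected (small-expected-count)
  tables differ by far more.
* **Permutation batching.** Label permutations are processed in batches
  (default 256) so the additive-model inner loop is a single BLAS product of
  the precomputed dosage-indicator matrices with the label matrix; memory
  stays at `n x batch` doubles, and results are identical for any batch
  size. Permutation blocks run with distinct seeds pool by concatenation and
  are equivalent to one long run over the combined stream.
* **Failed markers.** A SNP whose table is unusable in a genome scan (an
  entirely missing phenotype class) is assigned `P = 1` with a warning
  rather than aborting the run.

## Validation design in the test suite

Statistical checks are seeded and sized to be reproducible and sharp:

* The hypergeometric shortcut is validated against 100,000 explicit uniform
  draws of m-SNP subsets per grid cell: means and variances within 3
  Monte-Carlo SE (with the exact finite-sample variance of the sample
  variance; on two-point supports, where the sample variance is a
  deterministic function of the sample mean and the normal approximation
  degenerates, the 3-SE mean band is propagated through that function
  instead), plus a chi-square goodness-of-fit against the exact pmf at
  family level 0.01 (Bonferroni across the grid).
* Every association statistic is compared with independently coded
  brute-force oracles on all 230,230 case/control tables with total <= 20;
  the HWE test against an exact-rational enumeration for all tables with
  <= 30 individuals.
* Type-I calibration runs 50 null replicates of the default design with
  `Pi = 200`: the fraction of set p-values at or below 0.05 must lie in the
  binomial 99% band. Uniformity is tested by KS at level 0.01 on randomized
  tie-broken p-values `p* = (#{>} + U(1 + #{=}))/(Pi + 1)`, which are
  exactly Uniform(0,1) under exchangeability even on the discrete
  `Pi`-point grid; one set per replicate is used so the KS sample is
  independent (sets within a replicate share permutations). The reported
  untie-broken p-values are discrete and conservative by construction.
* Size robustness compares observed null z of a 10-SNP set and a 500-SNP
  set by two-sample KS (level 0.01) over 50 independent replicates per arm,
  with the counting threshold at 0.5. The indicator count of a 10-SNP set
  lives on an 11-point lattice, so its standardized distribution differs
  from a 500-SNP set's by an irreducible KS distance of roughly half its
  largest atom (~0.12) at any threshold; the threshold 0.5 minimizes that
  atom and the sample size is chosen so the test is insensitive to the
  lattice yet would detect the O(0.3+) size-dependent shifts that
  size-naive enrichment statistics exhibit.
* Power: with the default planted design (RR 1.5 on 30% of one 50-SNP
  pathway), the planted pathway must be the unique top-z set in > 90% of 50
  replicates — observed rates are at or near 1.0.

## Known limitations

Binary phenotypes only; no covariate adjustment, logistic or mixed models;
no X-chromosome-specific handling (the QC and tests assume autosomes); no
LD-aware pruning or SNP weighting inside sets; p-value resolution is limited
to `1/Pi`, so genome-scale FWER control needs correspondingly large `Pi`
(use permutation blocks); the FDR estimator is the permutation plug-in form
and can exceed observed false-positive rates on strongly correlated sets.
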