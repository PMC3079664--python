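# rsnpset

Random-set enrichment analysis of SNP sets in case/control genome-wide
association studies.

## The problem and the method

Single-marker GWAS analysis keeps only the strongest signals. For polygenic
traits much of the association is spread over many markers of moderate
effect, so a natural question is whether a *SNP set* — the SNPs positionally
mapped to the genes of a pathway — carries more association signal than
chance allows.

`rsnpset` tests over-representation of significant SNPs in each set against
two null hypotheses *simultaneously*:

1. **Permutation model** — genotype and phenotype are independent; realized
   by permuting case/control labels, which leaves every subject's genotype
   profile (and hence the LD structure) untouched.
2. **Randomization model** — the set's members might as well have been drawn
   at random from all `n` SNPs. Under this null the count of significant
   SNPs in a set of size `m` is hypergeometric, so the "row randomization"
   never has to be simulated.

Write `n` for the number of post-QC SNPs, `d` for the number with
single-marker p-value `P ≤ α`, `m` for the set size and `y` for the number of
significant SNPs inside the set. Under random set membership
`y ~ Hyp(m, d, n)` with

    μ = m·d/n,    σ² = m·(d/n)·(1 − d/n)·(n − m)/(n − 1),

and the restandardized enrichment score is `z = (y − μ)/σ` (defined as 0 when
σ = 0). The label-permutation layer recomputes all `n` single-SNP p-values
for each of `Π` permutations and re-standardizes with that permutation's own
`d_π`; the set's p-value is the fraction of permutations with `z_π ≥ z_obs`.
FDR and FWER across the `T` sets are estimated from the same permutation
score matrix. Because the score is an indicator count, a marker with
`P = 10⁻¹⁰` and one with `P = 10⁻³` contribute equally: enrichment must come
from many moderately associated markers, not one strong hit.

Per-SNP association supports five genetic models: general (2-df χ²),
dominant, recessive, multiplicative (1-df χ² with an exact-test fallback for
sparse tables), and additive (1-df Cochran–Armitage trend test — the
default). Marker QC implements the standard filters: Hardy–Weinberg exact
test in pooled controls, a control-vs-control association test when two
control cohorts exist, and a MAF floor (defaults 5.7×10⁻⁷, 5.7×10⁻⁷, 1%).

## Worked example

Simulate a study in which pathway `SET001` carries a per-allele relative risk
of 1.5 on 30% of its SNPs, then run the full pipeline:

```
rsnpset simulate --seed 11 --planted 0 --out demo/
rsnpset qc --genotypes demo/genotypes.tsv --phenotypes demo/phenotypes.tsv \
           --out-prefix demo/qc
rsnpset enrich --genotypes demo/qc.genotypes.tsv --phenotypes demo/phenotypes.tsv \
               --snp-annotation demo/snps.tsv --gene-annotation demo/genes.tsv \
               --gmt demo/sets.gmt --alpha 0.01 --perms 200 --seed 1 \
               --out demo/report.tsv
rsnpset report --qc-report demo/qc.qc_report.tsv --enrichment-report demo/report.tsv
```

which prints:

```
markers: 2000 kept / 2000 total
gene sets tested: 40  (d=24 significant SNPs)
top sets (by p, then z):
  SET001: m=50 y=7 z=8.416 p=0 FDR=0 FWER=0
  SET031: m=50 y=2 z=1.841 p=0.075 FDR=0.923 FWER=0.925
  SET028: m=50 y=2 z=1.841 p=0.115 FDR=0.923 FWER=0.925
  SET015: m=50 y=1 z=0.526 p=0.25 FDR=0.836 FWER=1
  SET007: m=50 y=1 z=0.526 p=0.305 FDR=0.836 FWER=1
```

Reading the planted row: of the genome-wide `d = 24` SNPs significant at
`α = 0.01`, `y = 7` fall in `SET001`'s 50 SNPs where the hypergeometric null
expects `μ = 0.6` — a score of `z ≈ 8.4` that no label permutation reached
(`p = 0` at Π = 200, FDR = FWER = 0). The runner-up null pathways sit at
`z ≈ 0.5–1.8` with unremarkable p-values.

The genotype TSV dialect is one header row `snp_id<TAB>sample…` followed by
one row per SNP with codes `0/1/2/NA` (minor-allele dosage); classic PLINK
`.ped`/`.map` pairs are also accepted (`--format plink_ped`). Gene sets use
MSigDB GMT format. Long permutation runs can be split with
`--scores-out block.npz` + distinct `--seed`/`--block-id` per run and pooled
with `rsnpset combine block1.npz block2.npz …`.

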