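# mmdpath

Kernel maximum-mean-discrepancy (MMD) testing for differentially expressed
pathways, with multi-omics integration by kernel addition.

## The problem

A pathway is a *set* of genes, so asking whether it is differentially
expressed between two conditions is a multivariate two-sample question: are
the two clouds of sample vectors drawn from the same distribution?  Classical
answers (Hotelling's T²) assume multivariate normality with a shared
covariance and break down as soon as the number of pathway features exceeds
the sample count — routine in omics.  The kernel MMD test avoids both
restrictions, and because it only touches the data through a kernel matrix it
also integrates heterogeneous omics blocks (e.g. transcript levels and
fatty-acid concentrations) by simply *adding* their kernel matrices.

## The statistic

For samples X = (x₁,…,x_m) ~ P and Y = (y₁,…,y_n) ~ Q and a kernel k, the
unbiased estimator of the squared population MMD (the RKHS distance between
the mean elements of P and Q) is

    MMD² = 1/(m(m−1)) Σ_{i≠j} k(x_i,x_j) + 1/(n(n−1)) Σ_{i≠j} k(y_i,y_j)
         − 2/(mn) Σ_{i,j} k(x_i,y_j)

With a universal kernel (the Gaussian k(x,x′) = exp(−γ‖x−x′‖²) used here),
the population MMD is zero iff P = Q.  Significance comes from a permutation
test on the fixed pooled kernel matrix: p = (1 + #{null ≥ observed})/(t + 1),
with t = 2499 permutations by default, so the smallest attainable p-value is
1/2500 = 4·10⁻⁴.  The bandwidth rate γ is set by a quantile heuristic: any
value between the reciprocals of the 0.9 and 0.1 quantiles of the pairwise
squared distances is admissible; the package deterministically uses the
reciprocal of the median and always reports the bounds.

Three baselines are included for comparison: Hotelling's T² (with an explicit
"not applicable" outcome when p > m + n − 2), and the two minimum-spanning-tree
generalizations of classical univariate tests — the multivariate
Wald-Wolfowitz runs test (count of subtrees left after cutting between-group
MST edges) and the multivariate Kolmogorov-Smirnov test (maximal empirical-CDF
gap along a height-directed preorder ranking of the MST).  Kernel PCA maps
with per-gene gradient arrows support interpretation of significant pathways.

## Worked example

The package bundles the public *nutrimouse* nutrigenomic study (40 mice —
20 wild-type, 20 PPAR-deficient — across 5 diets; 120 liver gene expressions
and 21 hepatic fatty-acid concentrations) and the 17-gene fatty-acid
catabolism pathway used in the published analysis.

```python
import mmdpath as mp

genes, lipids, meta = mp.load_nutrimouse()
report = mp.run_pathway_tests(
    [genes], meta, factor="genotype", levels=("wt", "ppar"),
    gene_sets={"genes": mp.catabolism_gene_set()},
    tests=("mmd", "hotelling", "mww", "mks"), t=2499, seed=1,
)
for res in report.results:
    print(f"{res.method:>9}  statistic={res.statistic:.4f}  p={res.p_value:.2e}")
```

prints

```
      mmd  statistic=0.5954  p=4.00e-04
hotelling  statistic=1229.4303  p=7.07e-13
      mWW  statistic=3.0000  p=4.00e-04
      mKS  statistic=0.8500  p=4.00e-04
```

Every test agrees that the catabolism pathway is differentially expressed
between genotypes; the MMD p-value sits at the permutation floor 1/2500.  The
mWW statistic R = 3 means cutting every wt–ppar edge of the 40-sample MST
leaves only three subtrees — near-perfect separation.

Multi-omics integration is one call away: building per-block Gaussian kernels
for the pathway genes and the three ω3 fatty acids (C20:5ω3, C22:5ω3,
C22:6ω3) and adding them turns the diet contrast sun vs fish from
non-significant on genes alone (p ≈ 0.26) into maximally significant
(p = 4·10⁻⁴) — while Hotelling's test is not applicable at those group sizes
(17 features, 8 + 8 samples).

```python
report = mp.run_pathway_tests(
    [genes, lipids], meta, factor="diet", levels=("sun", "fish"),
    gene_sets={"genes": mp.catabolism_gene_set(), "lipids": mp.omega3_lipid_set()},
    tests=("mmd",), t=2499, seed=1,
)
```

The same pipeline is scriptable from the shell:

```bash
mmdpath fixtures --seed 7 --out fixtures/          # synthetic 40-mouse dataset
mmdpath run --block fixtures/genes.tsv --block fixtures/lipids.tsv \
    --meta fixtures/meta.tsv --factor genotype --levels wt,ppar \
    --gene-set fixtures/pathways.gmt:catabolism:genes \
    --gene-set fixtures/pathways.gmt:omega3:lipids \
    --perms 2499 --seed 7 --out results/
mmdpath simulate --test mmd --m 20 --n 20 --p 16 --delta 0 --reps 500 --seed 1
mmdpath kpca --block fixtures/genes.tsv --meta fixtures/meta.tsv \
    --gene-set fixtures/pathways.gmt:catabolism --arrows all --out kpca/
```

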