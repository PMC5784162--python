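# cbsdgs

Two-stage genome-wide association and genomic prediction for cassava brown
streak disease (CBSD) resistance breeding.

Cassava (*Manihot esculenta*) breeding programs in East Africa score CBSD
foliar and root-necrosis severity on an ordinal 1–5 scale in multi-location
field trials, genotype their panels by sequencing, and need to (a) locate
resistance loci and (b) rank selection candidates by genomic estimated
breeding value. `cbsdgs` implements that workflow end to end as a tested,
reusable Python library with a thin CLI, plus a synthetic breeding-panel
generator so every stage can be validated against a known truth without any
field data.

## The analysis

**Stage 1 — trial mixed models.** Plot-level scores are fit per panel with a
linear mixed model matching the field design: fixed population mean and
location (a check effect for augmented designs, optionally a cassava mosaic
disease severity covariate), random clone `c ~ N(0, I σ²_c)`, incomplete
block, and (alpha-lattice) range nested in location-rep. Clone BLUPs `ĉ` and
their prediction error variances (PEV) are extracted at the REML optimum and
de-regressed,

    dereg BLUP = ĉ / (1 − PEV / σ²_c),

removing shrinkage before second-stage analysis. Broad-sense heritability is
reported on an entry-mean basis, `H² = σ²_c / (σ²_c + σ²_other / r̄)` with
`r̄` the harmonic-mean plot count.

**Stage 2 — genomics.** Marker QC (missingness → imputation AR² → MAF),
VanRaden genomic relationship matrix `G = WW′ / (2Σp(1−p))`, SNP
heritability from the one-step mixed model `y = μ + g + e` with
`g ~ N(0, G σ²_g)`, and PCA for stratification. Association uses a
mixed-linear-model scan with leave-one-chromosome-out (LOCO) kinship —
variance components are re-estimated per left-out chromosome so the tested
marker never contributes to the polygenic term that would absorb it — with a
Bonferroni threshold `−log10(α/m)`. Genomic prediction covers seven model
families: GBLUP, chromosome-partitioned multi-kernel GBLUP (GWAS-guided),
Gaussian-kernel RKHS `K_ij = exp(−d_ij θ)` over a bandwidth ladder with
REML-estimated kernel weights, BayesA/BayesB/BayesCπ/Bayesian LASSO Gibbs
samplers, and Random Forest. Introgression segments from the wild relative
*M. glaziovii* are called from ancestry-informative SNPs in non-overlapping
20-SNP windows by a 2× majority rule, and local LD is summarised by LD
scores (sums of small-sample-adjusted r²).

## Worked example

```python
from cbsdgs import simdata, stage1, genomics, gwas

cfg = simdata.SimConfig(seed=123)             # 900 clones, 5 x 1000 markers
geno, truth = simdata.simulate_genotypes(cfg)
pheno = simdata.simulate_phenotypes(geno, truth, cfg)

fit = stage1.fit_panel(pheno, response="cbsd6s", design="alpha")
print(f"H2 = {fit.H2:.2f}")                   # H2 = 0.55
dereg = stage1.deregress(fit)["dereg"].dropna()

geno_f = genomics.filter_markers(geno, max_missing=0.6, ar2_min=0.3,
                                 maf_min=0.01)
table = gwas.mlma_loco(geno_f, dereg, maf_min=0.05)
print(f"Bonferroni -log10 threshold: {gwas.bonferroni_threshold(len(table)):.2f}")
top = table.loc[table['p'].idxmin()]
print(f"top hit chr{int(top['chrom'])}:{int(top['pos'])}  "
      f"-log10(p) = {top['neglog10p']:.1f}")
```

This prints

```
H2 = 0.55
Bonferroni -log10 threshold: 4.76
top hit chr4:12390000  -log10(p) = 22.7
```

an entry-mean heritability of 0.55 (the simulated locations span
0.25–0.55), a genome-wide threshold of 4.76 for the 2,853 markers passing
MAF > 0.05, and a top association at 12.4 Mb on chromosome 4 — inside the
simulated 8–16 Mb *M. glaziovii* introgression block, i.e. the scan
localises a planted resistance signal. The same objects feed
`prediction.cross_validate` (model
accuracy as the correlation between predictions and held-out de-regressed
BLUPs), `introgression.call_windows` and `ldscore.ld_scores`.

The CLI mirrors the library: `cbsdgs simdata|stage1|gwas|predict|
introgression|ldscore|pipeline --help`.

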