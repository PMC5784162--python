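# Methods

## The two-stage model

Stage 1 fits, per panel, a plot-level linear mixed model by REML. For a
replicated alpha-lattice trial

    y = Xβ + Z_clone c + Z_block b + Z_range(loc.rep) r + ε,

with β the population mean and location effects, and `c, b, r, ε`
independent Gaussian random effects with scalar variances. For the
unreplicated augmented design the range term is dropped and a fixed check
effect is added. All variance ratios are profiled against the residual
variance and optimised on the log scale (L-BFGS-B from three starts,
Nelder-Mead polish, ratios boxed in `exp(±25)`), which keeps variances
non-negative and reproduces the balanced-design ANOVA estimators to ~1e-8.
BLUPs and PEVs come from the mixed-model equations at the optimum; PEVs are
clipped into `[0, σ²_c]`. Aliased fixed-effect columns are dropped by
rank-revealing QR with a logged warning. A constant response returns all
variances as zero rather than failing.

De-regression divides each BLUP by its reliability `1 − PEV/σ²_c`. The
formula diverges as reliability → 0, so clones at or below a reliability
floor (default 0.05) are flagged and excluded rather than returned as huge
values. Entry-mean broad-sense heritability uses the harmonic-mean number of
plots per clone (clones with zero plots excluded) with all non-clone
variances in the per-plot denominator — the standard plant-breeding
convention; the multi-location fit treats location as fixed and adds no GxE
random terms, matching the stage-1 model above.

Stage 2 consumes the de-regressed BLUPs. The default treatment of the two
panels is per-panel stage-1 fits pooled into one clone vector; a joint fit
is equally possible by passing the concatenated plot table.

## Kernels and REML machinery

Single-kernel mixed models (SNP heritability, GBLUP) use the spectral
trick: one eigendecomposition of `K` reduces the restricted likelihood to a
1-D profile in `δ = σ²_e/σ²_g`, scanned on a 64-point log grid over
`e^±14` and refined by bounded minimisation. Nearly-PSD kernels are "bent"
(negative eigenvalues clipped) with a warning. Multi-kernel models (one
variance per kernel; used for chromosome-partitioned GBLUP and RKHS) are
fitted by L-BFGS-B on log variances with analytic gradients
`∂(−2l)/∂σ²_k = tr(P K_k) − y′P K_k P y`.

GBLUP predicts untrained clones through the relationship matrix,
`ĝ_test = σ²_g K_test,train V⁻¹(y − μ̂)`; for multi-kernel models the same
propagation is done per kernel, so the total prediction decomposes exactly
into kernel components and each kernel's contribution to accuracy can be
read off as the correlation of its component with the validation values.

RKHS kernels are `K_ij = exp(−d_ij θ)` with `d_ij` the squared Euclidean
distance between dosage rows (a flag switches to the unsquared distance)
over the bandwidth ladder θ ∈ {5e-7, 5e-5, 5e-4, 5e-3, 1e-2, 5e-2}, all six
fitted jointly with REML weights.

## Association scan

The MLMA-LOCO scan re-estimates variance components once per left-out
chromosome (not per marker) with a VanRaden GRM of the remaining
chromosomes. After rotating the phenotype and candidate markers by
`V^{-1/2}` from that fit, each marker is tested by least squares with a
per-marker estimated residual scale and a t(n−2) p-value. The estimated
scale (rather than a fixed-scale Wald χ²) was chosen because it makes the
scan collapse *exactly* to ordinary least squares in the no-polygene limit
and keeps the null type-I rate inside the binomial band at moderate n; at
GWAS-significant p-values the two statistics are practically
indistinguishable. Markers are pre-filtered at MAF > 0.05 (configurable).
PVE of a hit uses the conventional `2p(1−p)β²/Var(y)` with `Var(y)` the
variance of the de-regressed BLUPs; the formula is not uniquely defined for
correlated markers, so it is reported per marker without joint fitting.

Bayesian whole-genome regressions are single-site Gibbs samplers (numba)
with running residuals. Hyperpriors: residual scaled-inv-χ² with df 5,
slab df 4.1, scales matched so the prior expects half the phenotypic
variance to be genetic; BayesB/Cπ spike-and-slab with prior inclusion 0.05
(π sampled with a Beta(1,1) conjugate update in BayesCπ); Bayesian LASSO
per Park–Casella with λ² ~ Gamma update. Defaults are 6,000 iterations /
1,000 burn-in; the test-suite and acceptance runs use 1,500–2,500
iterations, which at these problem sizes reproduce the longer chains to
well within sampling noise. Chains are exactly reproducible under a seed.

Random Forest is delegated to scikit-learn with ntree = 500 and
mtry = 300 (clipped to the marker count with a warning).

## The synthetic generator

The generator emulates the study conditions every stage assumes: two panels
(defaults 300 + 600 clones — a downscaling of the real 429 + 872 — over 5
chromosomes × 1,000 markers of a 173k-SNP panel), three locations each,
alpha-lattice (2 reps, 25-plot blocks, 4 blocks per range) or augmented
(6 checks per 25-clone incomplete block) designs, ordinal 1–5 scores, and
location heritabilities {0.25, 0.4, 0.55} inside the 0.11–0.75 range such
trials span. Chromosome 4 carries a wild-donor introgression block
(8–16 Mb, carrier haplotype frequency 0.25, effect −0.5 per donor copy);
chromosome 5 plays the role of the QTL-cluster chromosome (three linked
QTL, one with dominance) on top of a polygenic background (200 markers,
additive variance 1.0).

Mechanics: allele frequencies are Beta(0.5, 0.5) (U-shaped, as in GBS
panels); LD comes from copying 40 founder haplotypes in 25-marker blocks —
sufficient to give LOCO and LD-score statistics realistic local structure
at desk scale, though it produces block-constant LD rather than a smooth
recombination-distance decay. A configurable fraction of markers (default
0.2) is designated ancestry-informative: fixed for the esculenta allele in
the background and carrying the donor allele inside the segment, with the
donor haplotype fully homozygous-diagnostic; heterozygous carriers arise
from pairing donor/recipient gametes (carrier status drawn per gamete).
A 1% genotype-error rate re-draws calls from Hardy-Weinberg, giving the
window caller realistic (mild) noise. Window-level ancestry truth is
recorded with the same 20-AI-SNP windowing the caller uses.

Phenotypes: the plot latent value is location mean + location-specific
genetic value + block/range effects + residual, with the residual variance
solved per location so the entry-mean H² matches the configured value
(block and range variances default to 0.1 each; an H² of 1 with nonzero
design variances is rejected as inconsistent). The ordinal score is
`1 + #cutpoints below the latent value` with cutpoints (−1.8, −0.6, 0.6,
1.8); both the ordinal surface and the latent truth are returned, since the
real scale is ordinal but the analysis treats it as numeric. Inter-location
genetic correlation is a single parameter (default 0.7 — the printed
de-regressed-BLUP correlations are attenuated and do not pin it down).
`simulate_clone_values` provides clone-mean phenotypes at a chosen
narrow-sense h² as a stand-in for de-regressed BLUPs in stage-2 simulations.

What passing tests on these data do *not* show: robustness to real GBS
missingness patterns and imputation artefacts (dosages here are nearly
complete), to spatial field trends beyond block/range effects, to
year-to-year GxE, or to pedigree structure between the panels (clones are
exchangeable draws from one founder pool).

## Introgression calling and LD

AI SNPs are matched to the marker map by (chrom, pos); allele orientation
is reconciled so dosage counts the glaziovii allele (swapped ref/alt flips
`d → 2 − d`; other allele pairs are dropped with a log). Windows are 20 AI
SNPs per chromosome in position order, trailing remainders dropped. The
majority genotype class is called iff its proportion is **at least** twice
the second class's (ties at exactly 2× are calls, per "at least"); a
unanimous or two-class window with zero second-class proportion is always a
call; windows with fewer than 10 informative SNPs (configurable) are
NoCall, missing genotypes being excluded from the denominators. Segments
are maximal runs of identical non-EE calls; NoCall breaks a run; output BED
is 0-based half-open.

LD r² is the squared Pearson correlation of dosage vectors (genotypic r²);
the LD score of a marker sums the small-sample adjusted
`r² − (1 − r²)/(n − 2)` over all markers within ±1 Mb *including itself*
(so an isolated marker scores 1, and the null expectation is 1). The
local-LD view reports pairwise r² to an index SNP within ±1 Mb (a 2 Mb
span); monomorphic markers are excluded with a log message.

## Pipeline and problem sizes

`pipeline.run` derives one seed per stage from the global seed
(`SeedSequence([seed, stage_index])`), so any stage can be re-run in
isolation and a config + seed reproduces the run byte-for-byte (the
manifest contains no timestamps). Test-suite and acceptance problem sizes
(panels of 100–900 clones, 150–6,000 markers, 10-seed replications) were
chosen so each statistical check resolves its effect size well above
Monte-Carlo noise while the whole suite stays in the minutes range; the
epistatic reference trait used in the model-ordering checks mixes two
strong locus-pair products with a 40-pair polygenic epistatic background
(0.6/0.4 variance split, h² 0.8), a regime in which both Random Forest
(sparse interactions) and RKHS (dense A×A-like covariance) can express
their advantage over a purely additive kernel.

## Known limitations

* Stage-1 REML is dense; it is comfortable to ~10⁴ plots and ~2×10³ random
  effect levels but is not built for national-program-scale trials.
* The scan tests one marker at a time; no conditional/joint multi-SNP
  analysis, no meta-analysis across panels beyond pooling de-regressed
  BLUPs.
* No imputation (the AR² field is consumed, not produced), no pedigree
  A-matrix, no HMM smoothing of ancestry calls, no haplotype-phase r².
* Bayesian samplers report posterior means only; no convergence
  diagnostics beyond the finite-chain guard.
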