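# Methods

## The estimand and the model

For gene *g* let `m_g` and `f_g` be the mean expression (RPKM) over male and
female individuals. The per-gene statistic is `log2(m_g / f_g)`. Under full
dosage compensation its expectation is 0 everywhere; for an uncompensated
Z-linked gene in a ZZ/ZW species it is 1 (two male copies, one female copy).
Chromosome-level inference is a linear regression of log2(m:f) on
chromosome identity with the intercept dropped: the coefficients are the
per-chromosome means, the regression F statistic tests the joint null that
all chromosome means are 0, and per-chromosome confidence intervals are
Bonferroni-adjusted for the number of chromosomes and exponentiated to the
ratio scale. With indicator coding this per-gene regression is algebraically
identical to a regression of per-chromosome mean responses weighted by gene
count (the tests assert the equivalence to 1e-10); inference uses the pooled
per-gene residual variance. Chromosomes contributing fewer than 2 genes are
excluded with a warning.

Ratio summaries follow the log2 workflow throughout: the headline Z m:f and
Am:Af intervals are gene-level bootstrap percentile CIs of the mean log2
ratio, exponentiated; Z:A ratios within a sex are differences of mean log2
expression between Z-linked and autosomal genes, exponentiated, again with
independent gene-level bootstraps. Working on log2 keeps these summaries
from being dominated by a few highly expressed genes. `mean_ratio_ci` also
offers ratio-of-means and mean-of-ratios modes; ratio-of-means is the
default for paired sex means because it involves no per-gene division and
is therefore the least biased at small gene counts.

## Quantification and filtering

RPKM is `1e9 · C / (N · L)` with count `C`, library size `N` and exon length
`L` (bp). Chromosome labels are transferred over strictly one-to-one
orthology with a reference species; genes without a 1:1 orthologue are
dropped and counted. The core gene-set filter keeps a gene only if its RPKM
exceeds the individual's own mean RPKM (across all genes) in at least 2
males and at least 2 females, and if |log2 m:f| ≤ 4. The reference
population of that threshold is genuinely ambiguous in shallow-coverage
practice; this package reads it per individual (a `global` grand-mean switch
is provided). Genes with a zero mean in either sex have no finite log2 ratio
and are dropped wherever an m:f table is built.

**Known property of the filter at very low coverage.** When per-individual
per-gene coverage is a handful of reads, retention near the expression
threshold is partly decided by sampling noise. For an uncompensated Z
(female signal at half the male level) the female support condition then
preferentially retains genes whose female counts fluctuated upward, which
biases the filtered Z m:f estimate downward — at the package's default
simulation conditions by roughly 5–10% when the true ratio is 2, and
negligibly when the true ratio is 1 (the condition is sex-symmetric there).
The unfiltered regression on all genes with nonzero sex means recovers
`2^(1−d)` without detectable bias, which is what the parameter-recovery
tests check; the filtered pipeline is retained as the practical analysis
route because it is what one would run on real shallow data. Estimates from
a single simulated study of 150 Z genes and 4+4 individuals carry ~6%
Monte-Carlo standard error; the acceptance script therefore averages the
pipeline estimate over 20 replicate simulations.

## GC correction

Library PCR makes expression estimates GC-dependent, and GC composition
differs between chromosome classes (micro- vs macro-chromosomes; a
relatively GC-poor Z), so uncorrected GC bias masquerades as
between-chromosome m:f differences. The correction is linear: OLS of
log2(m:f) on GC fraction, with the adjusted value defined as residual plus
grand mean. This preserves the grand mean to machine precision, leaves the
adjusted values numerically orthogonal to GC (|corr| < 1e-8), and is
idempotent because the refit always uses the preserved raw column.
Sex-specific GC fits on mean log2 expression are computed for reporting.
A caveat that the package does not model: because the Z is both GC-poor and
dose-affected, the chromosome signal itself leaks slightly into a GC slope
fitted across all genes; the slope-recovery test therefore injects its GC
effect under a null dose signal (d = 1).

## Sex-bias classes and the expression ANOVA

Classes follow fixed ratio cuts: male-biased (m:f > 2), unbiased
(0.8 < m:f < 1.2), female-biased (m:f < 0.5). The gaps [0.5, 0.8] and
[1.2, 2] are intentional; genes there stay unclassified rather than being
forced into a class. The class-vs-expression analysis is a one-way ANOVA of
log2 expression (per sex) on class, reporting F, df, R², and pairwise
two-sided t tests with Bonferroni adjustment as the post hoc procedure.

## qPCR Z-linkage

Genomic template copy number is 2 for autosomes in both sexes and for the
male Z, 1 for the female Z. Replicate Ct values are averaged per
(sample, gene, locus) before ΔCt normalization to an autosomal control on
the same sample; replicate scatter is QC output only. The per-locus sex
comparison is a pooled-variance Student t with df = n_m + n_f − 2 and a
one-sided p for male > female — the direction implied by Z linkage; the
bundled worked example's printed p-values match this tail at df = 6. The
gene-level call demands consistency across loci: Z-linked only if every
locus has p < α and m:f at or above 1.5 (the linear midpoint of the
expectations 1 and 2; a log-scale midpoint √2 can be passed instead),
autosomal only if every locus is below the boundary with p ≥ α, otherwise
ambiguous. Note that an autosomal gene trips the p < α arm at exactly the
test's type-I rate, so with k called autosomal genes a plate is fully
recovered with probability ≈ (1−α)^k even when the assay is perfect.
Amplification efficiencies from serial-dilution standard curves are
reported as QC and deliberately not folded into the ΔCt concentrations —
matched controls absorb locus-level efficiency differences, and the m:f
ratio, not the absolute concentration, carries the linkage signal.

The synteny-disruption check is a Fisher exact test of moved/stayed counts
in the tested set against a background orthologue set, with both one-sided
(greater) and two-sided p reported; a brute-force hypergeometric enumeration
serves as an independent oracle in the tests. The intron-length check
regresses observed amplicon lengths on intron-inclusive expectations; slope
≈ 1 with high R² indicates whole-gene movement rather than
retrotransposition.

## The simulators

`simulate_expression` draws per-gene baseline log2 expression from a normal
distribution, applies optional sex-specific GC slopes (centred at GC 0.5),
scales the female Z output by `2^d` relative to a single copy
(`d` = compensation degree, so the true Z m:f is `2^(1−d)`; compensation is
modelled as female up-regulation, the direction favoured for birds), and
draws integer counts from a negative binomial with `var = μ + φμ²`.
`φ = 0` switches sampling off and returns exact expectations — the
noise-free mode used by exactness tests. Defaults, chosen once for realism
at the shallow-coverage study design the package targets: 3400 autosomal
genes on 17 autosomes plus 150 Z genes; 4 individuals per sex; 6.3 reads
per gene and individual; baseline log2 sd 1.5 (a typical spread for brain
transcriptomes); dispersion 0.15 (≈ 39% biological CV across wild
individuals); d = 0.56 (true Z m:f ≈ 1.36); GC uniform on [0.35, 0.65] with
the Z shifted 0.05 lower; GC slopes 0 unless injected.

Features of real data deliberately not emulated: sequencing effort is equal
across samples by design and the sample sheet records that nominal depth,
so composition-driven library-size differences between sexes (an
uncompensated Z slightly shrinks female libraries) do not enter the RPKM
denominators; there is no mapping error, no assembly artefact, no
gene-length-dependent count bias beyond the RPKM length term, and GC bias
is linear by construction. Passing recovery tests therefore demonstrates
the estimator chain, not robustness to those real-data complications.

`simulate_qpcr` writes `Ct = base_locus − log_(1+E)(copies) + ε` per
replicate with ε ~ N(0, σ_Ct); an optional per-sample offset (template
loading) cancels exactly in ΔCt and defaults to 0. With triplicates at
σ_Ct = 0.15 and 4+4 samples, a plate-level mean m:f carries ~5% sd, most of
it coherent across loci because the control gene's Ct error is shared —
which is why recovery checks average over replicate plates.
`simulate_orthology` moves a Bernoulli(rate) fraction of genes to a
uniformly chosen different chromosome and records the truth.

## Numerical and design notes

- Determinism: every generator takes an integer seed into
  `numpy.random.default_rng`; pipelines derive stage seeds from the run seed
  via `SeedSequence`. Identical seeds give byte-identical outputs.
- Degenerate inputs: constant GC → degenerate-design error; all-identical
  density input → degenerate-bandwidth error; zero variance in both t-test
  groups with equal means → t = 0, p = 0.5; a positive standard-curve slope
  is rejected.
- KDE bandwidth is Silverman's rule on a grid padded by 3 bandwidths;
  the trapezoid integral of the density is checked to 1e-3.
- The bundled 21-candidate qPCR table lists one Ensembl id under two
  independent candidate entries, exactly as assayed; calls group by the
  candidate key.
- Plots (densities, per-chromosome and per-class boxplots) are optional
  outputs and never required by tests.

## Limitations

Positional profiles inherit the reference species' gene order and are only
as good as conserved synteny; the GC model is linear with no spline option;
the cross-species correlation defaults to Pearson on log2 ratios (Spearman
behind a flag) since the appropriate statistic is not settled; and at 4+4
individuals with ~6 reads per gene, single-study estimates of chromosome
ratios are dominated by sampling noise — the package's CIs make that
visible rather than hiding it.
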