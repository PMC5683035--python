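# Methods

## Scope and data model

`biparpred` studies genomic prediction within and between bi-parental
breeding populations. Its in-memory objects are: a genetic map (chromosome,
position in cM per marker); a founder pair (two fully homozygous inbreds,
one 0/1 haplotype each); a bi-parental population (families × polymorphic
markers coded +1/0/−1 relative to parent A, plus the founder alleles needed
to re-orient codes against a shared parent); long-format trial records
(population, family, environment, replicate, trait-env, value); and tidy
result tables for the prediction experiments. Files are plain CSV with
`#`-prefixed provenance headers (master seed, config hash).

## Simulation model

**Meiosis.** Gametes recombine under the Haldane map function: crossover
probability between adjacent markers `d` cM apart is `(1 − e^(−2d/100))/2`,
with independent assortment across chromosomes and no interference. The
Haldane choice is the standard minimal model when no interference estimates
are available.

**Families.** An F2-derived family is coded from the genotype of its
founding F2 plant (two F1 gametes); a BC1-derived family from the backcross
plant (one F1 gamete plus the recurrent parent-A haplotype). Real breeding
programmes genotype a bulk of plants per family; coding from the founding
plant approximates that bulk call while preserving the 1:2:1 (F2) and 1:1
(BC1) class expectations that the segregation filter tests. Markers
monomorphic in a cross are dropped from the population's panel.

**Segregation filter.** Per marker, a χ² goodness-of-fit test of observed
genotype-class counts against the generation's Mendelian ratio; markers with
p < α are removed. Default α = 0.05, no multiplicity correction — the
filter emulates routine quality control, not inference.

**Trials.** `y_ijk = μ + g_i + (ge)_ij + ε_ijk` over a balanced grid of `e`
environments × `r` replicates. Genetic values are linear in coded QTL
genotypes (QTL are a random subset of markers, default 40, standard-normal
effects) and rescaled so their sample variance equals σg² exactly; GxE and
residual deviations are i.i.d. normal. Given a target h², the noise
components are solved analytically from the entry-mean heritability formula
under a fixed GxE-to-residual ratio (default σge² = 0.5·σe², a moderate
interaction typical of drought-stress trial networks). Balanced
complete-block trials stand in for the field α-lattice: only σg², σge², σe²
enter the heritability formula, so incomplete-block recovery is out of
scope. Environment main effects are omitted from the generative model (they
cancel from entry means); the analysis model still carries a random
environment term so it is correct when they are present.

**Default genome.** 10 chromosomes × 170 cM with ~20 evenly spaced markers
per chromosome (≈200 markers), matching the low-density panels of the
reference metadata (mean 206 polymorphic SNPs). The study-conditions
generator sizes each synthetic population to its metadata row (exact family
and SNP counts) by drawing the panel from a denser 300-site map whose
founders differ everywhere.

**Half-sib sets.** Two crosses share one parent; the three haplotypes are
drawn independently (Bernoulli 1/2 per site) on a denser map (45
sites/chromosome), and each population keeps a random 180-marker panel of
its own polymorphic sites. Roughly a quarter of sites segregate in both
crosses, so panel intersections land in the 44–100 range (mean ≈ 70)
observed for real shared-assay panels. Codes are anchored to the shared
parent (+1 = homozygous shared allele in both populations) before any
across-population fit; without that anchoring the sign of every transferred
effect would be arbitrary.

**Heritability targets.** Per-regime defaults follow typical tropical maize
testcross values: GY 0.38/0.27, AD 0.55/0.47, PH 0.59/0.37 (WW/WS). The
trend study spreads targets evenly over [0.25, 0.60] across populations so
the h² response is identifiable.

## Estimation

**Variance components.** Balanced data use the expected-mean-squares
estimators (σe² = MSE; σge² = (MS_GE − MSE)/r; σg² = (MS_G − MS_GE)/(e·r)),
negatives truncated to zero before h² is computed. Unbalanced data fall
back to REML on the all-random model (environment, genotype, GxE,
residual): the three variance ratios are optimised on the log scale
(Nelder-Mead from three starts, xatol/fatol 1e−10, then a BFGS polish), with
the residual variance profiled out. On balanced data with all components
interior the two paths agree to better than 1e−6 relative; at a boundary
(e.g. no environment variance) REML pools the corresponding sum of squares
and the paths legitimately differ — the balanced closed form is the
estimator of record.

**BLUPs.** On balanced data, family BLUPs are centred means shrunken by
exactly h² (verified equal to the Henderson mixed-model-equation solution
with a diffuse environment effect); unbalanced data solve the MME directly.
BLUPs are reported as deviations (`attrs['basis']`). The phenotype used for
all downstream prediction and correlation is the per-family BLUP within a
management regime.

**RR-BLUP.** Genotypes enter as coded, uncentred, with an explicit
intercept (in a bi-parental cross the intercept absorbs coding means).
REML for λ = σε²/σu² transforms the data by an orthonormal contrast basis
orthogonal to the intercept (Helmert rows) and eigendecomposes the
contrast-space kernel, making the restricted likelihood a cheap scalar
function of λ; bounded minimisation runs on log λ over [1e−5, 1e5] with
xatol 1e−8. Effects solve the kernel-sized system and equal the classical
ridge solution by the Woodbury identity. Degenerate fits (constant training
phenotype, fewer than three lines) raise a typed error; replicate
correlations undefined in the prediction set (zero variance, fewer than
three pairs) are reported as missing, counted, and excluded from r_MG —
never imputed as zero. Missing genotype calls are mean-imputed per marker
(never produced by the simulator; supported for external data).

## Experiments

**Factorial grid.** Every (population, trait-env, TPS, MD) cell enumerated
deterministically; TPS defaults 30/50/70/90, MD defaults 50/100/all. Cells
with TPS ≥ family count are flagged infeasible rather than dropped. Each
replicate (default 100) redraws both the training sample and, for numeric
MD, the marker subset, uniformly without replacement; an evenly-spaced MD
mode is deliberately not offered — random subsets are the neutral choice
when no selection protocol is specified. The prediction set is always the
full complement of the training sample. Every replicate's RNG stream is
derived from (master seed, population, trait-env, TPS, MD, replicate), so
scenarios can run in any order, or in parallel, with bit-identical results.

**Half-sib prediction.** The entire training population fits the model on
the common re-oriented markers; a single correlation per ordered pair (no
resampling). Pair enumeration excludes full-sibs (two shared parents) and
pairs across genotyping-platform groups; the bundled metadata maps testers
T1/T2 to one platform group and T3–T6 to the other, which reproduces the
panel's 34 ordered pairs (and 204 predictions over six trait-envs). Note
one pedigree appears on both platforms; it is excluded as a pair by both
rules at once.

**Factor analysis.** One row per (population, TPS, MD) cell and trait-env;
h², TPS and MD enter as quantitative predictors, MD as the realized marker
count (the "all" level becomes the population-specific panel size). Pearson
correlations with two-sided t tests, and a sequential (type-I) ANOVA in the
fixed order h², TPS, MD (configurable); shares are SS/SST·100 and sum with
the residual share to 100 exactly.

## Numerical and design choices

- **Subgroup sizes.** Heritability subgrouping of a 22-population panel
  uses ascending sizes (6, 5, 5, 6): six populations in the lowest
  subgroup, five in each middle one, and the remaining six on top, so every
  population is assigned. Ties sort stably by input order. Sizes are
  configurable.
- **Seed contract.** One master seed; every component stream is derived
  from it plus a label tuple via CRC32 words feeding a `SeedSequence`.
  Identical seeds give bit-identical populations, trials and grids.
- **Truncation.** Negative variance estimates are truncated at zero before
  heritability; h² is therefore always in [0, 1].
- **Scale invariance.** Accuracy is invariant to positive affine transforms
  of either argument, so BLUP basis (deviation vs mean-added) does not
  affect r_MG.

## Problem sizes

The trend study runs 20 populations × 180 families × ~200 markers over the
4 × 3 grid with 100 training draws per cell (e = 4, r = 2, h² targets
0.25–0.60); component-recovery studies use 300 families with 50–100
simulated trials; the half-sib null uses 10 pairs (20 ordered predictions)
with ~180-marker panels. These sizes give Monte-Carlo standard errors well
below the effects being demonstrated while keeping a full run in minutes on
one CPU.

## What passing tests do and do not show

The generator reproduces the *structure* of low-density bi-parental
testcross data — segregation ratios, panel sizes, balanced multi-env
trials, calibrated heritabilities, half-sib marker sharing — not its field
realities: no α-lattice spatial structure, no dominance or epistasis in the
testcross values, no selection across cycles, no genotyping error or
missingness, and Gaussian GxE without crossover interaction structure.
Results on synthetic panels demonstrate that the estimators and the
experimental machinery behave correctly and that the qualitative responses
of r_MG to h², TPS and MD emerge under the stated model; they do not
certify accuracy levels for any particular real breeding programme.
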