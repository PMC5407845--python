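# Methods

This note documents the statistical models implemented in `coexqtl`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
to know about.

## Quantitative genetics of expression

**Repeatability (H²).** For a clonally replicated cohort, the upper bound
on broad-sense heritability is estimated per gene by one-way ANOVA across
genotypes: `V_E` is the pooled within-genotype mean square and
`V_G = max((MS_between − MS_within)/n0, 0)` with Henderson's
`n0 = (N − Σn_i²/N)/(a−1)` for unbalanced replicate counts; then
`H² = V_G/(V_G + V_E)`. The replicate-noise correction matters: the raw
variance of genotype means contains `V_E/r̄`, and with 2–3 replicates an
uncorrected estimator cannot fall below roughly `1/(1 + r̄)` no matter how
noisy the trait, so low heritabilities would be unestimable. Permutation
significance reassigns samples to genotype labels; the permutation
statistic is the *untruncated* between/within variance ratio, because
truncating negative components first creates a tie atom at zero and
makes null p-values non-uniform.

**Q_ST.** On genotype means, a two-level Henderson-III (method-of-moments)
ANOVA gives `V_between` (among populations) and `V_within` (among
genotypes within populations); `Q_ST = V_between/(V_between + 2 V_within)`
with negative components truncated to zero before the ratio. Method of
moments was chosen over REML deliberately: it is closed-form, fast enough
for 1,000 permutations per gene, and exactly checkable by hand arithmetic;
on balanced designs it coincides with the REML solution. Q_ST is flagged
undefined when both components are zero; permutation replicates with
undefined values are dropped from the null and the effective null size is
recorded, so the add-one-smoothed empirical p-value uses the per-gene
count of valid permutations.

**Empirical p-values.** Everywhere, `p = (1 + #{null ≥ obs})/(1 + B)`.
The add-one smoothing guarantees p > 0 (a plain fraction can return 0,
which breaks downstream q-value machinery).

**Expression filtering.** Genotype-mean profiles are classed unexpressed
(median 0), weak (variance < 0.05 and median < 2), stable
(variance < 0.05, median ≥ 2) or retained; only retained genes enter
mapping and networks. Variance is the n−1 sample variance across genotype
means.

## Hidden confounders

Latent technical factors are estimated as the leading PCs of the
genotype × gene matrix (genes centred) and regressed out per gene. The
number of PCs removed is chosen by running the association scan on each
candidate residual matrix over a grid (default 0–20) and keeping the k
with the most Benjamini-Hochberg-significant associations at α = 0.05,
ties to the smaller k. Two implementation details: (i) inside the
selection loop the nominal p-values are recomputed at `df = n − 3 − k`,
since residualising k PCs consumes k degrees of freedom — without this
the count rises with k mechanically even when nothing needs removing;
(ii) the expensive permutation FDR is run once, after selection, not
inside the loop.

## eQTL mapping

SNPs pass if minor allele frequency ≥ 0.1 and major genotype frequency
≤ 0.9 (the MGF filter removes associations supported by a single
deviating genotype class, which can carry MAF ≈ 0.5), computed on
non-missing calls; SNPs with > 10% missing calls are dropped. The
population-structure covariate is the first PC of the LD-pruned dosage
matrix (greedy r² > 0.2 pruning in non-overlapping 50-SNP blocks, keeping
the earlier SNP).

Each gene × SNP pair is fitted by OLS,
`expression ~ 1 + dosage + covariate`, on genotype means; the dosage term
reports β, t (df = n − 3), two-sided nominal p, and R² as the squared
partial correlation given the covariate. Missing genotypes are excluded
pairwise. Pairs with nominal p < 1e-6 form the candidate set (the scan's
output threshold; the same cut the hotspot scan uses). The null is built
by permuting genotype labels globally — one permutation shared by all
genes per iteration, preserving gene–gene correlation — with the
genotype-derived covariate travelling with the labels; per gene the
maximum |t| across all SNPs is recorded, giving each gene a B = 1,000
family-wise null. Candidate associations get add-one empirical p-values
against their gene's null and Storey q-values across the candidate set
(π0 from a cubic fit to the λ profile, λ ∈ {0.05, …, 0.90}, capped at 1;
π0 = 1 reproduces BH). Significant associations (q ≤ 0.05) define eGenes
and eSNPs.

Local = same chromosome and ≤ 100 kbp from the gene span (distance 0
inside the gene); otherwise distant. Redundant eSNPs are collapsed per
gene by entering dosage columns in ascending genomic order into a joint
OLS fit and masking columns aliased by earlier entries (pivot tolerance
1e-8); the joint adjusted R² × 100 is the gene's combined %VE. Which of
two collinear eSNPs survives depends on entry order; the %VE does not.
The hotspot scan tiles chromosomes with non-overlapping 100-kb windows
and counts distinct eSNPs and distinct associated genes among
nominal-p < 1e-6 associations.

**MAF-fixing subsampling.** To compare effect sizes free of MAF-driven
power differences, samples are dropped greedily — each step removing the
sample whose removal brings the folded MAF closest to 0.25, seeded RNG
breaking ties — until 40 remain; success requires a final MAF within
±0.02. An all-heterozygote SNP is a designed failure case (its MAF is
0.5 under any subset).

## Genomic context

Per strand, the highest-priority feature containing the SNP wins:
UTR > exon/intron > upstream/downstream flank (2 kbp, strand-aware) >
intergenic. Genes overlapping on opposite strands both contribute a label
(intentional double counting); a SNP inside same-strand overlapping
models where one gene's intron covers another's exon is discarded as
ambiguous, as is a SNP inside a gene span but in none of its
sub-features. Densities are counts per kbp of each feature class;
positional profiles bin flanks per kbp and rescale gene bodies to 20
relative bins, split by whether the eSNP lies in its own eGene or a
neighbour. The context flank is 2 kbp; the population-genetic site
categories use 1-kbp flanks — the two analyses historically use different
window conventions and both are exposed as parameters.

## Co-expression network

Pearson correlations r across genotype means (after confounder removal);
unsigned adjacency `a = |r|^β` with β = 5; signed topological overlap

    TOM_ij = |ã_ij + Σ_{u≠i,j} ã_iu ã_uj| / (min(k_i, k_j) + 1 − a_ij),

with `ã = sign(r)·a` and `k_i = Σ_{u≠i} a_iu`. The unsigned adjacency
keeps strongly negatively correlated genes in one module; the signed TOM
makes third-party support cancel when correlation signs are inconsistent.
A brute-force triple-loop oracle in the tests pins the matrix
implementation to 1e-10.

**Module detection** clusters 1−TOM by average linkage with a static cut,
in two stages. The cut height (when not given) is the one maximising the
number of clusters of at least `seed_size = 5` genes; those seeds anchor
the modules. Each seed is then represented by its 10 most intra-connected
genes and every gene joins the seed with the highest mean TOM to those
representatives, if that exceeds 100× the lower quartile of that seed's
affinity distribution (the soft-threshold power compresses ratios: 100 in
TOM is ≈ 2.5 in correlation at β = 5); otherwise the gene stays in the
unassigned module 0. The representative stage exists because a plain
static cut fails on realistic inputs: TOM values live within ~1e-3 of
each other, unrelated genes attach at the same heights as between-module
merges, and average linkage dilutes the hub signal as clusters grow,
stranding module peripheries. Modules below `min_module_size = 30`
dissolve into label 0; labels are renumbered by decreasing size.

**Connectivity and cores.** kTotal is the adjacency row sum (self
excluded); kWithin/kOut split it by module co-membership;
`kDiff_norm = kWithin/(m−1) − kOut/(N−m)` puts both on a per-partner
scale so modules of different sizes are comparable. Module cores are the
top `ceil(0.10 × size)` genes by kDiff_norm among candidates with
kWithin > 1 (boundary ties to higher kWithin, then gene id); a module may
legitimately have no cores. The periphery holds genes of degree exactly 1
in the hard-thresholded graph, |r| > 0.4 by default or, optionally, the
threshold keeping the top 0.1% most correlated pairs. Betweenness is
computed on the same hard-threshold graph, normalised by (N−1)(N−2)/2.

**Scale-free fit** bins kTotal into 10 equal-width bins and regresses
log10 frequency on log10 mean connectivity; **label permutation tests**
shuffle a per-gene attribute across the fixed topology (default 10,000
shuffles) and score enrichment, depletion or two-sided displacement with
add-one empirical p-values.

## Diversity and divergence

From aligned intra-specific haplotype panels: S, θπ (per-site mean
pairwise diversity with the n/(n−1) factor), Watterson's θ = S/(a₁L),
and Tajima's D with the 1989 variance constants; D is undefined (NaN,
not zero) when S = 0, and identically 0 for n ≤ 3 where θπ ≡ θW. Site
degeneracy (0-fold / 4-fold; 2- and 3-fold excluded from both masks) is
classified from the reference haplotype's codons against the standard
genetic code; polymorphic codons keep the reference classification.
Statistics are reported for seven site categories (1-kbp flanks, UTRs,
introns, 0-fold, 4-fold) plus a gene-level aggregate; genes or categories
with fewer than 50 covered sites are flagged excluded.

Divergence to the outgroup uses Nei–Gojobori (1986) counting on the
majority-rule consensus vs the outgroup CDS: fractional synonymous/
nonsynonymous site counts averaged between the sequences, observed
differences averaged over equal-weight mutational pathways (pathways
through stop codons skipped), and Jukes–Cantor correction
`d = −(3/4)·ln(1 − 4p/3)`. dN/dS is undefined when dS = 0 or p ≥ 3/4.
NG86 replaces likelihood-based codon models deliberately: it is
self-contained, exactly testable, and adequate for the ~3% divergences
the pipeline targets; it will underestimate rates at high divergence.
Codons containing stops (possible when consensus construction combines
two individually stop-free variants) are skipped in the panel-level
wrapper and raise in the strict pairwise API.

## Integration

The gene summary joins five expression measures — kTotal, core flag,
expression level and variance (both computed *before* confounder removal,
where biological signal is intact), eGene flag — with the four sequence
metrics. Group contrasts are Mann-Whitney U (exact enumeration when both
groups ≤ 8, tie-corrected normal approximation otherwise) with
Hodges-Lehmann location shifts and distribution-free 95% CIs. The scaled
PCA standardises all five measures (flags as 0/1), eigendecomposes their
correlation matrix, orients each PC so its dominant variable loads
positively, and reports squared-loading contributions. Partial Spearman
correlations rank-transform all variables and read the partial
correlation off the inverse rank-correlation matrix, with t-approximate
p-values at df = n − 2 − #controls. The paralog analysis scores each
pair's expression correlation against its eGene count (OLS slope),
against size-matched random pairs (permutation null on the mean
correlation) and tests eGene under-representation among paralogs
hypergeometrically.

## The synthetic cohort generator

Expression for sample s of genotype g in population q is

    y = μ + Σ_e β_e·dose_e(g) + Σ_m λ_m·f_m(g) + √q_pop·u(pop)
        + resid(g) + Λ·c(s) + ε(s),

with all genotype-level shares defined as fractions of the genotype-MEAN
variance (normalised to 1), so a planted eQTL share of 0.4 is what the
mapping stage should measure as R² ≈ 0.4 on genotype means. Replicate
noise ε is sized from the per-gene H² target
(`Var(ε) = V_G(1−H²)/H²`), which bounds the feasible planted shares: at
2–3 replicates a module loading of 0.9 requires H² ≳ 0.64. Planted eQTL
effects get random signs; planted eSNPs are chosen among SNPs that pass
the default MAF/MGF filters with margin, so every planted signal is
discoverable. Module factors are genotype-level standard normals; hubs
load at the core loading, peripheral members at the lower loading with
random sign (exercising the unsigned network). Hidden confounders are
sample-level factors with per-gene normal loadings. LD is generated by
neighbour copying (a SNP duplicates its left neighbour's column with
probability `ld_copy_prob`) — enough to exercise LD pruning and
redundant-eSNP collapsing, but not a recombination model.

Sequence panels place segregating sites at per-site probability
θ·a₁(n) with derived-allele counts from the neutral SFS (∝ 1/i), which
makes θW and θπ unbiased for θ and Tajima's D ≈ 0 without a full
coalescent simulation. Haplotype 0 remains identical to the reference so
degeneracy classified from the first haplotype matches the generating
masks (SFS statistics depend only on derived-allele counts, not carrier
placement). The "constrained" regime emulates purifying selection three
ways: overall θ scaled by 0.7 (linked-selection diversity loss),
nonsynonymous changes — classified per change against the reference
codon — accepted with probability 0.1 (so dN/dS and θ0/θ4 land near the
suppression factor; suppressing whole 0-fold sites alone would leave the
nonsynonymous changes at 2-fold sites untouched and stall dN/dS near
0.25), and the SFS tilted to ∝ 1/i^1.5 (rare-variant skew, negative D).
Stop-creating changes are never introduced, in either regime.

What the generator does **not** emulate: read-level count noise and
normalisation (expression is emitted on the normalised scale directly),
recombination maps and realistic LD decay, allele-specific expression,
demography (bottlenecks/expansion), gene-density heterogeneity, or
correlated missingness. Passing tests therefore demonstrate correctness
of the estimators and the internal consistency of the pipeline under its
own assumptions — not robustness to the full messiness of field data.

## Problem sizes and defaults

Study-scale checks run at 86 genotypes × 200 genes × 2,000 SNPs with
1,000 permutations (the cohort shape the pipeline is designed around);
the module-recovery check runs at 300 genotypes because a peripheral
loading of 0.3 is below the identifiability limit at 86 genotypes — an
oracle assigning genes by correlation with the *true* factors only
reaches ARI ≈ 0.78 there, so no detector can meet a 0.9 bar; at 300
genotypes the implemented detector reaches ARI ≥ 0.94. Network
permutation tests are scaled to 2,000 shuffles in the checks (10,000 in
production defaults). The end-to-end integration cohort uses peripheral
loadings of 0.5 and one planted sample-level confounder: these are the
generator's default "realistic" conditions, chosen so that module
membership is identifiable at 86 genotypes and the confounder-selection
stage has something genuine to remove (with no confounder present, the
count profile over k is flat and the argmax wanders by ±1–2 counts of
jitter).

## Known limitations

- Method-of-moments variance components can be noisier than REML on
  strongly unbalanced designs; components are truncated at zero, which
  biases small components slightly upward.
- The candidate threshold (nominal p < 1e-6) bounds the resolution of the
  empirical FDR: genes whose best association misses the threshold are
  invisible to the permutation stage.
- Module detection is tuned for hub-and-periphery factor structure; very
  diffuse modules without hubs will be under-assigned.
- NG86 saturates above ~30% divergence; use a likelihood method there.
- The paralog permutation null draws unordered random gene pairs without
  matching genomic distance or expression level.
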