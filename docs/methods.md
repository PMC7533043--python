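# Methods

`facsex` implements a comparative population-genomic analysis for a pair of
long-diverged, phylogenetically independent sister lineages of a
facultatively sexual, highly inbred microbe (the motivating system is wild
*Saccharomyces paradoxus* from Europe and Far East Asia, with the North
American lineage and *S. cerevisiae* as outgroups). The input is a
per-chromosome multiple alignment of strain consensus genomes plus two
outgroup rows, a GFF3 annotation on the in-group reference, and strain
metadata. This note documents the models, the estimators, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## Coordinates, gene filters and site classes

All internal coordinates are 0-based half-open over the concatenated
genome; GFF3 (1-based inclusive) is converted at the boundary. Analyses
use only:

- genes that pass a paralog screen (no other gene with global alignment
  identity ≥ 0.8 over ≥ 100 bp, computed with edlib after a shared-k-mer
  prefilter) — both members of a matching pair are dropped, as in an
  all-against-all search where duplicates hit each other;
- "core" genes, i.e. genes not overlapping user-declared subtelomeric
  spans (subtelomere definitions are reference-specific and are therefore
  a required input, not a default);
- *complete* sites: no gap or N in any in-group strain of either
  population or in either outgroup. Gap and N are treated identically as
  missing.

Codon degeneracy is computed on the **inferred common ancestral codon**:
with the other two positions held at their ancestral state, a position is
k-fold when k of the four bases encode the same amino acid under the
standard genetic code (1 → 0-fold, 2 or 3 → 2-fold, 4 → 4-fold; the
3-synonymous isoleucine case is grouped with 2-fold). 2-fold sites are
annotated but excluded from all headline statistics, which contrast
0-fold (selected) against 4-fold (neutral) sites. A gene whose ancestral
frame contains an internal stop is excluded with a warning.

## Polarization

Every complete site is polarized with a two-tier outgroup rule:

1. one population polymorphic, the other monomorphic → the monomorphic
   population's allele is ancestral, if it segregates in the polymorphic
   population; otherwise the site is *missing*;
2. a fixed difference between monomorphic populations → the distant
   (North American) outgroup decides; if it matches neither allele the
   site is *missing*;
3. both monomorphic and identical → monomorphic;
4. both polymorphic, or more than two alleles across the populations →
   the distant outgroup is consulted; if its allele segregates in both
   populations it is ancestral (status `polymorphic_both`), otherwise
   *missing*. (Truly independent sister lineages should show no shared
   polymorphism; real inputs may violate this, so the tie-break is
   attempted before discarding.)

The status enumeration includes `polymorphic_both` because rule 4 can
succeed; monomorphism is evaluated on the analyzed sample, with no
frequency thresholds. Derived-allele (DA) carriers are strains not
carrying the ancestral allele; fixed differences make every strain of the
derived population a carrier. Resolved ancestral alleles concatenate into
the common ancestral sequence ('N' where unresolved), which then drives
the degeneracy annotation above — so the pipeline runs: structural
annotation → completeness → polarization → ancestral sequence →
degeneracy.

## Diversity

π (mean pairwise differences per site), Watterson's θ_w
(segregating sites / (a_n · L), a_n = Σ_{i<n} 1/i) and Tajima's D (the
classical constants) are computed per chromosome and population over the
complete sites of a chosen degeneracy class. Genome values are means
weighted by the per-chromosome count of analyzed sites of that class —
not raw chromosome length — so the per-bp denominators stay consistent;
per-chromosome values are retained for the paired across-chromosome
t-test used for all between-population contrasts. D is undefined and
excluded from averages when nothing segregates; an exactly-constant
per-chromosome difference vector is reported as p = 0 (or p = 1 at zero
mean) rather than NaN.

## Recombination and the frequency of sex

For a partially selfing facultative sexual, the scaled parameters are
θ = 4N_e u/(1+F) and ρ = 4N_e r S (1−F), where u is the mutation rate
per bp per cell division, r the recombination rate (M/bp) per meiosis, F
the inbreeding coefficient and S the number of sexual generations per
mitotic generation. Dividing gives the estimator

    S = (ρ/θ) · (u/r) / [(1+F)(1−F)],

with θ taken from 4-fold π. F defaults to 0.98 (the published estimate
for this yeast, reflecting extreme selfing and intratetrad mating); u and
r have **no defaults** — they are study-specific inputs. ρ per bp is the
genome total of per-chromosome 4N_e r estimates divided by the full
reference length (defaults 11,986,733 bp for the European/UK reference
and 11,813,124 bp for the Far Eastern one), not the filtered alignment
length. Multiple runs per chromosome are averaged unweighted; chromosome
totals are summed.

The fidelity path imports per-chromosome 4N_e r from LDhat-style runs
(two dialects: a two-column `chromosome 4Ner` table, or a raw text file
containing a `4Ner ... = value` line). The built-in alternative is an
explicit approximation: r² between all qualifying biallelic complete
sites (minor-allele frequency ≥ 0.1 by default), binned by physical
distance, fit by weighted least squares to the sample-size-adjusted
drift expectation E[r²] ≈ (10+C)/(22+13C+C²) + 1/n with C = ρ·d. On
coalescent simulations it recovers ρ within a factor of ~1.5 (typically
biased ~0.7× low, as is common for r²-decay fits), which propagates into
the same factor on S; the LDhat import path should be preferred whenever
available.

## Divergence and the 0/4-fold ratios

Each strain's divergence from the inferred common ancestor counts the DAs
it carries per class (fixed differences count for every strain), divided
by the complete-site denominator of that class. Fixed vs. polymorphic is
evaluated within each population independently. The population 0/4 ratio
uses the mean per-strain per-bp divergence; by default per-chromosome
ratios are combined weighted by 4-fold complete-site counts (a pooled
genome mode is available — the two differ slightly, which is why a pooled
0.00228/0.01236 ≈ 0.1845 does not exactly equal a per-chromosome-weighted
value). Chromosomes with zero 4-fold divergence are flagged and dropped
from the paired test with a warning.

## Among-strain variation

The central randomization test holds each site's derived-allele count k
fixed and redraws which k strains carry it, uniformly without
replacement, independently per site and permutation; the statistic is the
across-strain variance of total DA counts. The 0/4-ratio variant permutes
within each degeneracy class separately and excludes (with a warning)
strains whose 4-fold DA count is zero. Group contrasts (e.g. strains from
a high-radiation area vs. others) permute labels; the statistic is the
absolute difference of group means, making the test two-sided. All
Monte-Carlo p-values use the add-one estimator (1 + #{null ≥ obs})/(1+N),
so p is never 0 and ties count toward the null — at N = 1,000 the
smallest attainable p is 1/1001, and for the label-permutation group test
the attainable minimum is further limited by permutations that redraw the
identical partition (expected ≈ 2N/C(n, n₁) exact ties). Saturated sites
(all strains carriers) are permutation-invariant and legal; an error is
raised only when no derived allele exists at all. Covariate analyses
report Pearson r of per-strain DA totals against e.g. latitude, plus a
per-chromosome concordance count assessed with the exact one-tailed sign
test P[Binom(n_chrom, ½) ≥ k]. Default 1,000 permutations; every test
takes an explicit seed and is bit-reproducible.

## Distribution of fitness effects

The DFE model is the classical two-stage construction: the neutral
(4-fold) spectrum fits a step-change demography; the selected (0-fold)
spectrum, with demography fixed, fits a gamma distribution of deleterious
effects.

Numerics: allele frequencies evolve on a discrete Wright–Fisher grid of
K1 = 100 haploid copies. New mutations enter at count 1 at constant
influx; the ancestral standing distribution solves the linear balance
equations; a size change to K2 = ratio·K1 (clipped to [10, 400]) is
applied by binomial resampling followed by t2·K2 generations of explicit
propagation with continued influx (t2 is measured in units of N2
generations); the sample spectrum is a binomial down-sampling to n.
Selection acts deterministically with per-copy coefficient
s = γ/(2K), γ = 4N_eS_d, capped at |s| ≤ 0.95 — effects too strong for
the grid contribute essentially no polymorphism, matching their
biological behaviour, but this also means the SFS carries little
information about the far tail of the gamma distribution (mean estimates
inherit the usual DFE-fitting uncertainty there). The gamma integral uses
mass-binning on a fixed 36-point log grid of γ ∈ [10⁻², 2·10⁴] with
below/above-grid mass assigned to the end points; spectra are cached per
demography.

The likelihood is Poisson per frequency class (independent sites): classes
1..n have mean θ·E_i and class 0 absorbs the remaining sites; θ is a free
nuisance scale per site class. Fitting is multi-start Nelder–Mead in log
parameters, with the constant-size model always evaluated as a fallback
candidate in stage 1. Fixations are accumulated only over the modelled
post-change epoch, so class-n mass is dominated by all-derived sampling of
segregating sites; divergence-calibrated absolute fixation counts (and
hence absolute log-likelihood or E_s values comparable to other software)
are outside this parameterization. We report the gamma shape b, the mean
population-scaled effect 4N_eS_d (scale = mean/shape), and the gamma mass
in severity bins [0,1), [1,10), [10,100), [100,∞) — the bin edges are a
declared choice.

Identifiability: the shape is estimated robustly, but the mean lies on a
flat shape–mean likelihood ridge — the SFS contains almost no information
about the gamma tail, so even at 10⁶ selected sites individual data draws
can place the maximum far along the ridge (a well-known property of this
model family). Parameter-recovery checks therefore evaluate the median
over replicate fits, and users should treat single-dataset mean estimates
as order-of-magnitude quantities unless profiled or bootstrapped.

Nested models are compared with likelihood-ratio tests (χ² with the
parameter-count difference as df; an alternative falling below its null
beyond numerical tolerance raises as an optimization failure). The
positive-selection test adds a proportion p_a of advantageous mutations
with a single scaled effect γ_a (log-interpolated on a precomputed grid
of beneficial spectra) and tests p_a = 0 with df = 2. Conservation
classes label each 0-fold site CON when its codon translates identically
in the two outgroups, NCON otherwise, unclassified on missing data; both
classes are meant to be tested against the same total 4-fold spectrum.

## Synthetic data

`simulate_population` draws a coalescent sample (msprime, haploid samples,
infinite sites by default with collisions pushed to adjacent free integer
sites) with given per-bp θ and effective ρ; `effective_rates` encodes the
selfing identities so that a simulation at (u, r, N, F, S) has exactly the
effective rates the estimator assumes, making the S-recovery test an exact
algebra check up to coalescent noise. A forward Wright–Fisher mode
(N ≤ 500) cross-validates the scaling.

`simulate_two_lineages` is a direct generative model rather than one deep
coalescent history, so every quantity has recorded truth: a random coding
genome (ATG…stop genes with uniform non-stop codons, plus intergenic
spacers) defines the true ancestor and site classes; each lineage stem and
each outgroup receives Bernoulli fixed differences; within-population
polymorphism comes from per-population msprime samples whose variants are
placed on unused sites; strains optionally receive latitude-proportional
extra private mutations (a multiplicative terminal-branch rate effect —
the simplest mechanism producing a south-more-derived-alleles cline).
Mutations at 0-fold sites are thinned by acceptance sampling against the
gamma DFE: fixed differences by the relative fixation weight
γ/(e^γ − 1), polymorphisms by the milder sojourn weight 2(1 − e^{−γ/2})/γ,
so fixed 0/4 ratios fall below polymorphic ones, as purifying-selection
theory predicts. Defaults mirror the motivating study's conditions (23 vs.
8 strains, ~1.2× faster stem in lineage A, ~2× higher diversity in A,
gamma shape 0.23 and mean ≈ 300, inbreeding F = 0.98 for the effective-
rate identities). Because sites are drawn disjointly, the data are exactly
infinite-sites: polarization must be error-free, and per-strain DA totals
must equal the recorded per-strain mutation counts — both are asserted in
tests. What the generator does **not** emulate: homoplasy and back
mutation, alignment error, linked selection, gene conversion, base
composition and codon-usage bias, and realistic intergenic structure; the
estimator tests therefore validate the statistical machinery, not
robustness to those real-data complications.

`simulate_sfs` samples Poisson counts from the DFE model's own expected
spectra, making DFE parameter recovery a self-consistency check of the
likelihood and optimizer (not of the Wright–Fisher machinery against an
external standard; that is covered by the neutral 1/i and qualitative
selection checks).

Two calibration details worth knowing: realized 4-fold π in
`simulate_two_lineages` falls below the nominal θ parameter, because
variant placement competes across site classes and 0-fold variants are
DFE-thinned (selection genuinely removes diversity); population contrasts
are unaffected. And the neutral Tajima's-D check simulates a *recombining*
20 kb region (ρ_eff = 0.002/bp): without recombination each replicate is a
single genealogy, so the mean of D across replicates is dominated by
genealogy-shape noise (sd ≈ 0.85 per replicate) rather than by the
statistic being validated; with recombination the per-replicate sd drops
to ≈ 0.36 and the check measures the estimator.

## Problem sizes and reproducibility

Simulation-based checks use deliberately desk-scale sizes chosen as the
package's own defaults: 20 coalescent replicates of n = 20 over 200 kb for
S recovery, 2·10⁵ neutral + 10⁶ selected sites for DFE recovery, 200 null
datasets for randomization-test calibration, 200 neutral replicates for
the Tajima's D check. All randomness flows through explicit integer
seeds; identical seeds give byte-identical outputs.

## Known limitations

- The DFE stage does not model divergence-calibrated fixations, so its
  absolute likelihoods and E_s-style scale parameters are not comparable
  across software; only shape, mean 4N_eS_d and severity proportions are
  interpretable here.
- The built-in ρ estimator is a moment fit to an equilibrium drift
  approximation; under strong demographic non-equilibrium its bias can
  exceed the factor seen in the neutral tests.
- Polarization assumes the sample represents population monomorphism;
  with very small samples, segregating sites mis-read as fixed inflate
  the fixed-difference class (a consensus mode for the sister-population
  outgroup is deliberately not the default).
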