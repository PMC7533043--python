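# facsex

Comparative population genomics for facultatively sexual microbes:
estimating population size, the frequency of sex, generation time and the
efficacy of purifying selection from whole-genome alignments of two sister
lineages plus outgroups.

## Who this is for

Microbes such as the wild yeast *Saccharomyces paradoxus* reproduce
mitotically most of the time, go through meiosis rarely, and self or mate
within the tetrad when they do (inbreeding coefficient F ≈ 0.98). Given a
multiple alignment of strain genomes from two phylogenetically independent
sister populations and two outgroup sequences, this package answers:

- How large are the two populations (silent-site diversity π, Watterson's
  θ_w, Tajima's D)?
- How often do they have sex? From the identities θ = 4N_e u/(1+F) and
  ρ = 4N_e r S(1−F),

      S = (ρ/θ) · (u/r) / [(1+F)(1−F)]

  where S is the number of sexual generations per mitotic generation, u
  and r the per-division mutation and per-meiosis recombination rates,
  and ρ comes from LDhat-style per-chromosome 4N_e r estimates (or a
  built-in LD-decay approximation).
- Which lineage has divided more often since the common ancestor?
  Derived alleles (DAs) are polarized with a two-tier outgroup rule and
  counted per strain; more 4-fold (synonymous) DAs per bp means more
  cell divisions, i.e. a shorter generation time.
- How effective is purifying selection? The 0-fold/4-fold DA ratio,
  partitioned into fixed vs. polymorphic sites, and a two-stage maximum-
  likelihood fit of a gamma distribution of deleterious fitness effects
  (step-change demography fit to the 4-fold spectrum, then gamma shape b
  and mean 4N_eS_d fit to the 0-fold spectrum) with likelihood-ratio
  tests for site-class partitions and for positive selection.
- Do individual strains differ in mutation accumulation? Randomization
  tests that reshuffle DAs among genomes at fixed site frequencies, group
  contrasts, and covariate correlations (e.g. latitude) with an exact
  per-chromosome sign test.

A fully seeded synthetic-data generator (msprime-based coalescent samples,
plus a two-lineage genome simulator with recorded per-strain truth)
provides ground-truth validation for every estimator.

## Worked example

`examples/02_diversity_and_frequency_of_sex.py` simulates a two-lineage
dataset, computes 4-fold diversity, and applies the frequency-of-sex
estimator to the published genome-wide summaries of the European (EU) and
Far Eastern (FE) wild-yeast populations:

```
EU: n=23  pi4=0.00100  theta_w=0.00115  Tajima's D=-0.38
FE: n=8   pi4=0.00054  theta_w=0.00071  Tajima's D=-0.99

calibrated u/r = 6.336e-05
EU: S = 0.000621  -> one sexual generation every 1,610 mitoses
FE: S = 0.000193  -> one sexual generation every 5,169 mitoses
```

The simulated lineage A has ~2× the silent diversity of lineage B (larger
population), both have negative Tajima's D (excess rare variants,
population expansion). On the real summaries, the estimator turns
θ = 0.0021 and ρ = 0.000815 M/bp (EU) into roughly one sexual generation
per 1,600 mitoses, and the FE values into one per ~5,200 — sex is rare in
both populations but ~3× more frequent in the larger, more diverse one.

The other examples cover polarization against recorded simulation truth
(`01`), 0/4-fold divergence ratios under a gamma DFE (`03`), among-strain
randomization tests and the latitude cline (`04`), and DFE parameter
recovery (`05`). Each prints what it computes and what the numbers mean.

## Layout

- `src/facsex/io_formats.py` — alignment FASTA / GFF3 / metadata TSV /
  LDhat-summary reading, concatenated-coordinate bookkeeping
- `src/facsex/degeneracy_filter.py` — paralog screen, core/complete-site
  filters, ancestral-codon degeneracy annotation
- `src/facsex/polarize.py` — two-tier outgroup polarization, ancestral
  sequence, derived-allele matrix
- `src/facsex/diversity.py` — π, θ_w, Tajima's D, paired chromosome tests
- `src/facsex/recombination_sex.py` — ρ import/normalisation, LD-decay
  estimator, frequency of sex
- `src/facsex/divergence.py` — per-strain DA profiles, 0/4-fold ratios
- `src/facsex/individual_variation.py` — randomization tests, sign test,
  covariate correlations
- `src/facsex/dfe.py` — Wright–Fisher SFS machinery, gamma-DFE fitting,
  LRTs, conservation classes
- `src/facsex/synthetic_data.py` — seeded generators with recorded truth

See `docs/methods.md` for the models, numerical choices and limitations.
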