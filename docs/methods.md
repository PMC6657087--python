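# Methods

## The problem the package addresses

Recent radiations leave two genealogical signatures that are easy to
confuse: incomplete lineage sorting (ILS), where ancestral polymorphism
sorts discordantly but symmetrically across the species tree, and
introgression, where hybridisation moves alleles asymmetrically between
particular lineages.  For a four-taxon hypothesis (((P1,P2),P3),O) with the
outgroup defining the ancestral allele "A" and "B" the derived allele, ILS
produces the two discordant biallelic site patterns ABBA and BABA with equal
probability, while gene flow between P3 and one of P1/P2 inflates exactly
one of them.  Patterson's D,

    D = (n_ABBA − n_BABA) / (n_ABBA + n_BABA),

is therefore centred on zero under ILS alone.  The package implements this
test exhaustively over all donor/recipient configurations of an ingroup,
together with the surrounding stages of a SNP-based species-boundary study:
site filtering and format conversion, Bayes-factor ranking of
species-delimitation models, genetic-distance summaries, and a
base-composition homogeneity screen.

## Significance and direction of D

The null hypothesis n_ABBA = n_BABA is tested with a Pearson χ²
goodness-of-fit statistic against the 50:50 split,

    χ² = (n_ABBA − n_BABA)² / (n_ABBA + n_BABA),   df = 1,

without continuity correction; the identity χ² = D²·(n_ABBA + n_BABA) holds
and is asserted by a property test.  This choice reproduces, from the
packaged published counts, every printed D (3 decimals), every printed
p-value at its own printed precision, and every direction call at α = 0.01
for the 30-hypothesis *Montipora* table — the package's justification for
the approximation, not a claim about how the original numbers were produced.
A delete-one block-jackknife alternative (`d_statistic_jackknife`) is
provided for data with linked sites, since the independent-site χ² is
anti-conservative under linkage.

Direction calls: p < α and D < 0 → "13" (BABA excess, P1–P3 sharing);
p < α and D > 0 → "23"; D = 0 never yields a call regardless of p.

Counting modes: the default `strict` mode uses only sites where all four
samples are called and homozygous (the homozygous outgroup call polarises
the site); sites failing this are excluded with tallied reasons.  The
`frequency` mode keeps heterozygous information by accumulating the
weights (1−f1)·f2·f3·(1−f4) and f1·(1−f2)·f3·(1−f4) with f_i the
alternate-allele dosage / 2.  Which convention a given published table used
is generally not recoverable; both are exposed rather than guessed.

## Site filters

The filters mirror the vcftools options a RADseq study applies
(`--remove-indels --max-missing 0.50 --thin 300 --mac 3 --minQ 30`), in a
fixed order chosen for determinism and reported per rule:
indels → multiallelic → minimum QUAL → minor-allele count → call rate →
thinning.  Multiallelic SNPs are removed because both the 0/1/2 genotype
coding and outgroup polarisation require biallelic sites.  The minor-allele
count is taken over called genotypes only; `max_missing` is the minimum
fraction of called genotypes (vcftools convention, 1.0 = no missing);
thinning keeps a greedy left-to-right per-chromosome set with successive
retained positions ≥ `thin_bp` apart (the named tool's semantics).  Sites
with a missing QUAL field fail the quality rule whenever `qual_min` > 0.
Alignment export drops columns called in fewer than `min_samples_locus`
samples (default 10) and encodes heterozygotes as IUPAC ambiguity codes;
a majority-allele resolution mode is provided because converter defaults
differ between studies.

## Bayes-factor delimitation ranking

Marginal likelihoods of sample→species partitions are *inputs*: estimating
them requires a full coalescent MCMC plus path sampling, machinery with
undisclosed settings and cluster-scale cost that is deliberately out of
scope.  Given the estimates, BF = 2·(log mL_ref − log mL_alt), models are
ranked by marginal likelihood descending (ties broken by id), and evidence
categories follow the conventional bands: |BF| < 2 negligible, 2–6
positive, 6–10 strong (interpolated between the two bands the source
framework states explicitly), > 10 decisive.  The packaged six-model
*Montipora* fixture carries the published groupings and MLEs; its
sample-level roster is a reconstruction of the stated study design and is
labelled synthetic in the fixture file.

## Distances

Uncorrected p-distances use pairwise deletion (sites where either taxon is
missing/ambiguous are skipped per pair), the common default of classical
distance software and the choice that maximises usable sites; a
complete-deletion analysis can be obtained by pre-filtering columns.  The
net between-group distance is d_between − (d_within,A + d_within,B)/2.
Bootstrap standard errors resample alignment columns with replacement
(default 500 replicates) and use the population (n) denominator; a
singleton group has an undefined within-distance, and any net distance
involving it is reported as undefined rather than silently zero.

## Composition homogeneity

The tree-aware posterior-predictive composition tests used by nonstationary
Bayesian software require an MCMC engine; this module implements the
classical screening analogue: a taxa × {A,C,G,T} table of unambiguous
counts and a Pearson χ² against pooled expected frequencies, df =
(n_taxa − 1) × 3.  With pooled expectations a zero-expected cell can only
occur for a base absent from every taxon; such structural-zero columns
contribute nothing to χ² and are recorded in the result rather than
altering df.  An optional parametric null redraws each taxon's counts from
a multinomial with the pooled frequencies and the same row total and
reports the tail fraction of resampled χ² values; it converges to the
analytic p for large counts (checked within Monte-Carlo error).

## The synthetic-data generator

The generator emulates exactly the dichotomy the D test exploits, using
site-wise sampling from a finite outcome space rather than a sequential
coalescent, so its distribution has a closed form:

1. with probability γ the recipient lineage is re-parented into the donor's
   population, making donor and recipient sisters in the effective quartet
   tree for that site;
2. the sister pair coalesces inside the internal branch (length T,
   coalescent units) with probability 1 − e^(−T); otherwise coalescence is
   deep and the three ingroup pairings are equiprobable;
3. a single mutation (infinite-sites) falls on one of the six branches of
   the realised rooted genealogy, uniformly per branch by default.  An
   optional branch-length weighting uses schematic expected coalescence
   times (species splits at depths 1, 1+T, 2+T; exponential waiting-time
   means within each interval); it changes the pattern mix quantitatively
   but not the ABBA/BABA symmetry properties.

`pattern_probabilities` enumerates admixture state × coalescence category ×
mutation branch and returns the exact site-pattern distribution, so every
stochastic test compares the simulator against an oracle rather than
another simulation.  Genotypes are diploid and homozygous for the lineage
allele (one sample per lineage by default, matching single-sample study
designs; `samples_per_lineage` replicates lineages to exercise
coverage-based filters), then perturbed: heterozygote injection at
`het_rate` (exercising strict-mode exclusions) and masking at
`missing_rate`.  Defaults are chosen once as a realistic RADseq-like
regime: 10 000 sites, T = 1 coalescent unit (substantial but not extreme
ILS: discordant genealogies at rate e^(−1)/3 ≈ 0.12 each), het and missing
rates of 0.05, site QUAL uniform on [30, 90].

What the generator does *not* emulate: linkage and recombination structure,
demographic size changes, allele-frequency spectra within populations,
sequencing-error models beyond the het/missing injection, and
reference-mapping artefacts.  Passing calibration tests therefore shows the
statistical machinery is correct under independent sites, not that real
RADseq data meet those assumptions — with linked loci the block-jackknife
option is the appropriate significance route.

## Calibration results the tests compute

With γ = 0 the α = 0.01 rejection rate over 500 seeded replicates of
10 000 sites lies within the binomial 99% bounds of 0.01; with γ = 0.5
(donor P1 → recipient P3) power exceeds 0.95 and every significant call has
D < 0; empirical site-pattern frequencies match the enumeration within
3 Monte-Carlo standard errors.  An independent cross-check runs an msprime
coalescent model with a P3→P1 mass-migration pulse and confirms the sign
convention of D on data the package did not generate.  Replicate counts and
site numbers are those listed here and in `scripts/acceptance.py`.

## Numerical and interface choices

- Genotypes are int8 codes (0 hom-ref, 1 het, 2 hom-alt, −1 missing);
  half-calls normalise to missing before state mapping.
- All randomness flows from explicit integer seeds via numpy Generators;
  identical seed and configuration give byte-identical pipeline outputs,
  which the provenance header (version, seed, config hash) makes auditable.
- p-value display: three decimals, switching to two-significant-digit
  scientific notation below 10⁻³; D displayed at three decimals.  Full
  precision is always available programmatically.
- The pipeline validates its configuration (paths exist, α ∈ (0,1)) before
  running any stage and aborts with the failing stage named.

## Known limitations

- The D test here is the four-taxon statistic; five-taxon partitioned
  statistics and admixture-fraction estimators are out of scope.
- Marginal likelihoods are consumed, never estimated.
- The composition test is tree-free; lineage-correlated composition drift
  will inflate its χ² relative to a tree-aware test.
- Distance values printed in SNP-based studies depend on the underlying
  read data and filtering; they are not desk-reproducible and are not
  asserted by the test suite.
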