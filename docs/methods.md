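# Methods

This note records the statistical conventions, default parameters and design
choices behind `selfpath`, and what the synthetic-data tests do and do not
demonstrate.

## Data model

Genotypes are biallelic SNP calls in the Illumina AB convention (A/T → allele
"A", G/C → allele "B"), stored as allele-B dosage (0/1/2, −1 missing). All
homozygosity statistics are per-individual: the genotypic counts
(n_AA, n_AB, n_BB) over that individual's *own* non-missing calls, with
observed homozygosity (n_AA + n_BB)/(n_AA + n_AB + n_BB). Using each
individual's own genotyped total as denominator (rather than the panel size)
is deliberate: genotyped totals differ slightly between samples and the
per-individual denominator keeps homozygosities comparable.

## Quality control

Filtering order is fixed and matters:

1. drop samples with call rate < 0.87 (computed over all markers present
   before any marker filtering);
2. drop markers with call frequency < 0.95 over retained samples;
3. drop markers with MAF < 0.01 computed on retained samples.

MAF is defined on the post-sample-filter cohort, so the filter is idempotent.
The cohort used for MAF is a parameter (`sample_subset` of the relevant
functions): panels ascertained on a germplasm collection may legitimately
compute MAF on the clone subset rather than on clones plus inbreds.
Missing-call tokens `--`, `NC` and the empty string are accepted on input;
`--` is always written.

## The selfing expectation and per-offspring test

From parent counts, the one-generation expectation is
(n_AA + n_AB/4, n_AB/2, n_BB + n_AB/4). Two conventions deserve note:

- **No rescaling by default.** Offspring are typically genotyped at slightly
  different totals than the parent; the Pearson χ² (df = 2, fully specified
  null) is computed against the parent-scale expectation. A
  `rescale_expected` option rescales the expectation to the offspring total
  (e.g. χ² = 126.44 instead of 126.36 for one reference offspring); it is
  statistically preferable when totals differ by more than a few percent,
  and off by default for continuity with the unscaled convention of the
  bundled benchmark.
- **df = 2**: three genotype classes, no estimated parameter (the null is
  fully determined by the parent's counts). The test's size is verified by
  simulation: multinomial offspring drawn from the expectation reject at
  0.05 ± 0.01 (10,000 replicates).

Direction of deviation is defined on the homozygous *fraction* (observed vs
expected), matching how a breeder reads the result. An expected class of
zero with non-zero observations is reported as an infinite deviation rather
than a numeric χ².

## Family summaries

Per family (the members of its most advanced genotyped generation, sharing
one selfed parent):

- μ, σ, min, max of per-offspring homozygosity at **full precision** from
  counts — not from rounded values. σ uses the n−1 denominator. (Rounding
  first distorts z: e.g. −1.93 instead of −1.879 for one benchmark
  offspring.)
- standardized homozygosity z = (h − μ)/σ; undefined (flagged) when all
  offspring are equal. Selection order is z descending with ties broken by
  individual id, so reports are deterministic.
- expected family homozygosity = h_parent + (1 − h_parent)/2.
- RMSD between observed homozygosities and that prediction uses the **n**
  denominator (a population-style RMSD, consistent with the bundled
  benchmark values).
- the family *t* statistic is a one-sample two-sided t of per-offspring
  (observed − expected) homozygous-call counts against zero. On the bundled
  dataset its two-sided p-values are 0.489, 0.335, 0.373, 0.027, 0.342,
  0.572 for families A–F; we report both t and p. If every offspring sits
  exactly at expectation, t = 0 and p = 1 by convention.

### Surrogate parents

When a family's selfed parent was never genotyped, its counts are replaced by
the class-wise mean of its genotyped full siblings (who share the same
Mendelian expectation). A `parent_override` lets the analyst designate a
single named sibling instead; the bundled cacao benchmark uses this for
family C (`CACAO_FAMILY_C_PARENT_RULE`, sibling TSH-1188_S1_3), which is the
rule that reproduces the family's published per-offspring χ² values and
expected homozygosity. Under either rule the family's mean/σ/RMSD agree to
3 decimals.

## Parentage screening

A selfed offspring cannot carry an allele its parent lacks: parent AA with
offspring AB or BB (and symmetrically BB with AA/AB) is an opposing-genotype
incompatibility; a heterozygous parent is compatible with everything. Loci
missing in either member are excluded from numerator and denominator.
Defaults: exclusion when the incompatibility rate exceeds `max_rate = 0.02`
over at least `min_compared = 500` loci — 2 % tolerates roughly 1 % per-call
error striking either member, while unrelated pairs on a polymorphic panel
conflict at hundreds of loci; fewer comparable loci give "inconclusive".
Both thresholds are explicit parameters because the appropriate cutoff
depends on panel error rates.

## Cohort statistics

Per-marker MAF is folded to ≤ 0.5 and is invariant under A↔B relabeling. The
HWE test is a Pearson χ² with 1 df (one estimated allele frequency, three
classes), no continuity correction; markers with minimum expected class
count < 1 are flagged, monomorphic markers are not scored. The inbreeding
coefficient is F = 1 − H₀/Hₑ with per-marker H₀ and Hₑ = 2pq averaged over
polymorphic markers before the ratio ("ratio of means", default) or averaged
per locus (`per-locus-mean`); both are exposed because the two estimators
differ under sparse data. Recovery is validated on simulated cohorts: founder
F ∈ {0, 0.15, 0.3, 0.6} is recovered within ±0.02 (500 samples × 3,000
markers) and estimates are monotone in the simulated F.

## Distances, trees, F1 heterozygosity

The pairwise distance is the squared codominant genotypic distance (per
locus: 0 identical, 1 homozygote↔heterozygote, 4 opposite homozygotes —
i.e. the squared dosage difference). Loci missing in either member are
dropped per pair; because comparable-locus counts then differ between pairs,
a `normalize` option divides by that count (summed distances are the
default). The 4:1 weighting mirrors F1 value: an AA×BB mating yields a
heterozygous F1 with probability 1, a mating involving a heterozygote with
probability ½ — which is exactly the `expected_f1_heterozygosity` score, so
for fully homozygous parents distance/4 per locus equals the F1
heterozygosity.

UPGMA is implemented in-package with deterministic tie-breaking
(lexicographically smallest cluster pair at equal merge distance) and node
heights at half the merge distance, so Newick output is reproducible
byte-for-byte; its cophenetic distances are cross-checked against an
independent average-linkage implementation in the tests. Non-finite
distances are rejected.

## The synthetic generator

The generator emulates the study design the analysis targets:

- **Markers**: 3,380 independent biallelic loci by default. MAF is drawn
  from Beta(5, 2) scaled to [0, 0.5] (mean ≈ 0.36, left-skewed toward high
  MAF), emulating panels ascertained for informativeness; a uniform option
  exists for null calibration.
- **Founders**: genotypes from inbreeding-adjusted frequencies
  (q² + Fpq, 2pq(1−F), p² + Fpq). F may be negative down to the per-marker
  feasibility bound: real breeding clones are often *more* heterozygous than
  HWE predicts, and an F = 0 founder cannot have homozygosity below 0.5.
  Where a study's baseline is stated as a homozygous-call fraction, founders
  can instead be constructed with that exact fraction (`founder_h0`).
- **Selfing**: parental homozygous and missing calls are copied; AB loci
  segregate 1:2:1 independently (no linkage — consistent with the
  count-based model, and a documented limitation: real chromosomes make
  offspring homozygosities more variable than the independent-loci model
  predicts, so simulated σ values are a lower bound).
- **Noise**: per-call missingness then symmetric class-swap error at the
  configured rates (defaults 0; study-like settings are 0–5 % missing,
  0–1 % error). Allele-dropout-style asymmetric error is out of scope.
- **Determinism**: one integer seed; all streams derive from it via
  `SeedSequence` spawning; fixed seed gives byte-identical output.

`simulate_program` advances one selected individual per generation per
strategy (`max_z`: highest measured homozygosity — within a single family
the z-ranking and the homozygosity ranking coincide; `random`: uniform), and
records the trajectory. Benchmarked properties: the random-strategy mean
trajectory follows 1 − (1 − h₀)/2^g within Monte-Carlo error, and with
h₀ = 0.48, families of 30 and 3 generations (500 replicates) marker-assisted
advancement ends strictly higher than random (paired one-sided t, p < 0.01),
with selected S2 individuals reaching ≥ 0.86 homozygosity in a sizeable
fraction of replicates. These sizes keep the whole suite in tens of seconds
while leaving Monte-Carlo error well inside the asserted tolerances.

Passing tests on synthetic data show the estimators are correct *under the
generator's assumptions* (unlinked loci, symmetric error, single selfed
parent); they do not certify behavior under linkage, segregation distortion,
or selection against inbreeding — on real data those appear precisely as the
deviations the per-offspring χ² is designed to flag.

## Degenerate inputs and numerical notes

- All-missing samples: counts are returned, downstream statistics raise.
- σ = 0 families (identical offspring): z flagged undefined rather than ±∞;
  equality is tested on the values (`ptp == 0`), not on the floating-point σ.
- Monomorphic markers are excluded from F and HWE denominators; a cohort
  with no polymorphic marker is an error, not NaN.
- Bonferroni thresholds are computed (α/m), never truncated to fewer digits.
- Homozygosities feeding μ/σ/z/RMSD are never rounded before use; report
  files carry full precision, `summary()` rounds for display (3 d.p. for
  homozygosities and z, 2 d.p. for χ²).

## Known limitations

- Single-parent (selfing) pedigrees only; no outcrossed parentage inference.
- No linkage, haplotype or runs-of-homozygosity modeling.
- The χ² treats loci as exchangeable counts; correlated loci inflate the
  statistic's variance relative to the multinomial null.
- The forward simulator models selection on marker homozygosity only — no
  phenotypes, fitness or inbreeding-depression dynamics.
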