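# Methods

`codhoming` re-implements, as one tested pipeline, the chain of inference
that links microsatellite population structure in Atlantic cod (*Gadus
morhua*) to the migratory behaviour of archival-tagged individuals: diversity
statistics and a Hardy–Weinberg screening of the genotype data, Weir–Cockerham
F-statistics with permutation significance, Bayesian assignment of individuals
to pooled spawning references with Monte-Carlo exclusion, rule-based
classification of daily geolocation tracks into behavioural categories, and an
unconditional exact test of whether migration direction is independent of
genetic origin. A synthetic-data module generates inputs with the statistical
structure the analysis assumes, so the whole chain runs and is testable
without any external download.

## Genotype model and file formats

Genotypes are diploid, unphased microsatellite calls stored as positive
integer allele codes; code 0 is reserved for missing data and a call is either
fully present or fully missing — half-calls are rejected at parse time because
none of the estimators below defines them. The exchange format is Genepop
(title line, locus names, `pop`-delimited blocks, fixed-width 2- or 3-digit
codes). Population labels are recovered from the common prefix of the
individual identifiers in a block (the de-facto convention in circulating
Genepop files), falling back to the last identifier and then to `popK`; the
writer prefixes identifiers with the sample label so a write/read cycle is the
identity on labels and bit-exact on allele codes. Sample metadata (region,
stage, date, WGS84 coordinates, per-individual year-class) travels in a
sidecar CSV, since Genepop cannot carry it. Archival-tag data use one CSV with
`meta` rows (release/recapture date, position, region per fish) and `daily`
rows (date, longitude); daily series are date-sorted on read.

## Diversity and the per-allele HWE screen

Observed heterozygosity Ho is the proportion of heterozygous non-missing
genotypes; expected heterozygosity He is Nei's unbiased gene diversity
(2n/(2n−1))·(1−Σp²) with n the number of genotyped individuals at the locus
(FSTAT's convention); Na is the allele count. All three are averaged over the
loci of the requested panel; a locus with no data in a sample is dropped from
that sample's averages with a logged warning.

The data-quality screen tests each allele separately for departure from
Hardy–Weinberg proportions (as would arise from null alleles or allele
dropout): all other alleles at the locus are pooled, F_IS = 1 − Ho/He is
computed on the recoded biallelic data with He = 2p(1−p), and the statistic
n·F_IS² is referred to χ² with one degree of freedom. A configuration switch
(`hwe_stat: n_fis`) substitutes the literal n·F_IS form; since that quantity
can be negative (heterozygote excess), negative values are reported with
p = 1. The statistic is asymptotic: for rare alleles (a few expected
heterozygote counts) its null distribution is visibly discrete and the
p-values are not uniform; the calibration tests therefore sample common
alleles (n = 200, allele frequencies ~0.1–0.5), which is the regime in which
the screen is informative. No multiple-testing correction is applied — the
screen is advisory and its flags are warnings, not filters.

## F-statistics

Population differentiation uses the Weir–Cockerham (1984) estimator θ.
Per locus and allele the three variance components are computed from sample
sizes n_i, allele frequencies p_i and heterozygote frequencies h_i: a (among
populations), b (among individuals within populations), c (within
individuals), with the n_c correction for unequal sample sizes; missing data
enter only through per-locus gene counts. The multilocus estimate is the
ratio of sums Σa / Σ(a+b+c) over loci and alleles — never the mean of
per-locus ratios — and negative estimates are reported, not clamped. A locus
contributes nothing when fewer than two samples have data for it; θ is
undefined (an error) when every locus is monomorphic.

Significance is assessed by permuting whole multilocus individuals among
samples, preserving sample sizes, with p = (1 + #{θ* ≥ θ})/(reps + 1): one
coherent resampling scheme for all differentiation tests, and the +1
correction keeps the p-value valid at any replicate count. Temporal
(year-class) stability applies the same machinery to cohorts pooled within a
region, excluding cohorts below a minimum size (default 10) with a warning.

Pairwise θ matrices are embedded with classical (Torgerson) metric MDS:
negative cells — legitimate for θ, impossible for distances — are clamped to
zero before squaring; the double-centred matrix is eigendecomposed,
coordinates are the top-k eigenvectors scaled by √eigenvalue, negative
eigenvalues are truncated, and k is reduced with a warning when fewer
positive eigenvalues exist. Because a classical embedding is only defined up
to rotation and sign, tests compare inter-point distances, never raw
coordinates.

## Genetic assignment, leave-one-out, exclusion

Reference samples are pooled into regional references (here: "Kattegat" and
"North Sea/W Skagerrak") before assignment; pooling reduces the number of
candidate sources and increases reference sizes. The default scoring rule is
the Bayesian Dirichlet posterior-predictive (Rannala–Mountain-style): with
per-locus allele counts n_i, gene count n, k distinct alleles at the locus
counted once over the union of all pools plus the individuals to be assigned
(a common Dirichlet(1/k, …, 1/k) prior across pools), and α = n + 1,

    P(ii) = (n_i + 1/k)(n_i + 1 + 1/k) / (α(α+1))
    P(ij) = 2 (n_i + 1/k)(n_j + 1/k) / (α(α+1)),   i ≠ j

summed in log over the genotype's non-missing loci. The pseudo-count keeps
every likelihood finite, including alleles absent from a pool. A
frequency-based criterion (observed frequencies, pseudo-frequency 1/(2N+1)
for unobserved alleles) is available behind `criterion="frequency"` for
sensitivity analysis. Assignment is the arg-max over pools; exact ties are
broken toward the first configured pool (toward the own pool in
self-assignment) and logged — with continuous likelihoods ties occur only for
degenerate pools.

Self-assignment of reference individuals applies the leave-one-out rule: the
focal individual's two genes are removed from its own pool's counts, locus by
locus, before scoring, which provably lowers the own-pool likelihood and
removes the self-assignment bias.

The exclusion test asks whether a tagged individual is plausible under each
reference at all: its log-likelihood is ranked within the likelihoods of
`n_sim` genotypes (default 1000) simulated in HWE from the pool's posterior
allele frequencies (counts plus the 1/k prior mass, consistent with the
scoring model), at the individual's non-missing loci; exclusion_p =
(1 + #{simulated ≤ observed})/(n_sim + 1), a valid Monte-Carlo rank p-value,
uniform when the fish really originates from the pool. A fish whose best
exclusion_p falls below the threshold (default 0.01) is flagged with a
warning but retained. Per-fish random streams are derived from the root seed
and a stable hash of the fish id, so results do not depend on processing
order. A robustness check re-assigns all tagged fish after repeatedly
subsampling the largest reference down to the size of the smallest (default
10 replicates) and reports mean assignment proportions per behavioural group.

## Geolocation validation and behaviour classification

Daily longitude estimates from archival tags are noisy and contain spurious
single-day excursions. A running "valid longitude" starts at the release
longitude; a new location is committed only when three consecutive estimates
each depart more than one degree from the current valid longitude *and* agree
among themselves (each within one degree of their window mean); the committed
value is the window mean, dated at the window's first day. The
three-consecutive/one-degree trigger is the published rule; taking the window
mean and requiring mutual coherence are implementation choices that make the
committed location robust to a stray value inside the run.

Classification is deterministic and total. A fish is excluded when its time
at liberty is 30 days or less (strictly more than 30 required) or when
neither a recapture position nor any track exists. Otherwise: any validated
longitude — or the recapture longitude — west of 10°E classifies the fish as
migrating towards the North Sea (from its release region); failing that, a
fish released in the eastern Skagerrak but recaptured inside the Kattegat
box is a Skagerrak → Kattegat migrant; all remaining fish are nonmigratory in
their release region. The Skagerrak/Kattegat boundary has no standard
definition; the default puts the Kattegat at latitude < 57.75°N (Skagen's
parallel) and longitude ≥ 10°E, and both cuts are configurable. Spring-tagged
fish that did not span a spawning season carry a `spans_spawning=False` flag
rather than being dropped.

## The unconditional exact test

For the directionally migrating fish, the 2×2 table crosses genetic
assignment (rows) with migration direction (columns). The two direction
groups are taken as fixed-size binomial samples — they are defined by
observed behaviour, assignment is the response; the transposed convention is
available by flag. Boschloo's unconditional test uses Fisher's exact p as the
ordering statistic: p = sup over the common success probability π of
P(T ≤ T_obs | π), computed on a uniform grid of 1001 points in (0.001,
0.999) with golden-section refinement around the grid argmax (the supremum is
interior for non-degenerate tables). Ties in T are included with absolute
tolerance 1e-12. The default sidedness is one-sided in the philopatric
direction ("migrates toward the pool it is assigned to"); two-sided uses the
two-sided Fisher statistic. Boschloo's p never exceeds Fisher's p on the same
table, and on the published table (3,12;0,20) the one-sided test gives
p = 0.0310, matching the published P = 0.032 to the reporting precision.
Fisher's test itself (hypergeometric enumeration, both margins fixed) is kept
as the embedded statistic and as an independent oracle; degenerate margins
give p = 1 by convention.

## Synthetic data

The generator's defaults are the study conditions: two reference populations
at F_ST = 0.004 genotyped at 12 loci with 15 alleles each, reference sizes
435 (Kattegat) and 201 (North Sea/W Skagerrak), 2% missing calls, and 100
tagged fish with five behavioural patterns, 35% of them directional, released
60/40 between eastern Skagerrak and Kattegat, with a philopatry probability
φ = 0.9, daily-longitude noise of 0.2° and 5% isolated outliers.

Divergence follows the Balding–Nichols model: each population's allele
frequencies at a locus are Dirichlet with parameters p⁰·(1−F)/F around the
ancestral frequencies p⁰, so the expected Weir–Cockerham θ equals F — the
only divergence parameter the analysis uses, which is why this model was
preferred over a coalescent simulation. Ancestral frequencies default to the
classical broken-stick abundance sequence p_i = (1/K)·Σ_{j≥i} 1/j — uneven,
with the rarest allele holding ≈1/K² of the mass, so all K alleles are
actually observable in samples of the study's size (random stick-breaking
instead produces alleles at frequencies below 10⁻³ that would never be seen
and that bias any moment estimator of F_ST in small samples); a `uniform`
model (all frequencies 1/K) is available. Genotypes are drawn in HWE, calls
erased at the missing rate. Calibration: over 200 replicates at n = 200 per
population, the mean multilocus θ is 0.0040 ± 0.0001 at F = 0.004, 0.0198 ±
0.0002 at F = 0.02 and 0.0990 ± 0.0009 at F = 0.1.

Each tagged fish draws a genetic origin pool, a genotype from that pool's
frequencies, a release region and a behaviour: directional with probability
`p_migratory`, heading toward its origin region with probability φ and away
from it otherwise; a "migrant" whose destination equals its release region
ends up nonmigratory there. Alternatively, exact behaviour-group counts can
be fixed (e.g. 27/5/3/29/36) and origins drawn conditionally (home pool with
probability φ), which reproduces the published group structure
deterministically. Tracks are emitted directly as reconstructed daily
longitudes — the representation the classifier consumes — not as raw light
curves: directional fish drift linearly to a destination beyond the relevant
boundary, reaching it at 60% of the liberty period; Gaussian noise and
isolated single-day outliers (>1.5°, never three consecutive) are
superimposed. What the generator does *not* emulate: within-region spatial
structure, linkage between loci, genotyping error other than missingness,
latitude information, and real geolocation error structure (autocorrelated,
season-dependent). Passing tests on synthetic data therefore demonstrate the
correctness and calibration of the estimators and decision rules under the
model's assumptions, not the field accuracy of light-based geolocation.

All outputs are bit-reproducible from the root seed; per-fish streams are
keyed by fish id.

## Pipeline, problem sizes, defaults

The pipeline runs: load/simulate → HWE screen (warnings only) → diversity
table → pairwise θ + permutation p + MDS coordinates → pooling → LOO
self-assignment → exclusion → tagged-fish assignment → behaviour
classification → group summaries → contingency + Fisher + Boschloo →
subsampling robustness. The 8-locus panel is the default for structure
stages and the full 12-locus panel for assignment stages, mirroring the
study's two panels. Defaults: 199 permutation replicates, 1000 exclusion
simulations, Boschloo grid 1001. Stage tables are pure functions of
(inputs, config, seed) and byte-identical across re-runs; the JSON run
report echoes the configuration and collects every warning.

The statistical test suite uses scaled problem sizes chosen to keep each
property informative: θ calibration at 200 replicates per F value, HWE
uniformity at 1000 sampled loci, Boschloo type-I at 2000 simulated tables
per null π (exploiting that only 4×33 distinct tables exist at the study's
group sizes 3 and 32), end-to-end philopatry recovery at 100 seeds for
φ = 0.9 and 200 for φ = 0.5, and classifier recovery on a 500-fish cohort.

## Known limitations

* The per-allele HWE screen is asymptotic (see above); exact
  (Markov-chain) HWE tests are out of scope.
* Permutation significance replaces the exact G-test of the original
  software chain; the two agree in calibration but not numerically.
* The exclusion test simulates at the focal fish's non-missing loci, which
  makes its rank p-value exactly uniform under the pool's model; software
  that simulates full genotypes and compares incomplete observations is
  slightly conservative instead.
* MDS coordinates are reported up to rotation/reflection.
* Confidence intervals on regional mean pairwise θ are reported as
  mean ± 1.96·SD/√(number of pairs) — a reporting convention, not an
  estimator claim; bootstrap CIs over loci are not implemented.
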