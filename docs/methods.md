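# Methods

This note documents the models implemented in `strdnm`, the assumptions of
the synthetic-data generator, the numerical choices, and the limits of
what the test suite demonstrates.

## Catalog attributes

An STR catalog row is (chrom, start, end, motif), 0-based half-open, with
the reference repeat tract (RRT) length `end − start` in bp, capped at
140 bp (beyond typical short-read resolvability). Repeat purity is the
number of exact, in-frame motif copies observed scanning left to right in
steps of the motif length, divided by `floor(tract length / motif
length)` — the copies a perfectly pure tract would show. Partial trailing
copies count toward neither term; interruptions that shift the reading
frame therefore depress purity for the remainder of the tract, which is a
deterministic choice among several defensible counting schemes (the
definition only fixes the ratio, not the counting). A consequence worth
knowing: a tract whose length is not a motif multiple can still score
purity 1 if every complete frame matches.

Motif equivalence classes close a motif under circular shifts and reverse
complement (e.g. AAT ≡ ATA ≡ TAA ≡ ATT ≡ TAT ≡ TTA), with the
lexicographically smallest member as representative; classes are reported
for motif lengths 1–3, longer motifs pass through as singletons.

Expected heterozygosity is Nei's gene diversity with small-sample
correction, H = [n/(n−1)](1 − Σ p_i²) over the allele-frequency spectrum
at a marker (n = 2 × genotyped individuals).

## De novo calling

A marker-trio is *available* when all three members have GQ strictly
greater than the threshold (default 60). On available marker-trios the
caller tests the two transmission statements (see README); this is
provably equivalent to brute-force enumeration of all Mendelian
transmissions, which the suite verifies exhaustively on a small allele
universe.

The de novo allele is the child allele absent from the union of parental
alleles when exactly one such exists. If both are absent the event is
flagged ambiguous and the allele farther from the parental alleles is
chosen; if neither is absent (both child alleles confined to one parent)
the event is also ambiguous and the allele farther from the
non-contributing parent's pair is chosen. The progenitor is the parental
allele nearest the de novo allele (ties: smaller allele, flagged); the
step size is their difference in bp and, divided by the motif length, in
motif units. Because the true progenitor is unobservable, the
nearest-allele rule can understate but never overstate the step
magnitude; the zero-noise suite checks both that bound and exactness
whenever the rule picks the true progenitor.

Homozygous call pairs (child homozygous for the de novo allele) closer
than 1 Mbp on one chromosome are removed in both directions, as such
clusters indicate an autozygous (effectively haploid) region rather than
two mutations; distance is between marker start coordinates. Parental
read support of the de novo allele is classified `none` / `low` (< 5% of
reads and ≤ 2 reads in each parent) / `high`; `high` marks candidate
parental allelic dropout. The filter order is fixed: eligibility →
detection → autozygosity → support flags, and output is invariant to
input row order.

## Phasing

Three methods, consolidated conservatively:

* **reads** — haplotype-labelled reads supporting the de novo allele; all
  supporting reads must agree;
* **allele sharing** — applicable when the de novo allele is in neither
  parent; if the child's other allele is carried by exactly one parent,
  the de novo came from the other parent;
* **three-generation** — a de novo transmitted to a grandchild lies on
  the haplotype the proband passed on, hence on the side of the
  grandparent of origin of that haplotype; a non-transmitted de novo lies
  on the opposite haplotype. All informative grandchildren must agree.

Consensus is the unique parent among non-unknown method calls; any
conflict yields `unknown`. No majority vote is attempted — the age model
downstream handles unphased events natively, so `unknown` costs
information but never injects error.

## Rates

r_i = D_i/T_i per motif length (D_i calls, T_i = Σ_t available markers of
length i), overall rate ΣD/ΣT. Confidence intervals: percentile bootstrap
resampling *microsatellites* (one row per marker with its tested-trio and
call counts), B = 100 by default, 2.5/97.5 percentiles; the point
estimate is always reported alongside, and a single-marker input
degenerates to it with a warning. Genome-wide extrapolation is
E = Σ r_i n_i with an option to exclude homopolymers (motif length 1),
whose genotyping error rate is highest. Annotation overrepresentation is
the density odds ratio (calls/bp inside) / (calls/bp outside) over merged
half-open intervals, infinite when no call falls outside. The attribute
regression is a Poisson log-linear GLM (statsmodels) of per-marker call
counts on motif length, RRT length, motif GC and purity with
log(tested trios) offset. Step-size summaries report per-parent,
per-motif-length mean |steps| with a two-sided Mann–Whitney rank-sum
comparison, and signed-step means with expansion fractions by RRT bin.

## The latent-phase Poisson age model

Per trio: y_P paternally phased, y_M maternally phased, y_U unphased
events; ages at conception A_P, A_M; availability m_t. Identity-link
means μ_P,t = (α_P + β_P A_P,t)·e_t with exposure e_t = m_t/M̄
(switchable off), maternal analogous. The log-likelihood accumulates, in
log space,

    log Σ_{y*_P=y_P}^{y_P+y_U} f(y_T − y*_P; μ_M,t) f(y*_P; μ_P,t)

with f the Poisson pmf and no combinatorial weighting of the allocations.
A binomially weighted variant (weight C(y_U, y*_P − y_P)) is available
behind a flag for comparison; it is an extension, not the default.

**What the unweighted sum is the likelihood of.** If phase information is
lost *per trio* — with some probability all of a trio's events are
phased, otherwise none — the unweighted sum is exactly the likelihood up
to parameter-free factors, the MLE is consistent, and Wald intervals
attain nominal coverage (the suite verifies ≥90/100 coverage at 2000
trios). If instead each event is unphased *independently*, the correct
likelihood factorizes into three independent Poissons involving the
phasing probability, and the unweighted sum is an interval-censored
pseudo-likelihood whose intercept estimates are noticeably biased (the
maternal intercept drifts up, the paternal slope slightly down). The
count-level generator therefore offers both mechanisms
(`phasing_mode="trio"`, the exact mirror and default, and `"event"`),
while the marker-level simulator is mechanistically per-event, like real
phasing pipelines. Slope estimates remain usable under per-event
unphasing but should be read as approximate; this is a property of the
model itself, not of the optimizer.

Fitting: multi-start (intercepts at {0.5, 1, 2}× the unphased-inflated
phased-count means; slopes at 0 and a crude least-squares slope),
L-BFGS-B with the analytic gradient and a smooth penalty pushing back
from the positivity boundary (μ > 0 for every trio must hold — the
identity link does not guarantee it), followed by a Nelder–Mead polish of
the best candidate. Invalid parameter regions raise a dedicated
`InvalidMeanError` when the likelihood is evaluated directly,
distinguishing domain failure from underflow (which log-space
accumulation avoids). Covariance is the inverse negative numerical
Hessian (central differences of the analytic gradient); Wald 95% CIs
follow. With y_U ≡ 0 and equal availability the fit provably reduces to
two independent identity-link Poisson regressions, checked against
statsmodels to 1e-8 relative log-likelihood.

Each slope's significance is a likelihood-ratio test against the nested
model with that slope fixed at 0, χ² with 1 df; the nested optimum is
re-used as a starting point for a full-model refit so the statistic
cannot go negative beyond optimizer tolerance. Under the null the LRT
p-values are uniform (KS-checked over 500 replicates of 300 trios).

Genome-wide conversion multiplies a per-M̄ coefficient by M_total/M̄
(M_total defaults to 1,394,292, the microsatellite census the defaults
emulate); the predicted genome-wide count for parent ages (X, Y) is
(I_F + β_F X + I_M + β_M Y)/(M̄/M_total). Note this scaling is only
meaningful when M̄ is on the real-cohort availability scale; on a
scaled-down simulated catalog the factor is arbitrary.

## Phenotypes

Per parent-offspring pair the attributed count (consensus-phased by
default; optionally plus a proportional share of unphased events) is
residualized by OLS on parental age, parental sex, sequencing method,
sample type and m_t (categoricals dummy-coded; aliased columns absorbed
with a warning); residuals are averaged over each parent's offspring and
rank-inverse-normal transformed with the Blom offset,
Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks for ties. Residualize → average →
transform keeps offspring-specific covariates usable; the alternative
order (aggregate first) is available by composing the primitives. The
transform is invariant under strictly monotone input transformations.

The enrichment test prunes one random member of each variant pair with
r² > 0.9 (seeded), counts per gene the variants with association p < 0.05
among N remaining, and applies a one-sided binomial test at rate 0.05
with Bonferroni correction over genes. For small N the test is
conservative (discreteness), visible in the null simulation.

## The synthetic cohort

The generator's defaults are the emulated study conditions; they are not
tuned per test.

* **Catalog**: motif-length mix (62.9/14.8/4.7/10.5/4.7/2.4% for lengths
  1–6) matching the high-quality set composition; RRT lengths
  exponential above per-length minima, truncated at 140 bp; purity
  1 − Beta(1, 10) (mean ≈ 0.91); primitive random motifs; markers
  scattered over 22 chromosomes.
* **Mutation placement**: per-marker weights ∝ exp(c_motif + 0.03·RRT +
  2·purity) with c_motif giving the observed rate ordering
  (dinucleotide highest, hexanucleotide lowest).
* **Counts**: per-trio paternal events Poisson((4.43 + 0.178·A_P)·m_t/M̄),
  maternal Poisson((1.31 + 0.058·A_M)·m_t/M̄). Intercepts were derived
  from the emulated cohort's mean of 12.7 events/trio and 76.9% paternal
  share at mean parental ages 30/28 together with the published slopes;
  the cohort's own printed age predictions imply intercepts ~10% lower —
  the published summaries are not mutually consistent at that level, and
  the means+slopes derivation was preferred. Ages are truncated normal
  (fathers 30 ± 5, mothers 28 ± 5, range 18–55; the source cohort's age
  distribution is unpublished).
* **Steps**: |step| ~ Geometric in motif units (paternal p = 0.76,
  maternal p = 0.61, matching mean motifs-affected 1.32/1.64); expansion
  probability a declining logistic in RRT length (pivot 60 bp), giving
  expansion bias at short tracts and contraction bias at long ones.
* **Availability**: per-trio availability probability Beta-distributed
  with mean 0.404 (the dispersion is a modelling choice — only the mean
  is published); an unavailable marker-trio fails via one random member's
  GQ. Mutations are placed at markers *available* to the trio, at
  *distinct* markers within a trio, and a step that would yield a
  Mendelian-consistent genotype is resampled: the generative model is for
  detectable counts (mirroring the m_t/M̄ exposure of the age model), and
  at genome scale two events at one marker-trio or undetectable
  collisions are vanishingly rare, so excluding them keeps scaled-down
  cohorts exactly recoverable under zero noise.
* **Phasing evidence**: 40% of events carry haplotype-labelled supporting
  reads; allele-sharing phasability emerges from the simulated parental
  genotypes; the first `n_threegen_families` trios have grandchildren
  with recorded haplotype inheritance. At the default cohort composition
  the union lands near the emulated 60% phased share (the read fraction
  was calibrated once against the simulator for that target).
* **Noise**: per-allele slippage errors (±1 motif) largest at
  homopolymers (2e-5) and small elsewhere; error-affected genotypes drop
  below the GQ threshold with probability 0.7 (enriched, not perfectly
  filtered); parental allelic dropout at 5e-6 per parent per available
  marker-trio suppresses one parental allele from the genotype while
  leaving a reduced read trace — the resulting spurious calls carry
  `high` parental support, which is how dropout is flagged in practice.

What the simulator does **not** emulate: read-level sequences, reference
context, linkage disequilibrium between markers, population structure,
imputation-based filters (Hardy–Weinberg, info score), somatic mosaicism,
or locus-specific mutational idiosyncrasies. Passing tests demonstrate
the pipeline's internal correctness and the statistical calibration of
the estimators under the assumed generative structure — not robustness to
real-data artefacts outside that structure.

## Problem sizes

The suite runs scaled-down cohorts chosen to exercise every path with
stable statistics: 400 markers × 80–100 trios for end-to-end fixtures;
100 replicate cohorts of 2000 trios for Wald coverage; 500 replicates of
300 trios for the LRT null; 200 outer replicates of a 300-marker table
for bootstrap coverage. The acceptance script uses 800 markers × 500
trios for the marker-level pipeline and 6084 trios at the count level for
the age-model fit. Per-microsatellite rates from scaled-down catalogs are
intentionally inflated (the same per-trio event count is spread over
fewer markers); rate *formulas* are validated on the published cohort
counts instead.

## Known limitations

* The unweighted latent-sum fit is approximate under event-level
  unphasing (see above); intercept-sensitive outputs (predictions)
  inherit that approximation.
* Ambiguous calls (~1% at default diversity) have unidentifiable de novo
  allele labels; they are flagged rather than dropped.
* The nearest-allele progenitor rule can understate step sizes when the
  true progenitor is not the closest parental allele.
* Bootstrap percentile intervals at B = 100 undercover slightly; B is
  configurable upward.
* The autozygosity filter uses marker start distance and removes both
  members of a close homozygous pair; isolated autozygous calls are not
  detectable from call data alone.
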