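# strdnm

Microsatellite de novo mutation (mDNM) analysis for parent-offspring trio
cohorts: detection, parent-of-origin phasing, mutation-rate estimation and
parental age-effect modelling, together with a synthetic cohort simulator
that makes every stage testable without access-controlled data.

## The problem

Short tandem repeats (STRs, 1–6 bp motifs) mutate orders of magnitude
faster than unique sequence, mostly by slippage that adds or removes whole
motif units. In a trio, an mDNM shows up as an offspring allele pair that
cannot be explained by transmission of one allele from each parent: with
proband alleles (A1, A2) and parental pairs M, F, the genotype is
consistent iff

    (A1 ∈ M and A2 ∈ F)  or  (A1 ∈ F and A2 ∈ M)

and a de novo call is made when neither holds (alleles are repeat-tract
lengths in bp; membership is exact match). Calls are restricted to
marker-trios where all three genotype qualities exceed a phred threshold
(GQ > 60), filtered for autozygosity (pairs of homozygous calls < 1 Mbp
apart), and flagged by parental read support of the de novo allele to
account for allelic dropout.

Each call is assigned a parent of origin by three independent methods —
haplotype-labelled reads, allele sharing, and transmission to grandchildren
in three-generation families — with conflicts resolved conservatively to
`unknown`.

The per-motif-length mutation rate is r_i = D_i / T_i (mutations per
microsatellite per generation), with a percentile bootstrap over markers
for confidence intervals, and the genome-wide expectation per offspring is

    E[mDNMs] = Σ_i r_i · n_i

over the motif-length census n_i. Parental age effects are fitted by
maximising a latent-phase Poisson likelihood that sums over all
allocations of unphased events between the parents:

    L_t = Σ_{y*_P = y_P}^{y_P+y_U}  f(y_T − y*_P; μ_M,t) · f(y*_P; μ_P,t)

with identity-link means μ_P,t = (α_P + β_P·A_P,t)·m_t/M̄ (and maternal
analogue), where m_t is the trio's available-marker count. Slopes are
interpolated genome-wide by M_total/M̄. Per-parent transmitted-mDNM
phenotypes (covariate residualisation → per-parent averaging → rank
inverse-normal transform) are produced for downstream association testing.

## Worked example

```bash
strdnm simulate --seed 1 --n-markers 400 --n-trios 200 --out-dir sim
strdnm detect --genotypes sim/genotypes.tsv --pedigree sim/pedigree.fam \
              --catalog sim/catalog_attributes.tsv --out-dir det
strdnm phase  --calls det/mdnm_calls.tsv --read-evidence sim/read_evidence.tsv \
              --threegen-evidence sim/threegen_evidence.tsv \
              --trios sim/trios.tsv --out-dir ph
strdnm agefit --counts ph/age_input.tsv --out-dir fit
```

The simulator defaults reproduce the study conditions of a large Icelandic
trio cohort (≈12.7 detectable mDNMs per trio, ≈77% paternal, paternal age
slope 0.178 and maternal 0.058 events/year on the mean-availability
scale, ≈60% of events phasable at the default cohort composition). On the
run above the phasing log reports `phased_fraction=0.740` — higher than
the full-cohort 60% because the 100 three-generation families are a much
larger share of a 200-trio cohort — and `fit/agefit_report.json` contains

```json
"params": {"alpha_p": 4.457, "beta_p": 0.170, "alpha_m": 2.480, "beta_m": 0.027}
```

with a paternal-slope likelihood-ratio p-value of 2.8e-4: the paternal
age effect (true value 0.178) is recovered and clearly detected even at
200 trios, while the weaker maternal slope (true 0.058) is not
significant at this size (p = 0.41) — detecting it needs cohort-scale
data, and the maternal intercept drifts upward because event-level
unphasing makes the latent-sum fit approximate (see
`docs/methods.md`). The same workflow in Python:

```python
import numpy as np, strdnm
cfg = strdnm.SimConfig(n_markers=400, n_trios=200)
rng = np.random.default_rng(1)
cat = strdnm.generate_catalog(cfg, rng)
sim = strdnm.simulate_pedigrees(cat, cfg, rng)
observed = strdnm.inject_errors(sim, cfg, rng)
res = strdnm.call_mdnms(observed, sim.pedigree, cat)
phased, concordance = strdnm.phase_calls(res["calls"], sim.read_evidence,
                                         sim.threegen_evidence)
```

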