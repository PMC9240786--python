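# Methods

`breedsim` simulates a generic cereal (barley-like) genomic-selection
breeding programme in which favourable alleles at a handful of large
disease-resistance QTL exist only in an external germplasm source and are
introgressed into an elite breeding population, while selection continues
on a polygenic disease trait and on grain yield in two environments.  This
note records the model, the parameter choices, and the places where the
design was genuinely open.

## Genetic model

Two traits — disease resistance and grain yield — are controlled by
additive biallelic QTL, simulated in two environments.  QTL sets for a
trait overlap between environments at rate *q* = 0.7 and not at all between
traits (*p* = 0).  With *N* QTL per trait per environment, the number of
environment-unique QTL per trait solves s + u = N with shared fraction
s/(s + 2u) = q, giving u = round(N(1 − q)/(1 + q)); at N = 1,001 this is
177 unique per environment plus 824 shared, 1,178 distinct QTL per trait
and 2,356 overall.

Effects for the four (trait, environment) columns are drawn by sampling a
standard-normal matrix u₀ and multiplying by the Cholesky factor L of the
effect covariance w (between-environment genetic correlation 0.8 for
disease, 0.4 for yield, zero across traits), v = u₀L, then masking with the
0/1 design matrix of trait-environment memberships (a = X ∘ v).  The ten
disease QTL with the largest mean absolute effect across their active
environments are designated *major*; the favourable allele at every QTL is
the one that raises the trait's merit.

### Major-QTL rescaling

Major effects are multiplied by a constant c such that the majors carry 10%
of the disease *genic* variance — the linkage-equilibrium decomposition
Σⱼ Var(dosageⱼ)·aⱼ², summed per locus — in a reference pool of 400 parent
lines containing 20% external lines.  All disease effects are then
standardised to unit SD over their active entries.  Genic variance, rather
than the variance of the realized major/minor TBV components, is the right
quantity here: in the mixed reference pool, population origin induces a
strong negative covariance between the major and minor components (external
lines carry the majors but slightly weaker polygenic backgrounds), and a
whole-variance criterion would shrink the "majors" to minor-sized effects.
Under the genic criterion the emergent mean major effect at the full
29,069-locus, 2,356-QTL scale is ≈3.5 in minor-effect SD units, consistent
with a large-effect introgression target.  The effect-size scenarios
instead fix the mean major effect directly (`major_effect_size`, e.g. 3.21
vs 5.20).

## Founders

Founders are ~1,950 fully inbred lines (both haplotypes identical) on a
7-chromosome, 29,069-SNP panel (~655 Mb per chromosome), split into an
*existing* population (default 1,850 lines) and a smaller *external* pool
(default 100).  The external pool is deliberately small: when 20% of 400
parents (80 lines) are drawn from it by maximising major-allele counts, the
chosen lines' mean major frequency stays near the pool mean of 0.65, which
reproduces a parent-pool frequency of ≈0.13 after introgression; a large
pool would push the chosen lines well above 0.65.

Per-locus favourable-allele frequency targets by class:

| class | existing | external |
|---|---|---|
| major disease (10) | 0 (absent) | 0.65 |
| minor disease | U(mean ± 0.10), mean 0.85/0.52/0.27 by scenario | existing ∓ U(0.03, 0.19), lower with prob. 0.55 |
| yield | U(0.2, 0.8) | existing ∓ U(0.05, 0.13), lower with prob. 0.7 |
| neutral markers | U(0.05, 0.95) | U(0.05, 0.95), independent |

The between-population differences are given a random per-locus sign with a
tilt toward the external population being lower — slight for the minor
disease QTL (0.55) and stronger for yield (0.7).  Both populations descend
from elite material, so minor-disease differences should be mostly
unsystematic: a fully one-sided difference would make each external line
several genetic SD worse *coherently* across ~580 minor loci, far beyond
the mild post-introgression dip the model is meant to produce.  Yield gets
the stronger tilt because an introgression donor is typically chosen for
the target trait and systematically lags the elite programme in the
others — the classic linkage-drag setting.  The tilts, plus the ceiling
effect at high existing frequencies, reproduce the mild decline of
minor-disease and yield frequencies after introgression.  Founder loci are
sampled independently (no founder LD); linkage builds up through simulated
meiosis.

## Meiosis

Gametes recombine with a Poisson(λ = 1) number of crossovers per
chromosome, placed uniformly on the physical map with no interference,
starting from a random parental haplotype per chromosome.  Each locus then
mutates (allele flip) with probability μ per gamete.  The meiosis primitive
defaults to μ = 0.001; the programme configuration overrides this to
μ = 10⁻⁵.  At μ = 0.001 per locus per gamete, mutation injects major-QTL
favourable alleles de novo at a rate that selection amplifies to
frequencies above 0.1 within a few cycles even with *no* introgression,
erasing the contrast between scenarios with and without donors — the study
design requires majors to be absent from the existing population unless
introduced.  μ is configurable for sensitivity work.

## Phenotypes and prediction

TBV is g = Ma (favourable-allele dosage times effects).  Stage-1 phenotypes
add independent normal residuals with SD √((1 − h²)/h² · σ²ₐ), with
h² = 0.5 (disease) and 0.25 (yield) and σ²ₐ the realized TBV variance of
the phenotyped cohort per trait-environment, so realized heritability is on
target every cycle.  Earlier generations carry TBV only.

Marker effects are estimated by Bayesian ridge regression per
trait-environment column on the full SNP panel (QTL included).  The default
"fast" mode is the closed-form ridge posterior mean with plug-in variance
components derived from the configured h²; the shrinkage parameter
λ = Σ2pq·(1 − h²)/h² is phenotype-independent, so columns with equal h²
share one factorization.  A blocked Gibbs sampler (joint normal update of
the effect vector via a one-off eigendecomposition, scaled-inverse-χ²
updates of both variance components, 2,000 iterations / 500 burn-in by
default) is provided and agrees with the closed form when the variances are
frozen.  A line's per-trait score is the mean of its two environment GEBVs.

## Programme flow

Each of 8 cycles: 400 parents → 200 random disjoint primary crosses (each
parent once); the 150 crosses with the highest summed parental major-allele
counts spawn 90 top crosses (best ranks: F1 × the highest-index parent
outside the cross, which places major alleles into elite background) and 60
backcrosses (next ranks: F1 × the cross parent with more major alleles,
which doubles the donor contribution); 10 progeny per cross (3,500
F1-type plants), each selfed to 2 F2 (7,000); half the F2 selected; 10 F3
per selected F2 (35,000); single-seed descent to F5; 800 F5 selected
equally across the 350 families into Stage-1 trials (phenotyped in both
environments); the top 400 on the index become the next cycle's parents.

Cycles 1–3 are phenotypic: F2 and F5 selections are random (no phenotypes
or model exist at those stages) and parent selection uses the phenotype
index.  Genomic selection runs from cycle 4; F2 and F5 use the *lagged*
model (fitted through the previous cycle), parent ranking refits including
the current Stage-1 phenotypes.  The training window holds the last three
cycles' 400 selected parents.  Reported prediction accuracy always uses the
lagged model.  Introgression happens once, at the start of cycle 4:
⌈pct·400⌉ external lines with the most major alleles replace the
lowest-index parents; incoming lines rank below all retained parents (they
have no records), so they spread majors through their own primary crosses
and backcrosses rather than monopolising top crosses.

The selection index is I = w_D·u_D/σ_uD + w_Y·u_Y/σ_uY (+ k·N), standardised
by the candidate cohort's SDs; N is the candidate's favourable-allele count
over the 10 major QTL and k = 0.01 in the marker-assisted scenario (the kN
term then applies wherever the index is used in GS cycles).

Genetic gain per trait is the mean environment-averaged TBV of the newly
selected parents, centred and scaled by the initial 400 parents' TBV mean
and SD (fixed at the start of cycle 1).

## Desk-scale profiles and what they show

Full-scale runs (29,069 loci, 35,000 F3) are supported but slow; tests and
the shipped scenarios use structure-preserving profiles:

* `scaled_config` — 1/10 cohort sizes (40 parents, 700 F2, 3,500 F3, 80
  Stage-1) on a 1,500-locus panel with 501 QTL per trait-environment.
* `trend_config` — 2× `scaled_config` (80 parents), used for
  introgression-percentage comparisons so that 1% still resolves to a
  single external line.

The QTL count is scaled less aggressively than the cohorts because the
relative size of a major QTL under the 10% genic-variance criterion grows
with √(number of minor QTL); at ~100 QTL per trait-environment the "majors"
degenerate to minor-sized effects and the introgression mechanism the
programme probes disappears.  Scenario comparisons use common random
numbers: the replicate seed is independent of the scenario, so founders,
architecture and meiosis coincide across scenarios until the introgression
event diverges, which sharpens paired contrasts.

Passing desk-scale trend checks show that the *mechanisms* (donor-allele
amplification, linkage drag, diminishing returns with introgression
percentage) operate at desk scale; they do not reproduce the absolute gain
values obtained from the proprietary founder data, and small-cohort drift
makes desk-scale curves noisier than 50-replicate full-scale means.

## Numerical choices and degenerate inputs

Ties in truncation selection and major designation break by candidate/locus
index (stable sorts).  Family balancing gives every family ⌊n/k⌋ slots and
distributes the remainder one per family per round to the families whose
best unselected candidate scores highest; unfillable quotas are
redistributed the same way.  Frequency targets of exactly 0 or 1 produce
monomorphic loci; zero-variance phenotypes, monomorphic marker panels and
zero-SD index components raise errors rather than propagating NaNs.
Zero-effect QTL default to allele 1 as favourable.  The VCF writer emits
plain VCFv4.2 with homozygous GT calls; the reader (cyvcf2) rejects any
heterozygous founder record.

## Known limitations

No founder LD, no crossover interference, no dominance or epistasis, no
pleiotropy (the overlap machinery accepts only p = 0), one introgression
event, and no plot/block field-trial error structure.  G×E is limited to
the between-environment genetic correlation.  The external population's
internal structure (families, relatedness) is not modelled.
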