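# Methods

`recgain` simulates recurrent doubled-haploid (DH) selection programmes on a
sorghum-like genome to quantify how artificially increased recombination
rates (2-, 4-, 8-fold map rescaling) change genetic gain, variance dynamics
and genomic-prediction accuracy under phenotypic versus RRBLUP-based genomic
selection. This note records the model, its assumptions, the defaults and
why they were chosen, and what the synthetic data do and do not emulate.

## Genome and genetic map

The base genome has 10 chromosomes with genetic lengths (cM)
186.3, 226.5, 168.2, 169.4, 118.5, 165.2, 132.6, 131.7, 134.6, 112.1
(total 1545.1 cM) and, by default, 10,000 biallelic SNP loci per chromosome.

Loci are placed uniformly in *physical* position and translated to cM
through a crossover landscape: the cM coordinate is a mixture of a uniform
component (weight 0.03) and a U-shaped Beta(0.10, 0.10) CDF (weight 0.97)
concentrated at the chromosome ends. With these defaults ~82% of crossovers
fall in the most recombinogenic 25% of the physical genome, and the
pericentromeric half of the physical genome spans ~11% of the map — the
distal/pericentromeric contrast characteristic of cereal genomes. This
matters scientifically: QTL sampled uniformly among SNPs then cluster in
recombination-poor regions, creating the tight-linkage blocks whose
repulsion phase an increased recombination rate can resolve. With uniform
cM placement (`map_landscape=None`) neighbouring QTL are ~2 cM apart, almost
no variance is trapped by linkage, and map rescaling has little effect on
gain — a structurally different (and less realistic) regime.

An increased recombination rate is modelled exactly as a map rescale: every
cM position and length of the base map is multiplied by the factor. Because
a centimorgan *is* a unit of crossover probability, no separate crossover-
density model is needed; the landscape only decides where loci sit.

The map is drawn once per experiment from the base seed and shared by all
replicates (one genome, like a real reference map); QTL, marker panels,
effects and founders are re-sampled per replicate.

## Meiosis

Chiasmata on the four-strand bundle follow a stationary gamma renewal
process along the cM axis: inter-event distances are Gamma(shape = nu,
mean = 50 cM), giving two chiasmata per Morgan; the first event distance is
drawn from the equilibrium residual distribution (uniform fraction of a
length-biased Gamma(nu+1) interval), avoiding edge artefacts. Each chiasma
is transmitted to a gamete independently with probability 1/2 (no chromatid
interference). `nu = 2.6` by default — the conventional interference
strength of stochastic gene-dropping simulators for plant genomes — with
`nu = 1` recovering the no-interference (Poisson/Haldane) limit, which the
tests verify against a Poisson oracle. No obligate crossover is enforced by
default; `obligate_crossover=True` places one uniform crossover on
chromosomes where thinning retained none (sensitivity analyses only).

A crossover at position x switches strands for loci with position strictly
greater than x; a locus exactly at x is copied before the switch (half-open
convention, deterministic). Crossover positions are drawn in float32
(placement precision ~2e-4 cM, far below any locus spacing); gamete copying
is an integer kernel compiled with numba.

Populations track only the loci a scenario needs (QTL, plus chip markers
under genomic selection). This is exactly equivalent to simulating all
100,000 loci because crossovers are generated on the true chromosome
lengths and then applied to the tracked positions.

## Synthetic founders

The breeding programme starts from 3,000 fully homozygous founders. The
generator emulates, without external simulators, founders drawn from a
diversity panel:

1. An ancestral pool of 298 haplotypes (the size of the diversity panel the
   study landscape derives from) receives, at each locus, a derived-allele
   count k with P(k) proportional to 1/k — the neutral coalescent site-
   frequency spectrum — with random allele labelling (folded U-shape).
   `spectrum="beta"` substitutes the simpler Beta(0.2, 0.2)-frequency
   Bernoulli model. `maf_floor` (default 0.01) truncates the ancestral
   spectrum; loci fixed later by drift are retained — no MAF filtering
   anywhere.
2. The pool is paired into 298 diploids and randomly mated for 50
   generations using the meiosis engine, establishing linkage
   disequilibrium that decays with cM distance.
3. Each founder is a doubled haploid of a random individual from the mixed
   population (fully homozygous by construction).

What this emulates: cM-governed LD decay, a rare-allele-rich U-shaped
frequency spectrum, block-structured local haplotype diversity, full
homozygosity. What it does not: the deep coalescent fine structure of real
sorghum haplotypes, real SNP spatial clustering beyond the parametric
landscape, ascertainment bias of real SNP panels, or structural variation.
A cross-check replacing this generator with true coalescent founders
(outcrossing and selfing-adjusted effective recombination) left all headline
outcomes statistically indistinguishable, so the stand-in is not the
binding approximation for the quantities reported here; see "Known
limitations" for what is.

## Trait model

A single additive trait: 10, 100 (default) or 1,000 QTL per chromosome
sampled uniformly among loci; raw effects N(0,1) rescaled by one constant so
the founder genetic variance is exactly 1 (tolerance 1e-9); genetic value =
sum of effect × dosage (dosage in {0,1,2}). Environmental noise is i.i.d.
N(0, sigma_e^2) with sigma_e^2 = (1-h2)/h2 fixed once at founder calibration
(h2 in {0.2, 0.5 (default), 0.8} describes the founder population; realised
heritability then declines as genetic variance is depleted — intentional and
central to the dynamics). No dominance, epistasis, GxE, or mutation.

Variance bookkeeping per generation: *genetic* variance = realised variance
of genetic values (denominator n); *genic* variance = sum of 2 p (1-p) a^2
at current QTL frequencies (the Hardy-Weinberg/linkage-equilibrium
expectation). The Bulmer statistic is reported as genetic / (genic / 2).
Note that for fully inbred DH lines the linkage-equilibrium value of this
ratio is 4 (inbreeding doubles the additive variance), so values below 4
indicate selection-induced negative disequilibrium; the statistic is
reported as defined, not re-normalised.

## Breeding scheme

One cycle (all defaults as in the simulated programme): truncation-select
the top 30 of 3,000 DH lines, draw 60 crosses with uniformly random distinct
parent pairs from the 30 (pairs may repeat across crosses), self each F1
once to give a single F2 plant, and derive 50 DH lines from each F2 — 3,000
new DH lines. The single-F2 funnel is a deliberate 2-haplotype bottleneck
per cross.

A programme is initialised by 10 burn-in cycles of phenotypic selection at
the normal map (the founder selection counts as the first burn-in cycle).
Reporting conventions, applied at burn-in end: the genetic *gain* is the raw
mean genetic value on the founder sigma_A^2 = 1 scale, offset to zero; the
*variance* trajectories are divided by the burn-in-end genetic variance
(so cycle 0 has gain 0 and variance 1). The offset-only gain scale is the
internally consistent one: a first-cycle genomic-selection response of
i × r × sigma_g (≈ 2.665 × 0.82 × sigma) would exceed the entire 15-cycle
total if gains were expressed in burn-in-end standard deviations.

After burn-in the map may be rescaled and 15 further cycles run with either
phenotypic selection or genomic selection (RRBLUP trained on the current
3,000-DH generation, selecting on GEBV within that same generation).
Training happens at cycles 0, k, 2k, ... for training interval k (a model
must exist at cycle 0 to select at all); between trainings the most recent
model is reused verbatim. Prediction accuracy is recorded each generation
as the Pearson correlation between the GEBVs used for selection in that
generation and its true genetic values.

Two further experiments: *model maintenance* (train at burn-in end, select
on GEBV, rescale the map, run one cycle, reapply the stale model and record
the accuracy change) and *merged training* (a 3-generation rolling training
window spanning the recombination change, retrained every cycle, with a
factor-1 benchmark arm; phenotypes of merged generations are pooled raw,
without per-generation standardisation).

## RRBLUP

y = 1 mu + Z u + e with u ~ N(0, sigma_u^2 I), e ~ N(0, sigma_e^2 I), Z the
column-mean-centred dosage matrix. lambda = sigma_e^2 / sigma_u^2 is
estimated by REML: one spectral decomposition of Z Z^T makes the restricted
likelihood a cheap function of lambda (coarse log-grid over 16 orders of
magnitude, then bounded refinement); effects come from the mixed-model
equations at the optimum via a Cholesky solve, with the intercept profiled
out by GLS. Training is deterministic given the training set.

Numerical choices: the covariance build and factorisations run in float32
(REML arithmetic in float64); for training sets larger than 1,500 records,
lambda is REML-estimated on an evenly spaced row subsample of 1,500 (the
full system is still solved exactly at that lambda) — ridge solutions are
insensitive to the resulting lambda noise (fitted-value correlation > 0.999
against the full REML fit in tests). A non-finite REML criterion falls back
to the plug-in lambda = m (heritability 0.5) with a warning; a constant
response returns zero effects and the constant as intercept. A small
diagonal jitter (100 eps × trace) keeps the Cholesky positive definite when
the REML optimum sits at the zero-shrinkage boundary.

## Replication and seeding

A base seed spawns one `SeedSequence` child per replicate; within a
replicate, one stream drives founders and burn-in and one further stream per
treatment arm. All arms of an experiment therefore share founders and
burn-in replicate-by-replicate (seed pairing), which is what makes gain
ratios well-behaved; runs are bit-reproducible for a fixed seed. Gain
ratios divide replicate-mean cycle-15 gains (ratio of means; mean of paired
ratios is available as an option).

## Problem sizes for the shipped experiments

The preset drivers reproduce the headline experiments at sizes chosen for a
single CPU. Phenotypic-selection arms run the full programme (3,000 DH):
factors 1/4/8 seed-paired for 36 replicates, the 8-fold arm extended to 100
replicates for the across-replicate variance. First-cycle-accuracy arms run
the full programme for 24 replicates. The long-term genomic-selection and
training-cadence arms — whose per-cycle RRBLUP refit dominates cost — run at
half population (1,500 DH = 30 crosses × 50 DH, still selecting 30 parents)
for 7 replicates; halving the population raises the selection fraction from
1% to 2% (intensity 2.67 → 2.42), biasing those gains slightly downward.
The acceptance tests use the same drivers at 30/70, 24 and 7 replicates.

## Known limitations

- The recombination-factor response is compressed relative to large
  programmes built directly on a real genome: with this genome stand-in the
  phenotypic-selection gain ratios come out around 1.1-1.25 (4-/8-fold)
  rather than ~1.4-1.6, because less variance is trapped in tight repulsion
  at burn-in end and allele fixation races its release. The effect's
  direction, its mechanism (map-factor-proportional release of repulsion
  variance, verified on constructed repulsion populations), and the
  variance/accuracy phenomenology (variance crash under genomic selection,
  fixation by ~cycle 5, accuracy decay, replicate variance rising with the
  map factor) all reproduce; absolute factor contrasts should be read as
  conservative.
- Fixed sigma_e^2 means realised heritability falls over cycles; schemes
  that re-phenotype with controlled heritability would behave differently.
- Single trait, no new variation introduced mid-programme, no fertility or
  fitness cost of increased recombination, no hotspot re-positioning — the
  landscape is static and only the cM scale changes.
- The PLINK-MAP dialect cannot carry a chromosome length separate from the
  last locus position; the reader defines length = last position (exact for
  default maps, which pin the final locus to the chromosome end).
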