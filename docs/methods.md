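# Methods

## The experiment being modelled

A cultured cell population is sampled down to *B* = 200 founder cells and
expanded for *d* population doublings (the study design allows 13–17).
Both the pre-bottleneck ("early") and expanded ("late") populations are
deep-sequenced over a targeted region (~290 kb, mean depth ~1656×, range
~661–2856×), and somatic variants are read out as alternate/total read
counts per site.  Because the bottleneck is small, a variant's frequency
can change substantially with no selection at all; the package's central
object is the full null distribution of that change.

## Population model

**Bottleneck.** A variant at true early frequency *f*₀ contributes
*i* ~ Binomial(*B*, *f*₀) founder cells.

**Growth.** The founders expand to *N* = *B*·2^*d* cells by sequential
division events; at each event the dividing cell is chosen with
probability proportional to fitness, 1 for wild type and (1 + *s*) for
carriers.  This fitness-biased Pólya urn is exactly the embedded jump
chain of two independent Yule (pure-birth) processes with per-cell rates
1 and (1 + *s*), which is what "a Moran-type model modified for net
growth" means here: births without compensating deaths, overlapping
generations, fitness acting multiplicatively on division opportunity.

Assumptions: no cell death, no cell-cycle structure beyond exponential
waiting times, one allele copy per lineage (haploid bookkeeping — see
*Ploidy* below), a single bottleneck, and a fixed final size *N*.

**Analytic law of the final frequency.** For a Yule process started from
*i* cells, *M*(*t*)e^{−(1+s)t} → *X* ~ Gamma(*i*, 1) almost surely, and
similarly *W*(*t*)e^{−t} → *Y* ~ Gamma(*B*−*i*, 1) for the wild-type side.
Stopping growth when *M* + *W* = *N* gives

    X·u^{1+s} + Y·u = N,   f = X·u^{1+s}/N,   u = e^{T}.

Inverting the stopping relation at a frequency threshold *c* yields a
closed-form conditional CDF,

    P(f <= c | Y) = GammaCDF_i( c·(1−c)^{−(1+s)} · Y^{1+s} · N^{−s} ),

averaged over *Y* by 128-node Gauss–Legendre quadrature in probability
space (nodes mapped through the Gamma quantile function).  For *s* = 0
this collapses to the exact neutral law *f* ~ Beta(*i*, *B*−*i*),
independent of *d* — which is why the drift-null p-values are insensitive
to the number of doublings while the selection likelihoods are not.  The
*s* = 0 kernel is evaluated directly with the incomplete-beta functions
(`betainc`/`betaincc`); using the complementary function for upper-tail
bin masses keeps relative accuracy down to ~1e-300, which the extreme
drift-null p-values (1e-40 territory) require.  For *s* ≠ 0 the
quadrature resolves tail masses to order of magnitude, which is ample for
likelihood profiling.

For small populations (*N* ≤ 4096) the kernel is instead computed by an
exact event-by-event dynamic program over mutant counts; the Monte Carlo
simulator is the arbiter for both realisations (total-variation tests).

**Simulator.** `simulate_growth` draws division events exactly (one
Bernoulli per event, vectorised over replicates) up to 2^16 cells; any
remaining growth follows the deterministic branching flow obtained by
solving the stopping relation for the current (mutant, wild-type) pair.
Drift accumulated beyond 2^16 cells has standard deviation
≈ 0.25·(0.25·2^16)^{−1/2} ≈ 0.002 on the frequency scale — below one bin
of the default 512-bin grid — so the truncation is invisible to the
analytic-vs-simulated comparisons.  Frequencies are discretised on the
grid with true atoms at 0 and 1 (extinction and fixation), and mass below
one cell in the final population (1/*N*) is collapsed into the extinction
atom.

## Read model and inference chain

A read drawn at a site with true variant frequency *f* reports the
alternate base with probability q(f) = f·(1−ε) + (1−f)·ε/3: miscalls
occur at rate ε per base and scatter uniformly over the three non-reference
bases.  ε defaults to 1e-3, the error rate corresponding to the Q30
base-quality floor applied when counting reads.

The per-site chain is:

1. posterior over *f*₀ from the early counts — uniform prior over the
   frequency bins, binomial likelihood through q(·).  The uniform prior is
   the minimal-assumption choice that lets an observed zero count retain
   mass near (but not exactly at) zero;
2. Binomial(*B*, *f*₀) founder mixture;
3. growth kernel at the tested *s*;
4. Binomial(late_total, q(*f*)) read sampling.

The drift-null p-value is the tail probability of the late count under
this chain with *s* = 0, one-sided in the direction of the observed
frequency change, compared against a Bonferroni threshold whose
denominator is the target-region size in bp (2.9e5 by default), not the
number of discovered variants.  The selection estimate maximises the same
chain's log-likelihood over *s* ∈ [−1, 1] in steps of 0.05 (ties resolve
toward the smallest |*s*|); the 95% CI is the set of grid values with
2·ΔlogL ≤ 3.84 (χ², 1 df).  Likelihoods are floored at 1e-300.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `bottleneck_size` B | founder cells | 200 | the experiment plates 200 cells per well |
| `divisions` d | population doublings | 17 | within the stated 13–17; calibrated by validating the estimator against the published worked examples (below) |
| `seq_error` ε | per-base miscall rate | 1e-3 | Q30 base-quality floor |
| `grid_size` | frequency bins | 512 | bin width ~0.002, below the drift SD of all relevant founder counts |
| `diploid` | read freq = cell fraction / 2 | off | observed late frequency 55.3% exceeds the 50% ceiling of a strictly heterozygous-cell model; counts are allele counts |

**Calibrating d.** The drift-null p-values do not depend on *d* (the
neutral law is the Beta limit), so *d* only matters for *ŝ*.  Across the
admissible range the three published worked examples give:

| d | ŝ (CDKN2A) | ŝ (ERCC8) | ŝ (BRCA2) |
|---|---|---|---|
| 13 | 0.65 | 0.40 | 0.30 |
| 15 | 0.55 | 0.35 | 0.30 |
| 17 | **0.50** | **0.30** | **0.25** |

*d* = 17 reproduces all three published estimates simultaneously and is
the default; estimates at other *d* are one to three grid steps higher.
Users analysing experiments with a known doubling count should set *d*
accordingly (`ExperimentParams(divisions=...)`).

## Variant screen

The screen re-implements the two-step discovery rule for variants whose
frequency changes between passages, plus the published filters, directly
on pileup tables (it does not wrap an external caller, so it is testable
on synthetic pileups):

* **calling** — P(X ≥ alt_count) where X is the Poisson-binomial count of
  error reads with per-read probability 10^{−Q/10}/3 over all piled reads;
  exact truncated DP convolution, or a binomial tail when qualities are
  homogeneous.  The working threshold is p < 0.01/(number of screened
  sites), i.e. the 0.01 level with the Bonferroni correction quality-aware
  callers apply over tested positions.  At the study's mean depth
  (1656×, Q30) this makes the effective detection floor 9 alternate reads
  ≈ 0.54% frequency, matching the empirical observation that retained
  variants have ≥ 8 copies and frequency > 0.48%;
* **passage uniqueness** — a called allele is discarded if it is
  detectably present in the other passage (relaxed, uncorrected p < 0.01
  call).  Presence is deliberately *not* "≥ 1 read": at 1500× a single
  Q30 error read appears at ~40% of sites, which would veto a true
  late-arising clone almost half the time;
* **shared-site outliers** — alleles present in both passages pass
  through a 3-SD rule instead: flag sites whose |Δfrequency| exceeds
  mean + 3·SD across all shared variant sites (how a clone already
  present in the early passage, like the BRCA2 case, re-enters);
* **host-genotype gate** — the lower-frequency passage must be ≥ 98%
  reference (a pileup-level surrogate for "expected homozygous genotype";
  the published genotype-caller criterion has no pileup equivalent);
* **minimum count** — ≥ 3 alternate reads in the detected passage
  (empirically, false positives carry ≤ 2);
* **dinucleotide merge and neighbourhood filter** — adjacent candidate
  pairs merge into tandem events (CC>TT / GG>AA are the UV signature);
  candidates with more than one other candidate within ±50 bp are dropped.

## Detection-limit evaluation

Mixture controls are scored with the pileup presence rule used for such
controls (alternate count ≥ 1 at host-homozygous sites), not the screen's
corrected threshold.  With ε = 1e-3 at 2000×, sensitivity at dope
fractions 0.2–0.4% is high (~94–99%) but specificity is ~51%, because at
a Q30 error *floor* roughly half of all sites carry at least one error
read at that depth.  Real libraries, whose post-filter error rate is well
below the floor, show higher specificity; the synthetic evaluation is
deliberately conservative on this axis.

## Synthetic data

The generator emulates the study geometry end to end: log-normal depth
(σ_log = 0.25 around mean 1656×, spanning the reported 661–2856× range),
uniform-over-three-bases errors at ε, constant Q30 qualities, and planted
variants following the full chain (early frequency → bottleneck draw →
growth at their *s* → reads).  A planted variant may instead pin its true
late frequency directly, which screen-recovery tests use to control the
truth exactly.  All randomness flows from a single seed; output is
byte-identical across runs.

What it does **not** emulate: alignment and mapping artefacts, PCR
duplicates (removed upstream in the real pipeline), strand bias,
quality-score miscalibration, or error-rate variation along the genome.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated error model, not robustness to artefacts a
real aligner/caller stack would introduce.

## Statistical behaviour checked by the test suite

* drift-null p-values agree with a 1e5-replicate Monte Carlo of the full
  null chain on small geometries (within 3 MC standard errors);
* the analytic growth law is within total variation 0.02 of the
  event-level simulator (5e4 replicates, 16 equal-mass comparison bins —
  TV on the raw 512-bin grid would be dominated by per-bin sampling
  noise);
* neutral calibration: the fraction of 2,000 synthetic neutral sites
  (depth 1500×) with p < 0.05 stays within 3 binomial SEs of nominal —
  the test is conservative, never anti-conservative;
* parameter recovery: for 200 sites planted at *s* = 0.4 (early frequency
  0.5%, 2000×), the median *ŝ* is within ±0.1 of the truth and ≥ 90% of
  the 95% CIs cover it, scored on the sites whose clone survived the
  bottleneck — an extinct lineage (37% of Binomial(200, 0.005) draws)
  carries no information about its own fitness and would never reach the
  estimator in practice, since the screen only forwards variants seen in
  a passage;
* at target scale, 290 kb error-only experiments produce zero screen
  calls in ≥ 95 of 100 seeds, while planted clones reaching ≥ 0.5% and
  ≥ 8 alternate reads at the study's mean depth are recovered.

## Numerical choices and limitations

* The frequency grid is uniform; very low-frequency structure inside the
  first bins (below ~0.2%) is represented by the bin centre plus the
  extinction atom.  This is adequate for the depths modelled (≥ ~500×)
  but a log-spaced grid would serve ultra-deep data better.
* The branching-process kernel is an *N* → ∞ limit; its finite-size error
  at the default *N* = 200·2^17 is far below the grid resolution, and the
  exact DP takes over automatically for small *N*.
* Ties in the *s*-grid search resolve toward the smallest |*s*|
  (conservative with respect to claiming selection).
* p-values below ~1e-300 would underflow; the implementation floors
  probabilities at 1e-300 and reports the floor rather than zero.
* Joint inference across sites (linkage between variants in the same
  clone) is out of scope; each site is tested marginally.
* Estimates of *s* inherit the uncertainty of *d*: if the true doubling
  count of an experiment is known, set it rather than relying on the
  calibrated default.
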