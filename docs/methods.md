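# Methods

## Model overview

The package studies two questions about trinucleotide mutational spectra:
(i) how far the spectrum estimated from a subsample of diploid individuals
sits from the whole population's spectrum, as a function of sample size and
demographic history, and (ii) the power of a pooled two-proportion Z test
to detect a population-specific rate shift of a single mutation type.

All variation is neutral.  Mutations are context specific and independent:
a site's total mutation rate and its derived-base distribution depend only
on the ancestral trinucleotide centred on it, through a 192-entry rate
matrix.  Ancestral context is fixed — rates are always read from the
ancestral sequence, and sites struck more than once on a genealogy are
discarded, matching the biallelic restriction of spectrum analyses.

## Coalescent engine

Genealogies are drawn backward in time under the structured coalescent.
N counts diploid individuals throughout; a lineage pair in a population of
size N(t) coalesces at rate 1/(2N(t)) per generation.  Epochs change size
instantaneously at their boundaries; within an epoch a forward exponential
growth rate g gives N(t) = N₀·exp(−g·(t − t₀)) backward, and the waiting
time to coalescence is drawn by exact inversion of the integrated hazard
(an epoch whose size grows into the past can yield no event, correctly
leaving the wait to the next boundary).  Migration relocates single
lineages backward at configured per-generation rates on configurable time
intervals; at a split time every lineage of the child population moves into
the parent.  The engine records, per branch, which population the lineage
occupied when — this is what lets a rate shift apply only to mutations
arising while a lineage is in the shifted population.

Mutation placement is exact given the genealogy: the total mutation count
is Poisson with mean Σ_segments (length × Σ_sites rate), and each mutation
is assigned hierarchically to a branch segment, a site (∝ per-site rate
under that segment's population matrix) and a derived base (the site's
conditional distribution).

Equivalence with the forward process is guarded two ways: a forward
Wright–Fisher oracle in this package (discrete generations, haploid gamete
resampling, 10·Nₑ burn-in, per-site ancestral-context mutation; supports
constant sizes and splits, and deliberately not growth or migration), run
at toy sizes (N ≤ 500) with an inflated per-site rate (10⁻⁵) so variation
accumulates — means of segregating-site counts agree within Monte-Carlo
error; and msprime as an independent structured-coalescent implementation
for genealogy statistics.  Closed forms (E[T₂] = 2N, Watterson's
E[S] = 4NμL·Σ1/i, the neutral folded SFS) are asserted in tests.

### Recombination

Recombination (10⁻⁸ /bp/generation in the study design) is approximated by
cutting the sequence into independent non-recombining windows (default
10 kb; the packaged experiments use 25–100 kb).  This overstates
recombination between windows and ignores it within them.  Expected
spectra and expected private-allele counts are unaffected; only
across-region variances are approximate.  Consequently per-replicate power
in "expected" mode (below) and mean convergence curves are insensitive to
the window length, which the experiments exploit by using longer windows
than the default for speed.

## Demographic models

* **Basic models**: ancestral population of 10,000 diploids; a derived
  population splits off 4,000 generations before present (configurable) at
  10,000 (constant), 1,000 (decline) or 100,000 (growth) diploids.  The
  forward-simulation notion of a 10·Nₑ burn-in has no coalescent analogue;
  the engine samples stationarity directly.
* **Human**: three-population out-of-Africa model with an OOA bottleneck
  ghost population, transcribed from Gravel et al. (2011), Table 2
  ("low-coverage + exons" fit), 25 y/generation; European and East Asian
  populations grow exponentially from the bottleneck (0.38%/0.48% per
  generation).
* **Chimpanzee**: four populations — Western, Nigeria-Cameroon, Central,
  Eastern — 20 y/generation.  Present-day sizes for Western (5,700) and
  Central (72,000) follow the published Great Ape Diversity Panel
  estimates; the remaining sizes, the split times (~150/250/550 kya) and
  the Central↔Eastern migration are literature-scale approximations, since
  the source model's full supplementary parameter table is not reproduced
  anywhere in this package's inputs.  Results for chimpanzees therefore
  carry parameter uncertainty beyond Monte-Carlo error (see Limitations).

Model configs are data (YAML), validated on load: positive sizes, ordered
epochs, migration rates in [0, 1], and split events forming a single tree
with parents extant at the split, so backward lineage movement is defined
at every time.

## Sequences

The synthetic generator draws i.i.d. bases at a chosen composition —
uniform for fine-scale experiments (making every category's expected share
exactly 1/c under a uniform matrix) and 59% AT / 41% GC ("hominid-like")
for broad-scale chromosomes.  It stands in for real reference chromosomes;
it does not emulate isochores, CpG islands or repeats, so passing tests
show correctness of the sampling machinery, not realism of any particular
genome's context composition.  Missing bases (N) in real FASTA input are
imputed once per experiment from the chromosome-wide composition.

## Spectra and subsampling

Private SNPs of a focal population are rows segregating there
(0 < derived count < haplotype count) with derived count 0 in every other
sampled population.  Spectra are tallied in the stranded 192 space;
collapsing to 96 merges each type with its reverse complement into the
pyrimidine-centred representative (the signature-literature convention; the
source analyses name none).  All frequencies enter the spectrum, including
singletons: the empirical practice of dropping singletons addresses
sequencing error, which these simulations do not contain.

Subsampling draws diploid individuals uniformly **with replacement**
(sizes beyond the population sample are legal); privacy is still evaluated
against the full non-focal samples.  The distortion statistic is the sum
of absolute proportion differences across categories (twice the total
variation distance, range [0, 2]); "percent" columns are ×100.  The full
experimental grid is 5–200 by 5, 300–1,000 by 100, 2,000–10,000 by 1,000
(57 sizes), five replicate draws per size; packaged defaults use smaller
grids.

A scale note: the "whole population" in the packaged broad-scale runs is a
large sample (200 diploids per population) rather than every individual of
the population, and chromosomes are 0.5–3 Mb rather than the 46.7 Mb of a
real chromosome 21.  Total-difference values scale roughly like
1/√(private-allele count), so desk-scale values are conservative
(larger) relative to full-chromosome runs, and ≥-bounds checked at desk
scale would only tighten at full scale.

## Power procedure

For a population pair and a focal mutation type, each replicate simulates
one region (default 1 Mb) under the pair's demographic model with a
Jukes–Cantor matrix; the shifted population's matrix has the focal type
(both strand representatives when working in the 96 space) multiplied by
the fold, then the whole matrix is rescaled so the overall rate stays at
μ = 10⁻⁸ (an option disables the rescaling).  Per population the replicate
yields a binomial count: successes = focal-type private alleles, trials =
all private segregating alleles.

Two modes:

* **expected** (default): power is the standard normal-approximation power
  of the pooled Z test at the *expected* shares (1/c vs f/(c−1+f) on a
  uniform sequence) with the *realized* trial counts, averaged over
  replicates.  This mirrors treating category counts as binomial with
  known proportions, and is deterministic given the trial counts.  It
  ignores the small dilution of the shift by mutations that arose on
  ancestral branches, so it is slightly optimistic.
* **empirical**: the Z test is applied once per replicate to the realized
  counts; power is the rejection fraction.  At fold 1 this calibrates the
  whole pipeline (rejection rate ≈ α; verified to within Monte-Carlo error
  across all three basic models).

Because the fold-shifted matrix is rescaled to the same overall rate and
category labels are assigned independently per mutation, the distribution
of trial counts is exactly invariant to the fold; the power surface
therefore shares one set of baseline simulations per sample size across
all folds in expected mode (a test checks agreement with fully per-fold
simulation).

α defaults to 0.05 two-tailed; c defaults to 96 (192 switchable).  Since
which population carries a shift is unknown in practice, both placements
are evaluated and the minimum of the two scenario-averaged powers is the
reported number.

## Reproducibility

Every cell of every experiment derives its seed from the master seed and
its labels through a keyed blake2b hash (`seed_stream`), so results are
bit-reproducible, independent of evaluation order, and collision-safe at
the scales used.  Output tables carry the config hash and master seed in
header lines.

## Problem sizes in the packaged runs

Chosen for a single desktop CPU: acceptance computations use 10,000
pairwise-TMRCA replicates; 200 Watterson replicates on 100 kb; 80
null-calibration replicates per basic model on 1 Mb; 30 power replicates
per fold for the chimpanzee pair and 10–20 for the human comparisons on
1 Mb regions (the original design's 100 regions per species shrink to
these counts, changing only Monte-Carlo error); and two 3 Mb broad-scale
chromosomes with 200-diploid population samples.  The test suite uses the
same machinery at smaller sizes.

## Known limitations

* Chimpanzee (and human fold-shift) parameter files are approximate
  transcriptions; headline chimpanzee power numbers shift by a few
  percentage points under plausible alternative parameter choices.
* Windowed recombination approximates variances, not means; confidence
  statements about across-region variability inherit that approximation.
* The WF oracle's scope excludes growth and migration, so engine-oracle
  equivalence is only checked directly for size-change/split histories.
* Expected-mode power inherits the normal approximation of the Z test,
  which over- or under-rejects when expected successes per category are
  very small (empirical mode exists precisely to measure that).
* The 96-space fold shift applies to both strand representatives; a
  strand-biased mutational process is not representable in that mode (use
  the 192 space).
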