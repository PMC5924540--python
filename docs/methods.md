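# Methods

This note records the models implemented in `mitopop`, the defaults and
why they were chosen, the numerical decisions that matter, and what the
synthetic-data generator does and does not emulate. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Sequence handling and haplotypes

Alignments are matrices over `{A,C,G,T,N,-}`. Gaps are treated as
missing, the same as `N`, throughout: population-level mtDNA indels are
rare, frequently alignment artefacts, and the downstream statistics
(Hamming distances, segregating sites) are defined on substitutions.
IUPAC ambiguity codes are accepted on read and recoded to `N` with a
logged count. Coordinates are 0-based half-open internally and 1-based
in written reports.

A column is *variable* when it contains at least two distinct
non-missing bases (`exclude-missing` policy); the `strict` policy first
deletes every column containing any missing cell — the conservative
treatment when ancient, gappy sequences would otherwise inflate
apparent invariance. Haplotypes collapse sequences identical over the
variable positions. A sequence with missing data *at* a variable
position joins an existing haplotype only when compatible (equal at all
mutually observed positions) with exactly one; otherwise it stands
alone and is flagged ambiguous. This rule is ours: haplotype callers
differ in how they resolve partial sequences, and an explicit,
deterministic, logged rule was preferred over silently guessing. The
flag is written into the haplotype table so downstream counts can be
audited.

## Diversity statistics

Nucleotide diversity is the mean per-pair proportion of differing
sites, using each pair's own effective length under pairwise deletion
(robust to ancient-DNA dropout); a complete-deletion mode is available
when exact comparability with column-filtered analyses is wanted. The
standard deviation is the square root of Nei's (1987) no-recombination
variance of π — appropriate for a single non-recombining mitochondrial
locus. Haplotype diversity uses Nei's heterozygosity estimator with the
n/(n−1) correction and Nei's sampling variance. These are the estimator
forms behind the familiar DnaSP output, chosen so results are
comparable with the population-genetics literature.

The deepest-lineage sampling probability (n−1)/(n+1) is the classical
result for the probability that a sample of n lineages from a panmictic
population brackets the root of the population genealogy. It frames the
interpretation of an ancient haplotype falling sister to the entire
modern sample: at n = 52 the probability of *missing* the deepest split
is only ~4%, so such a placement is unlikely unless the ancient
individual carries since-lost diversity.

## Group subsampling comparison

Between-group diversity uses raw mean pairwise difference counts from
k-subsamples (default k = 10, R = 100 replicates), not per-site rates,
matching how such comparisons are conventionally plotted; a per-site
flag exists for unequal alignment lengths. Sampling is without
replacement within a replicate and independent across replicates and
groups. Replicates are summarised as Tukey boxplots (1.5·IQR whiskers)
and groups ranked by median; pairs whose replicate ranges are disjoint
are flagged — the operational meaning of one group being "always"
more or less diverse than another under individual resampling.

One caution established by the test suite: with a single
non-recombining locus, the replicate spread reflects individual
sampling only, not genealogical noise. Distinguishing groups whose true
θ differs by two-fold is unreliable (one genealogy per group dominates
the variance); the design separates multi-fold contrasts robustly.

## Median-joining networks

Stage 1 is the ε-relaxed minimum spanning network: a link u–v is kept
iff d(u,v) ≤ bottleneck(u,v) + ε, where the bottleneck (minimax-path)
distance is computed from an MST; at ε = 0 this is exactly the union of
all minimum spanning trees. Stage 2 iterates: for every *feasible
triple* — three nodes joined within themselves by at least two current
MSN links (a triangle, or a path through a shared neighbour) — the
median (majority state per site) is computed; a site with a three-way
tie expands into all resolutions, capped at 32 combinations per triple
(beyond that the triple is skipped with a warning). New medians whose
connection cost d(u,m)+d(v,m)+d(w,m) lies within ε of the round's
minimum *and* which strictly reduce the MST length of the node set are
added; iteration stops at a fixed point (cap 50 rounds). Medians ending
with degree ≤ 2 lie on no shortest connection and are pruned, and final
links re-derived.

Two deliberate choices: the strict-reduction requirement guarantees the
network never grows longer than the haplotype-only MSN, and the
*parsimony length* of a network is defined as the MST length over its
final node set — the cost of one most-parsimonious tree realisable from
it — because the raw edge-weight sum of an MSN counts parallel
alternatives and is not comparable with a Steiner minimum. Determinism
comes from lexicographic processing of nodes and candidates. ε defaults
to 0 and site weights to 1, the conventional defaults when no weighting
scheme is justified.

## Serial-coalescent simulator

The genealogy simulator is a matrilineal (haploid) coalescent: N(t) is
the female effective population size itself, with no diploid factor-4
convention, and the pairwise coalescence hazard while k lineages are
active is k(k−1)/(2·N(t)·g) per year (g = generation time in years,
default 12). Demography is piecewise-constant; waiting times are drawn
exactly by piecewise-exponential inversion across epoch boundaries, and
a lineage becomes active only once time reaches its tip's age. The unit
tests verify the closed forms E[T₂] = N generations, E[total length] =
2N·Σ1/i, Watterson's E[S] and E[π] = θ, and cross-validate the TMRCA
distribution against msprime by a two-sample KS test.

Substitution uses JC69 by default (mutations as a Poisson process per
branch, uniform among alternative bases); HKY(κ, base frequencies) is
available, sampled exactly from the branch transition matrix
expm(Qt) with Q scaled to the requested rate. The model choice barely
matters for the package's statistics, which count differences rather
than fit substitution processes.

`make_study_fixture` emulates a two-ancient-plus-modern study design: 52
modern tips at 0 BP, two ancient tips at 5025 and 8470 years BP, a
4054 bp "coding" partition at 3.3954×10⁻⁸ substitutions/site/year (an
informative posterior-derived clock for mitochondrial protein-coding and
rRNA genes) and a 655 bp control-region partition at 1.7×10⁻⁷ (control
regions evolve several-fold faster; the value sits below the 2×10⁻⁷
upper bound conventionally placed on such rates). The demographic truth
is constant N_anc = 3000 females beyond 6000 BP, a log-linear decline
(discretised into four 1000-year steps) to N_anc/4 at 2000 BP, then
log-linear recovery (two steps, evaluated at each epoch's recent edge so
the present-day size *is* N_anc). N_anc = 3000 with g = 12 puts the
fixture's TMRCA around 50–80 kyr and yields ~20–26 haplotypes and ~50–90
segregating sites over the 54 sequences — the scale of a real
population-level mtDNA panel. The 4-fold decline depth is a stand-in:
the real magnitude of mid-Holocene declines inferred from such data is
read off skyline plots with wide credibility bands, not printed.

What the fixture does *not* emulate: sequencing or assembly error,
post-mortem damage (C→T deamination), contamination, recombination
(absent in mtDNA), selection, or population structure. Passing tests on
fixture data therefore validate the estimators under their own model
assumptions, not robustness to those artefacts. `inject_missing`
provides block-structured dropout for exercising missing-data paths.

## Skyline inference

Inference conditions on a *fixed* dated genealogy (the simulator's true
tree, or a user-supplied Newick with tip dates). This is a deliberate
reduction: jointly inferring tree and demography from sequences is a
different, much heavier tool, and conditioning on the genealogy makes
parameter recovery directly testable. The cost — genealogical
uncertainty is not propagated — is a known limitation, and credibility
bands should be read as conditional on the tree.

Trees in substitutions/site are calibrated by dividing node times by a
clock rate: a truncated-normal prior (point-calibration at its mean by
default, optional per-draw resampling) or a uniform prior for
fast-evolving partitions. Calibrated tip times must match declared tip
ages within tolerance, otherwise the offending tips are listed.

The likelihood groups the n−1 coalescent events into m contiguous
groups (default m = 10), each with constant θ = N_e·g in years. Working
in θ keeps the likelihood free of the generation time, which enters
only when trajectories are reported as N_e(t) = θ(t)/g. Sufficient
statistics per group (waiting-time integral A_j, event count c_j) make
a likelihood evaluation O(m), so desk-scale MCMC is cheap.

Two grouping rules are provided. `even-events` (the classic default)
balances event counts. With serially sampled panels whose events
concentrate in the recent past, even counts can leave one group
spanning nearly the whole calendar-time range — on fixture genealogies,
4000 BP and 8000 BP land in the *same* group in roughly half the
simulations, making any comparison between those epochs a structural
tie. `even-log-time` instead places group boundaries (still tied to
coalescent events, as the model requires) as close as possible to a
geometric grid between the first event and the root, spreading
resolution across calendar time; it is the recommended setting when the
question concerns specific dated windows, and constant-θ recovery and
coverage are indistinguishable between the two rules.

The prior is the classic skyline smoothing chain: θ₁ ∝ 1/θ₁ (bounded to
[10⁻⁶, 10¹²] years), θ_{i+1} | θ_i ~ Exponential(mean θ_i). Sampling is
Metropolis with log-scale Gaussian random-walk proposals per θ plus a
joint scale move; step sizes adapt toward 20–40% acceptance during
burn-in (default 10% of the chain) and are frozen afterwards, so the
retained chain is a valid time-homogeneous sampler and exactly
reproducible from its seed. Chains are initialised at the per-group
moment estimate A_j/(c_j+1). Default chain length is 30,000 sweeps;
the recovery and detection harnesses in the test suite use 10,000–30,000
sweeps, which hold ESS comfortably above the convergence gate.

ESS uses the initial-positive-sequence estimator of the integrated
autocorrelation time (autocovariance via FFT, consecutive pair sums
accumulated while positive), capped at the trace length; a constant
trace reports ESS 0 with a warning. The pipeline's convergence gate is
ESS > 200 for every parameter. Trajectory summaries evaluate each
posterior sample's step function θ(t) on a grid, convert by g, and
report pointwise medians with 2.5/97.5 percentile bands; grid points
beyond the root age are truncated with a warning.

Calibration facts established by the acceptance harness: on constant-θ
genealogies (n = 54, m = 10) the per-group posterior median lands within
a factor 1.5 of truth in roughly three-quarters of (seed, group) cases —
a group holds only ~5 coalescent events, so its log-posterior spread
(≈0.45) is about the factor-1.5 band half-width (log 1.5 ≈ 0.41), and
the smoothing prior pools only partially — while nominal-95% intervals
cover truth in ~97% of cases; on fixture genealogies the decline is
detected (median N_e at 4000 BP below that at 8000 BP) in well over 70%
of seeds under `even-log-time` grouping. Per-group statements are the
meaningful reading: demanding all ten groups simultaneously land within
factor 1.5 would have success probability near 0.8¹⁰ for *any* correctly
calibrated sampler.

## Pipeline

`run_pipeline` executes simulate → haplotypes → diversity → resample →
network → skyline in dependency order from a plain-YAML configuration,
validates inputs up front (hard errors before any compute), and writes
a manifest recording the package version, full configuration including
defaults, seeds, and a SHA-256 checksum of every output — a run is
reproducible and auditable from the manifest alone. Stochastic stages
require explicit seeds; nothing is seeded from the clock.

## Known limitations

* Fixed-genealogy skyline: no propagation of tree uncertainty.
* Single locus: all demographic information flows through one
  realised genealogy; credibility bands are wide and epochs with few
  coalescent events are essentially prior-driven.
* Haplotype network medians are capped per triple at 32 tie
  resolutions; data with extensive three-way polymorphism may produce
  warnings and a sparser median set.
* Gap-as-missing discards any phylogenetic signal in indels.
* The resampling comparison assumes groups are aligned to comparable
  regions; raw counts are not length-corrected unless requested.
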