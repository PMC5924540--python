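# mitopop

Mitochondrial population genetics at desk scale: haplotype collapsing and
Nei diversity statistics, subsampling-based diversity comparison between
species groups, median-joining haplotype networks, serial-coalescent
simulation with ancient (radiocarbon-dated) tips, and Bayesian skyline
inference of female effective population size on a fixed dated genealogy.

## Who this is for

Analyses of mixed ancient + modern mitochondrial DNA panels — e.g. a few
Holocene sub-fossil sequences set against dozens of modern conspecifics —
ask a recurring set of questions: how many haplotypes and variable sites
does the sample hold, and how much does a single ancient individual add?
How does the group's diversity compare with related taxa once sample
sizes are equalised? How do the haplotypes relate (network), and what
does the dated genealogy say about female effective population size
(N<sub>e</sub>) through time? `mitopop` implements that workflow as a
tested Python library with a thin CLI, plus a coalescent simulator that
generates data with exactly the structure the inference assumes, so every
stage can be validated against known truth.

## The models in brief

**Diversity.** Haplotype diversity Hd = n/(n−1)·(1 − Σp<sub>i</sub>²)
and nucleotide diversity π = Σ<sub>i&lt;j</sub> d<sub>ij</sub> /
(C(n,2)·L), with Nei's (1987) sampling variances; missing data (`N`,
`-`) handled by pairwise deletion. The probability that a sample of n
individuals from a panmictic population contains the population's
deepest divergence is (n−1)/(n+1) — for n = 52 this is 0.96, which is
why an ancient lineage falling *outside* the modern sample's diversity
is strong evidence of lost variation.

**Group comparison.** Draw k individuals per group (default k = 10),
average the pairwise count of differing positions over all C(k,2)
pairs, repeat R times; compare the replicate distributions as Tukey
boxplots, flagging group pairs whose ranges do not overlap.

**Median-joining network.** The ε-relaxed minimum spanning network over
haplotype Hamming distances, iteratively augmented with median vectors
(majority consensus of feasible node triples) that shorten connections,
then pruned (Bandelt, Forster & Röhl 1999).

**Skyline.** Conditional on a dated genealogy with heterochronous tips,
coalescent intervals grouped into m segments (default 10) each carry a
constant θ = N<sub>e</sub>·g (g = generation time, default 12 years);
with k active lineages the coalescence hazard is k(k−1)/(2θ) per year.
MCMC under the classic skyline smoothing prior yields posterior
trajectories N<sub>e</sub>(t) with 95% credibility bands; convergence is
gated at ESS > 200 per parameter.

**Simulator.** A matrilineal serial coalescent (haploid; N is female
effective size directly) with piecewise-constant N(t) and tips activated
at their sampling ages, plus JC69/HKY substitution along the genealogy.
`make_study_fixture` bundles a study-design data set: 52 modern + 2
ancient tips (5025 and 8470 years BP), ~4054 bp coding + ~655 bp
control-region partitions, and a demographic truth that declines from
6000 BP to a quarter of the ancestral size at 2000 BP, then recovers.

## Worked example

```
$ mitopop simulate --seed 1 --scale 1.0 --out-dir demo
$ mitopop diversity demo/alignment.fasta --dates demo/tip_dates.tsv
[
  {
    "label": "combined",
    "n": 54,
    "L": 4709,
    "S": 56,
    "n_haplotypes": 21,
    "hd": 0.8463,
    "hd_sd": 0.0436,
    "pi": 0.002360,
    "pi_sd": 0.001208,
    "mean_pairwise": 11.114
  },
  ...
]
```

54 sequences over 4709 aligned sites carry 56 segregating sites forming
21 haplotypes; haplotype diversity is high (0.85 ± 0.04) while per-site
nucleotide diversity is low (0.0024 ± 0.0012) — the signature of many
closely related mitochondrial lineages. Then:

```
$ mitopop network demo/alignment.fasta --out-prefix demo/net
21 observed + 5 median nodes, parsimony length 56
$ mitopop skyline demo/genealogy.nwk --dates demo/tip_dates.tsv \
      --grouping even-log-time --seed 1 --out-prefix demo/sky
min ESS 2893.1 (converged)
```

`demo/sky_trajectory.tsv` tabulates the posterior median and 95%
credibility band of female N<sub>e</sub> against years BP; on fixture
data it recovers the simulated decline-and-recovery shape within its
(wide) credibility band.

A YAML-configured end-to-end run (`mitopop all config.yaml`) executes
simulate → haplotypes → diversity → network → skyline and writes a
manifest recording every parameter, seed and output checksum.

## Layout

```
src/mitopop/
  alignment.py    aligned sequence sets, missing data, variable sites
  haplotypes.py   haplotype collapsing
  diversity.py    Nei diversity statistics
  resampling.py   group subsampling comparison
  network.py      minimum-spanning / median-joining networks
  genealogy.py    dated trees, Newick I/O
  simulate.py     serial-coalescent simulator + study fixture
  skyline.py      grouped skyline likelihood, MCMC, ESS
  pipeline.py     orchestration, validation, manifests
  cli.py          `mitopop` command group
docs/methods.md   modelling assumptions, defaults, limitations
```
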