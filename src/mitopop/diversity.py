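"""Diversity statistics for mitochondrial alignments.

Estimators follow Nei (1987, *Molecular Evolutionary Genetics*), the
formulas behind DnaSP's standard output:

* nucleotide diversity  pi = sum_{i<j} d_ij / (C(n,2) * L_eff)   (eq. 10.5),
  with its no-recombination sampling variance (eq. 10.7);
* haplotype diversity   Hd = n/(n-1) * (1 - sum p_i^2)           (eq. 8.4),
  with the sampling variance of heterozygosity (eq. 8.12).

Missing data (N or gap) are handled by pairwise deletion by default:
each pair is compared over the sites observed in both, and pi uses the
per-pair effective length.  ``policy="complete"`` assumes the caller has
already removed missing columns and divides by the full length.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict
import numpy as np

from .alignment import AlignedSequenceSet, count_segregating_sites
from .haplotypes import HaplotypeTable, collapse_haplotypes

__all__ = [
    "pairwise_diff",
    "nucleotide_diversity",
    "haplotype_diversity",
    "segregating_sites_delta",
    "deepest_lineage_probability",
    "DiversitySummary",
    "summarize",
]

_MISS = ("N", "-")


def pairwise_diff(a: str, b: str, policy: str = "pairwise-deletion") -> tuple[int, int]:
    """Count differing positions between two aligned sequences.

    Returns ``(differences, sites_compared)``.  Under pairwise deletion a
    position where either sequence is missing is skipped (and not counted
    as compared); under ``"complete"`` the caller is expected to have
    pre-filtered missing columns and all positions are compared.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if policy not in ("pairwise-deletion", "complete"):
        raise ValueError(f"unknown policy {policy!r}")
    diff = 0
    compared = 0
    if policy == "pairwise-deletion":
        for x, y in zip(a, b):
            if x in _MISS or y in _MISS:
                continue
            compared += 1
            if x != y:
                diff += 1
    else:
        compared = len(a)
        diff = sum(x != y for x, y in zip(a, b))
    return diff, compared


def _pair_stats(aln: AlignedSequenceSet, policy: str) -> tuple[float, float]:
    """Mean per-pair (d_ij / L_ij) and mean d_ij over all pairs."""
    n = aln.n_sequences
    miss = aln.missing_mask()
    per_site = []
    raw = []
    for i, j in itertools.combinations(range(n), 2):
        if policy == "pairwise-deletion":
            ok = ~(miss[i] | miss[j])
            L = int(ok.sum())
            d = int((aln.matrix[i, ok] != aln.matrix[j, ok]).sum())
        else:
            L = aln.n_sites
            d = int((aln.matrix[i] != aln.matrix[j]).sum())
        if L == 0:
            raise ValueError(f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}")
        per_site.append(d / L)
        raw.append(d)
    return float(np.mean(per_site)), float(np.mean(raw))


def nucleotide_diversity(
    aln: AlignedSequenceSet, policy: str = "pairwise-deletion"
) -> tuple[float, float]:
    """Nucleotide diversity per site and its standard deviation.

    pi averages the per-pair proportion of differing sites (per-pair
    effective length under pairwise deletion).  The standard deviation is
    the square root of Nei's no-recombination variance

        V(pi) = (n+1) / (3(n-1)L) * pi  +  2(n^2+n+3) / (9n(n-1)) * pi^2

    with L the mean number of sites compared.
    """
    n = aln.n_sequences
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    pi, _ = _pair_stats(aln, policy)
    if policy == "pairwise-deletion":
        miss = aln.missing_mask()
        Ls = [
            int((~(miss[i] | miss[j])).sum())
            for i, j in itertools.combinations(range(n), 2)
        ]
        L = float(np.mean(Ls))
    else:
        L = float(aln.n_sites)
    var = (n + 1) / (3 * (n - 1) * L) * pi + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) * pi**2
    return pi, math.sqrt(max(var, 0.0))


def mean_pairwise_differences(
    aln: AlignedSequenceSet, policy: str = "pairwise-deletion"
) -> float:
    """Mean raw count of differing positions over all sequence pairs."""
    _, mean_raw = _pair_stats(aln, policy)
    return mean_raw


def haplotype_diversity(ht: HaplotypeTable) -> tuple[float, float]:
    """Haplotype (gene) diversity and its standard deviation.

    Hd = n/(n-1) * (1 - sum p_i^2); the variance is Nei's sampling
    variance of heterozygosity,

        V(Hd) = 2/(n(n-1)) * { 2(n-2) [sum p^3 - (sum p^2)^2]
                               + sum p^2 - (sum p^2)^2 }.
    """
    n = ht.n_sequences
    if n < 2:
        raise ValueError("haplotype diversity needs >= 2 sequences")
    p = np.asarray(ht.counts, dtype=float) / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return hd, math.sqrt(max(var, 0.0))


def segregating_sites_delta(
    aln: AlignedSequenceSet, focal_id: str, missing_policy: str = "exclude-missing"
) -> tuple[int, int]:
    """Segregating-site count with and without one focal sequence.

    Quantifies how much variation a single (e.g. ancient) individual adds
    to the sample; removing a row can never create new variable columns,
    so ``S_without <= S_with`` always.
    """
    if aln.n_sequences < 3:
        raise ValueError("need >= 3 sequences to compare with/without a focal row")
    s_with = count_segregating_sites(aln, missing_policy)
    s_without = count_segregating_sites(aln.drop(focal_id), missing_policy)
    return s_with, s_without


def deepest_lineage_probability(n: int) -> float:
    """Probability that a sample of n individuals from a panmictic
    population contains the deepest divergence (root split) of the
    population's genealogy: (n - 1)/(n + 1).

    At n = 52 this is ~0.96: a random modern sample of that size almost
    surely brackets the basal split, so a lineage falling outside it
    (as an ancient sequence may) signals diversity since lost.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return (n - 1) / (n + 1)


@dataclass
class DiversitySummary:
    """Standard diversity panel for one alignment (or partition)."""

    label: str
    n: int
    L: int
    S: int
    n_haplotypes: int
    hd: float
    hd_sd: float
    pi: float
    pi_sd: float
    mean_pairwise: float

    def as_dict(self) -> dict:
        return asdict(self)


def summarize(
    aln: AlignedSequenceSet,
    policy: str = "pairwise-deletion",
    missing_policy: str = "exclude-missing",
) -> list[DiversitySummary]:
    """Diversity panel for the combined alignment and each partition."""
    out = []
    targets: list[tuple[str, AlignedSequenceSet]] = [("combined", aln)]
    for name in aln.partitions:
        targets.append((name, aln.partition(name)))
    for label, sub in targets:
        ht = collapse_haplotypes(sub, missing_policy)
        hd, hd_sd = haplotype_diversity(ht)
        pi, pi_sd = nucleotide_diversity(sub, policy)
        out.append(
            DiversitySummary(
                label=label,
                n=sub.n_sequences,
                L=sub.n_sites,
                S=count_segregating_sites(sub, missing_policy),
                n_haplotypes=len(ht),
                hd=hd,
                hd_sd=hd_sd,
                pi=pi,
                pi_sd=pi_sd,
                mean_pairwise=mean_pairwise_differences(sub, policy),
            )
        )
    return out
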