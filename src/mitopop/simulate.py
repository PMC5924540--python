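"""Serial-coalescent simulation of dated genealogies and mtDNA alignments.

The simulator generates data with the statistical structure the rest of
the pipeline assumes: a matrilineal (haploid) coalescent with
piecewise-constant female effective population size N(t), heterochronous
tips (ancient + modern sampling ages), and neutral substitution along
the resulting genealogy.  While k lineages are active inside an epoch of
size N, the pairwise coalescence hazard is k(k-1) / (2 N g) per year (g
the generation time in years); epoch boundaries and tip-activation times
are handled by piecewise-exponential time rescaling.

``make_study_fixture`` bundles a synthetic data set emulating a
middle-Holocene ancient-DNA study design: 52 modern mitochondrial
sequences plus two ancient ones dated 5025 and 8470 years BP, a ~4054 bp
coding + ~655 bp control-region alignment, and a demographic truth with
a decline starting 6000 years BP and recovery over the last 2000 years.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import AlignedSequenceSet, write_alignment
from .genealogy import Genealogy, GenealogyNode

__all__ = [
    "DemographicModel",
    "simulate_genealogy",
    "simulate_alignment",
    "make_study_fixture",
    "inject_missing",
    "StudyFixture",
]

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class DemographicModel:
    """Piecewise-constant female effective population size.

    ``epochs`` lists ``(start_age_years_BP, ne)`` with start ages strictly
    increasing from 0; each epoch extends to the next start (the last to
    infinity).  ``ne`` is the female effective size directly (haploid,
    matrilineal locus — no diploid factor-4 convention).
    """

    epochs: list[tuple[float, float]]
    generation_time: float = 12.0

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("at least one epoch required")
        starts = [s for s, _ in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at age 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start ages must be strictly increasing")
        if any(n <= 0 or not math.isfinite(n) for _, n in self.epochs):
            raise ValueError("all population sizes must be positive and finite")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive")

    def size_at(self, age: float) -> float:
        ne = self.epochs[0][1]
        for start, n in self.epochs:
            if age >= start:
                ne = n
            else:
                break
        return ne

    def boundaries(self) -> list[float]:
        return [s for s, _ in self.epochs[1:]]

    # JSON round-trip (the "true model" file of a simulated bundle)
    def to_json(self) -> str:
        return json.dumps(
            {
                "epochs": [{"start_age": s, "ne": n} for s, n in self.epochs],
                "generation_time": self.generation_time,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DemographicModel":
        obj = json.loads(text)
        return cls(
            epochs=[(e["start_age"], e["ne"]) for e in obj["epochs"]],
            generation_time=obj["generation_time"],
        )


# ---------------------------------------------------------------------- #
# genealogy simulation
# ---------------------------------------------------------------------- #
def simulate_genealogy(
    demog: DemographicModel,
    tips: list[tuple[str, float]],
    seed: int,
) -> Genealogy:
    """Simulate a heterochronous coalescent genealogy.

    Moving backwards in time, a lineage becomes active at its tip age;
    waiting times to coalescence are drawn by inverting the cumulative
    hazard integral(k(k-1) / (2 N(t) g)) dt across epoch boundaries and
    tip activations.  Deterministic given ``seed``.
    """
    if len(tips) < 2:
        raise ValueError("need at least 2 tips")
    labels = [t[0] for t in tips]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    if any(age < 0 for _, age in tips):
        raise ValueError("tip ages must be >= 0")

    rng = np.random.default_rng(seed)
    g = demog.generation_time
    pending = sorted(tips, key=lambda t: (t[1], t[0]))  # by age then label
    active: list[GenealogyNode] = []
    t = pending[0][1]
    boundaries = demog.boundaries()

    while pending and pending[0][1] <= t:
        label, age = pending.pop(0)
        active.append(GenealogyNode(time=age, label=label))

    while len(active) + len(pending) > 1:
        if len(active) < 2:
            label, age = pending.pop(0)
            t = age
            active.append(GenealogyNode(time=age, label=label))
            while pending and pending[0][1] <= t:
                label, age = pending.pop(0)
                active.append(GenealogyNode(time=age, label=label))
            continue

        k = len(active)
        target = rng.exponential(1.0)  # unit-rate cumulative hazard to consume
        next_tip = pending[0][1] if pending else math.inf
        coal_time = None
        tcur = t
        while True:
            ne = demog.size_at(tcur)
            rate = k * (k - 1) / (2.0 * ne * g)  # per year
            next_boundary = min(
                [b for b in boundaries if b > tcur] + [math.inf]
            )
            horizon = min(next_boundary, next_tip)
            span = horizon - tcur
            if rate * span >= target:
                coal_time = tcur + target / rate
                break
            target -= rate * span
            tcur = horizon
            if tcur == next_tip:
                break  # a new sample interrupts the wait

        if coal_time is None:
            label, age = pending.pop(0)
            t = age
            active.append(GenealogyNode(time=age, label=label))
            while pending and pending[0][1] <= t:
                label, age = pending.pop(0)
                active.append(GenealogyNode(time=age, label=label))
            continue

        t = coal_time
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        parent = GenealogyNode(time=t)
        parent.add_child(a)
        parent.add_child(b)
        active = [n for idx, n in enumerate(active) if idx not in (i, j)]
        active.append(parent)

    return Genealogy(active[0], units="years")


# ---------------------------------------------------------------------- #
# sequence simulation
# ---------------------------------------------------------------------- #
def _hky_matrix(kappa: float, freqs: np.ndarray, mu: float):
    """HKY85 rate matrix scaled so the expected rate is mu subs/site/year."""
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(freqs, np.diag(q))
    return q * (mu / scale)


def simulate_alignment(
    gen: Genealogy,
    mu: float,
    length: int,
    model: str = "JC69",
    kappa: float = 2.0,
    base_freqs=None,
    seed: int = 0,
) -> AlignedSequenceSet:
    """Evolve sequences along a dated genealogy.

    The root sequence is drawn from the model's equilibrium frequencies;
    under JC69 mutations are placed as a Poisson process on each branch
    (rate ``mu`` per site per year) with uniform choice among the three
    alternative bases.  Under HKY the per-branch substitution process is
    sampled exactly from the transition-probability matrix expm(Q t).
    Returns an ungapped alignment with tip ages attached.
    """
    if gen.units != "years":
        raise ValueError("genealogy must be calibrated to years before simulation")
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if length < 1:
        raise ValueError("length must be >= 1")
    if model not in ("JC69", "HKY"):
        raise ValueError(f"unknown substitution model {model!r}")

    rng = np.random.default_rng(seed)
    if model == "JC69":
        freqs = np.full(4, 0.25)
    else:
        freqs = np.asarray(
            base_freqs if base_freqs is not None else [0.25, 0.25, 0.25, 0.25],
            dtype=float,
        )
        freqs = freqs / freqs.sum()
        q = _hky_matrix(kappa, freqs, mu)

    root_states = rng.choice(4, size=length, p=freqs)
    states: dict[int, np.ndarray] = {id(gen.root): root_states}
    ids, ages, rows = [], [], []

    for node in gen.preorder():
        if node.parent is not None:
            parent_states = states[id(node.parent)]
            t = node.parent.time - node.time
            child = parent_states.copy()
            if model == "JC69":
                n_mut = rng.poisson(mu * t * length)
                for _ in range(n_mut):
                    site = rng.integers(length)
                    child[site] = (child[site] + 1 + rng.integers(3)) % 4
            else:
                from scipy.linalg import expm

                p = expm(q * t)
                for s in range(4):
                    idx = np.nonzero(child == s)[0]
                    if len(idx):
                        child[idx] = rng.choice(4, size=len(idx), p=p[s])
            states[id(node)] = child
        if node.is_tip:
            ids.append(node.label)
            ages.append(node.time)
            rows.append(BASES[states[id(node)]])

    return AlignedSequenceSet(
        ids=ids, matrix=np.array(rows), ages=np.array(ages, dtype=float)
    )


# ---------------------------------------------------------------------- #
# ancient-DNA dropout
# ---------------------------------------------------------------------- #
def inject_missing(
    aln: AlignedSequenceSet,
    target_ids,
    fraction: float,
    block_length: int = 50,
    seed: int = 0,
) -> AlignedSequenceSet:
    """Replace contiguous blocks with N in target rows until at least
    ``fraction`` of their sites are missing (emulating ancient-DNA
    dropout).  Other rows are untouched; block granularity means the
    final missing fraction can overshoot by up to one block."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    for tid in target_ids:
        aln.index_of(tid)  # raise on unknown id
    new = AlignedSequenceSet(
        ids=list(aln.ids),
        matrix=aln.matrix.copy(),
        ages=aln.ages.copy(),
        partitions=dict(aln.partitions),
        source_columns=aln.source_columns.copy(),
    )
    if fraction == 0.0:
        return new
    rng = np.random.default_rng(seed)
    L = new.n_sites
    for tid in target_ids:
        i = new.index_of(tid)
        if fraction >= 1.0:
            new.matrix[i, :] = "N"
            continue
        while (new.matrix[i] == "N").sum() < fraction * L:
            start = rng.integers(0, max(L - block_length, 0) + 1)
            new.matrix[i, start : start + block_length] = "N"
    return new


# ---------------------------------------------------------------------- #
# the bundled study-design fixture
# ---------------------------------------------------------------------- #
@dataclass
class StudyFixture:
    alignment: AlignedSequenceSet
    genealogy: Genealogy
    demography: DemographicModel
    mu: float

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "alignment": out / "alignment.fasta",
            "dates": out / "tip_dates.tsv",
            "genealogy": out / "genealogy.nwk",
            "demography": out / "true_demography.json",
        }
        write_alignment(self.alignment, paths["alignment"], paths["dates"])
        self.genealogy.write_newick(paths["genealogy"])
        paths["demography"].write_text(self.demography.to_json() + "\n")
        return paths


#: fixture constants: tip layout, rate, generation time, demography shape
N_MODERN = 52
ANCIENT_TIPS = (("anc05001", 5025.0), ("anc97001", 8470.0))
MU_CODING = 3.3954e-8  # substitutions/site/year, informative clock prior mean
RATE_SD = 7.705e-9
MU_DLOOP = 1.7e-7      # control region ~5x faster; below the 2e-7 upper bound
GENERATION_TIME = 12.0
CODING_LENGTH = 4054
DLOOP_LENGTH = 655
N_ANCESTRAL = 3000.0   # female effective size in the deep past
DECLINE_FACTOR = 4.0   # N falls to N_ANCESTRAL / 4 at the trough


def study_demography(
    n_anc: float = N_ANCESTRAL, decline_factor: float = DECLINE_FACTOR
) -> DemographicModel:
    """Piecewise-constant truth: constant ``n_anc`` before 6000 BP, a
    log-linear decline (4 steps) from 6000 to 2000 BP down to
    ``n_anc/decline_factor``, then recovery (2 steps) over the last
    2000 years back to ``n_anc``."""
    trough = n_anc / decline_factor
    epochs: list[tuple[float, float]] = []
    # recovery over the last 2000 years, reaching n_anc at the present:
    # two log-linear steps evaluated at each epoch's recent edge
    for start in (0.0, 1000.0):
        ne = n_anc * (trough / n_anc) ** (start / 2000.0)
        epochs.append((start, ne))
    # decline: four 1000-year steps spanning (2000, 6000]
    for start in (2000.0, 3000.0, 4000.0, 5000.0):
        mid = start + 500.0
        frac = (6000.0 - mid) / 4000.0  # 1 at 2000 BP side, 0 at 6000 BP
        ne = n_anc * (trough / n_anc) ** frac
        epochs.append((start, ne))
    epochs.append((6000.0, n_anc))
    return DemographicModel(epochs=epochs, generation_time=GENERATION_TIME)


def make_study_fixture(seed: int, scale: float = 1.0) -> StudyFixture:
    """Simulate the study-design bundle: 52 modern + 2 ancient tips
    (5025 and 8470 years BP), coding + control-region partitions, and
    the decline/recovery demographic truth.  ``scale`` shrinks sequence
    length for fast tests; byte-identical output for a given seed."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    demog = study_demography()
    tips = [(f"modern_{i:02d}", 0.0) for i in range(1, N_MODERN + 1)]
    tips += [(label, age) for label, age in ANCIENT_TIPS]

    rng = np.random.default_rng(seed)
    gen_seed, coding_seed, dloop_seed = rng.integers(2**31 - 1, size=3)
    gen = simulate_genealogy(demog, tips, seed=int(gen_seed))

    coding_len = max(int(round(scale * CODING_LENGTH)), 1)
    dloop_len = max(int(round(scale * DLOOP_LENGTH)), 1)
    coding = simulate_alignment(gen, mu=MU_CODING, length=coding_len, seed=int(coding_seed))
    dloop = simulate_alignment(gen, mu=MU_DLOOP, length=dloop_len, seed=int(dloop_seed))
    aln = AlignedSequenceSet(
        ids=list(coding.ids),
        matrix=np.hstack([coding.matrix, dloop.matrix[[dloop.index_of(i) for i in coding.ids]]]),
        ages=coding.ages.copy(),
        partitions={
            "coding": (0, coding_len),
            "dloop": (coding_len, coding_len + dloop_len),
        },
    )
    return StudyFixture(alignment=aln, genealogy=gen, demography=demog, mu=MU_CODING)
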