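"""Median-joining haplotype networks (Bandelt, Forster & Rohl 1999).

The network is built over haplotype variable-site strings.  Stage 1 is
the epsilon-relaxed minimum-spanning network (MSN): the union of all
links whose cost is within ``epsilon`` of the minimal cost connecting
their components during Kruskal growth — equivalently, all pairs (u, v)
with d(u, v) <= bottleneck(u, v) + epsilon, where the bottleneck distance
is the minimax path cost.  Stage 2 repeatedly adds *median vectors*
(majority-state consensus of node triples that are mutually linked in
the current MSN) whenever they reduce connection cost within epsilon,
then prunes medians that end up on no shortest connection (degree <= 2).

Characters are unordered (link cost = Hamming distance, weighted per
site); missing states (N, -) are excluded from comparisons.  Ties in
median construction generate all resolutions (capped); node ordering is
lexicographic for determinism.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .haplotypes import HaplotypeTable

logger = logging.getLogger(__name__)

__all__ = ["HaplotypeNetwork", "build_msn", "build_mj", "private_site_report"]

_MISS = ("N", "-")
_MEDIAN_TIE_CAP = 32


def hamming(a: str, b: str, weights: Optional[Sequence[int]] = None) -> int:
    """Weighted count of differing, mutually observed positions."""
    total = 0
    for i, (x, y) in enumerate(zip(a, b)):
        if x in _MISS or y in _MISS:
            continue
        if x != y:
            total += weights[i] if weights is not None else 1
    return total


@dataclass
class HaplotypeNetwork:
    """A haplotype network: observed nodes, inferred medians, weighted links.

    ``graph`` is an undirected networkx graph whose nodes are haplotype
    strings; node attributes carry ``kind`` ("observed" | "median"),
    ``label``, ``frequency`` and ``populations``; edge attributes carry
    ``weight`` (substitution count) and ``positions`` (differing variable
    positions, indices into the variable-site string).
    """

    graph: nx.Graph
    variable_positions: list[int] = field(default_factory=list)

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "median"]

    def total_edge_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def parsimony_length(self) -> int:
        """Length of a minimum spanning tree over the network's node set.

        This is the cost of one most-parsimonious tree realisable from
        the network (the network itself is a union of alternatives, so
        its raw edge-weight sum can exceed this).
        """
        if self.graph.number_of_nodes() <= 1:
            return 0
        comp = nx.Graph()
        nodes = list(self.graph.nodes)
        for u, v in itertools.combinations(nodes, 2):
            comp.add_edge(u, v, weight=hamming(u, v))
        mst = nx.minimum_spanning_tree(comp)
        return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))

    def write_edges_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node1\tnode2\tweight\tpositions\n")
            rows = sorted(
                (min(u, v), max(u, v), d) for u, v, d in self.graph.edges(data=True)
            )
            for u, v, d in rows:
                pos = ",".join(str(p + 1) for p in d["positions"])  # 1-based report
                fh.write(f"{self.graph.nodes[u]['label']}\t{self.graph.nodes[v]['label']}"
                         f"\t{d['weight']}\t{pos}\n")

    def write_nodes_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node\ttype\tfrequency\tpopulations\tsites\n")
            for n in sorted(self.graph.nodes):
                d = self.graph.nodes[n]
                pops = ",".join(sorted(d.get("populations", [])))
                fh.write(f"{d['label']}\t{d['kind']}\t{d['frequency']}\t{pops}\t{n}\n")

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for n, d in g.nodes(data=True):
            d["populations"] = ",".join(sorted(d.get("populations", [])))
        for u, v, d in g.edges(data=True):
            d["positions"] = ",".join(str(p) for p in d["positions"])
        nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------- #
# epsilon-relaxed minimum spanning network
# ---------------------------------------------------------------------- #
def _bottleneck_distances(nodes: list[str], dist) -> dict[tuple[str, str], int]:
    """Minimax path cost between all node pairs, via an MST."""
    comp = nx.Graph()
    comp.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        comp.add_edge(u, v, weight=dist(u, v))
    mst = nx.minimum_spanning_tree(comp)
    out: dict[tuple[str, str], int] = {}
    for src in nodes:
        # DFS from src tracking the max edge weight en route
        seen = {src: 0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y in mst.neighbors(x):
                if y not in seen:
                    seen[y] = max(seen[x], mst.edges[x, y]["weight"])
                    stack.append(y)
        for dst, w in seen.items():
            out[(src, dst)] = w
    return out


def _msn_edges(
    nodes: list[str], epsilon: int, weights: Optional[Sequence[int]]
) -> list[tuple[str, str, int]]:
    nodes = sorted(set(nodes))
    if len(nodes) < 2:
        return []
    dist = lambda u, v: hamming(u, v, weights)
    bottleneck = _bottleneck_distances(nodes, dist)
    edges = []
    for u, v in itertools.combinations(nodes, 2):
        d = dist(u, v)
        if d <= bottleneck[(u, v)] + epsilon:
            edges.append((u, v, d))
    return edges


def _diff_positions(a: str, b: str) -> list[int]:
    return [
        i for i, (x, y) in enumerate(zip(a, b))
        if x != y and x not in _MISS and y not in _MISS
    ]


def _assemble(
    nodes: list[str],
    observed: dict[str, dict],
    epsilon: int,
    weights,
    variable_positions,
) -> HaplotypeNetwork:
    g = nx.Graph()
    for n in sorted(set(nodes)):
        if n in observed:
            g.add_node(n, kind="observed", **observed[n])
        else:
            g.add_node(n, kind="median", label=f"mv_{n}", frequency=0, populations=set())
    for u, v, w in _msn_edges(list(g.nodes), epsilon, weights):
        g.add_edge(u, v, weight=w, positions=_diff_positions(u, v))
    return HaplotypeNetwork(graph=g, variable_positions=list(variable_positions))


def _observed_attrs(ht: HaplotypeTable) -> dict[str, dict]:
    attrs: dict[str, dict] = {}
    for h in ht.haplotypes:
        pops = {ht.populations[m] for m in h.members if m in ht.populations}
        if h.sites in attrs:  # ambiguous duplicates collapse onto one node
            attrs[h.sites]["frequency"] += h.count
            attrs[h.sites]["populations"] |= pops
        else:
            attrs[h.sites] = {
                "label": h.haplotype_id,
                "frequency": h.count,
                "populations": pops,
            }
    return attrs


def build_msn(
    ht: HaplotypeTable, epsilon: int = 0, weights: Optional[Sequence[int]] = None
) -> HaplotypeNetwork:
    """Minimum-spanning network over observed haplotypes.

    With ``epsilon=0`` this is the union of all minimum spanning trees;
    larger epsilon admits links up to that much costlier than the
    cheapest connection available at the same Kruskal stage.
    """
    if len(ht) < 1:
        raise ValueError("need at least one haplotype")
    attrs = _observed_attrs(ht)
    return _assemble(list(attrs), attrs, epsilon, weights, ht.variable_positions)


# ---------------------------------------------------------------------- #
# median joining
# ---------------------------------------------------------------------- #
def _medians(u: str, v: str, w: str) -> list[str]:
    """Majority-state consensus of a triple; ties expand all resolutions."""
    options: list[tuple[str, ...]] = []
    n_tie = 0
    for x, y, z in zip(u, v, w):
        states = [s for s in (x, y, z) if s not in _MISS]
        if not states:
            options.append(("N",))
            continue
        best = max(set(states), key=states.count)
        if states.count(best) >= 2:
            options.append((best,))
        else:
            n_tie += 1
            options.append(tuple(sorted(set(states))))
    if 3**n_tie > _MEDIAN_TIE_CAP:
        logger.warning("triple with %d three-way ties skipped (cap %d)", n_tie, _MEDIAN_TIE_CAP)
        return []
    return ["".join(combo) for combo in itertools.product(*options)]


def build_mj(
    ht: HaplotypeTable,
    epsilon: int = 0,
    weights: Optional[Sequence[int]] = None,
    max_iter: int = 50,
) -> HaplotypeNetwork:
    """Median-joining network: MSN augmented with inferred median vectors.

    Iterates: build the epsilon-MSN over the current node set; for every
    feasible triple (three nodes joined within themselves by at least two
    MSN links — a triangle or a path through a shared neighbour) compute
    median vectors; add the new medians whose connection cost
    d(u,m)+d(v,m)+d(w,m) is within epsilon of the round's minimum; stop
    at a fixed point.  Medians that end up
    with degree <= 2 (on no shortest connection) are then pruned, and the
    final links re-derived.  Deterministic: candidates are processed in
    lexicographic order.
    """
    if len(ht) < 1:
        raise ValueError("need at least one haplotype")
    attrs = _observed_attrs(ht)
    dist = lambda u, v: hamming(u, v, weights)
    nodes = sorted(attrs)

    for _ in range(max_iter):
        edges = _msn_edges(nodes, epsilon, weights)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((u, v) for u, v, _ in edges)
        candidates: dict[str, int] = {}
        for u, v, w in itertools.combinations(sorted(g.nodes), 3):
            # feasible triple: connected within itself by >= 2 MSN links
            # (a triangle, or a path through a shared neighbour)
            links = g.has_edge(u, v) + g.has_edge(u, w) + g.has_edge(v, w)
            if links < 2:
                continue
            for m in _medians(u, v, w):
                if m in nodes or "N" in m:
                    continue
                cost = dist(u, m) + dist(v, m) + dist(w, m)
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        # a median only helps if it can sit strictly inside connections,
        # i.e. it shortens some MST: accept within epsilon of the round's
        # cheapest connection cost and require an actual length reduction
        base_len = _mst_length(nodes, dist)
        new = [
            m for m in sorted(candidates)
            if candidates[m] <= lam + epsilon and _mst_length(nodes + [m], dist) < base_len
        ]
        if not new:
            break
        nodes = sorted(set(nodes) | set(new))
    else:
        raise RuntimeError(
            f"median joining did not converge in {max_iter} iterations "
            f"({len(nodes)} nodes, {len(attrs)} observed)"
        )

    # prune medians on no shortest connection (degree <= 2 in the MSN)
    while True:
        edges = _msn_edges(nodes, epsilon, weights)
        deg: dict[str, int] = {n: 0 for n in nodes}
        for u, v, _ in edges:
            deg[u] += 1
            deg[v] += 1
        drop = [n for n in nodes if n not in attrs and deg[n] <= 2]
        if not drop:
            break
        nodes = [n for n in nodes if n not in drop]

    return _assemble(nodes, attrs, epsilon, weights, ht.variable_positions)


def _mst_length(nodes: list[str], dist) -> int:
    if len(nodes) <= 1:
        return 0
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        g.add_edge(u, v, weight=dist(u, v))
    mst = nx.minimum_spanning_tree(g)
    return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))


# ---------------------------------------------------------------------- #
# private / shared variable sites of a focal haplotype
# ---------------------------------------------------------------------- #
def private_site_report(
    ht: HaplotypeTable, focal_haplotype: str, reference_ids: Sequence[str]
) -> tuple[list[int], int]:
    """Variable sites of a focal haplotype against a reference panel.

    A focal site is *variable* when the focal state differs from the
    reference consensus (majority state) at that position, and *unique*
    when the focal state occurs in no reference sequence at all.  Returns
    the variable positions (indices into the alignment coordinates) and
    the count unique to the focal haplotype.
    """
    if not reference_ids:
        raise ValueError("empty reference set")
    focal = ht.by_id(focal_haplotype)
    member_to_hap = ht.membership()
    ref_haps = []
    for rid in reference_ids:
        if rid not in member_to_hap:
            raise KeyError(f"unknown reference sequence id {rid!r}")
        ref_haps.append(ht.by_id(member_to_hap[rid]).sites)

    variable: list[int] = []
    unique = 0
    for i, pos in enumerate(ht.variable_positions):
        f = focal.sites[i]
        if f in _MISS:
            continue
        states = [h[i] for h in ref_haps if h[i] not in _MISS]
        if not states:
            continue
        consensus = max(set(states), key=states.count)
        if f != consensus:
            variable.append(pos)
            if f not in states:
                unique += 1
    return variable, unique
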