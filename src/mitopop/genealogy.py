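"""Rooted, dated genealogies for heterochronous (serially sampled) data.

A :class:`Genealogy` is a rooted binary tree whose nodes carry *times*
measured backwards from the present (years BP), or — before clock
calibration — expected substitutions per site.  Tips may be sampled at
different ages (ancient + modern sampling), so branch lengths are
differences of node times, not shared tip-to-root depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

__all__ = ["GenealogyNode", "Genealogy"]

#: tolerance (relative to tree depth) for tip-age consistency checks
_AGE_RTOL = 1e-6


@dataclass
class GenealogyNode:
    """One node of a genealogy; ``time`` increases into the past."""

    time: float
    label: Optional[str] = None
    children: list["GenealogyNode"] = field(default_factory=list)
    parent: Optional["GenealogyNode"] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "GenealogyNode") -> None:
        child.parent = self
        self.children.append(child)


class Genealogy:
    """Rooted binary tree with per-node times and a unit flag.

    Parameters
    ----------
    root
        Root node; every internal node must have exactly two children and
        a time strictly greater than either child's.
    units
        ``"years"`` (years BP) or ``"subs"`` (expected substitutions per
        site).  Operations that need calendar time reject ``"subs"`` trees.
    """

    def __init__(self, root: GenealogyNode, units: str = "years"):
        if units not in ("years", "subs"):
            raise ValueError(f"unknown time units {units!r}")
        self.root = root
        self.units = units
        self.validate()

    # ------------------------------------------------------------------ #
    # structure
    # ------------------------------------------------------------------ #
    def preorder(self) -> Iterator[GenealogyNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def tips(self) -> list[GenealogyNode]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[GenealogyNode]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def tip_ages(self) -> dict[str, float]:
        return {n.label: n.time for n in self.tips()}

    def coalescent_times(self) -> list[float]:
        """Times of the n-1 coalescent events, sorted increasing (into the past)."""
        return sorted(n.time for n in self.internal_nodes())

    @property
    def tmrca(self) -> float:
        return self.root.time

    def branch_length(self, node: GenealogyNode) -> float:
        if node.parent is None:
            return 0.0
        return node.parent.time - node.time

    def total_branch_length(self) -> float:
        return sum(self.branch_length(n) for n in self.preorder() if n.parent is not None)

    def validate(self) -> None:
        tips = 0
        internals = 0
        labels = []
        for node in self.preorder():
            if node.is_tip:
                tips += 1
                if node.label is None:
                    raise ValueError("tip without label")
                labels.append(node.label)
            else:
                internals += 1
                if len(node.children) != 2:
                    raise ValueError("genealogy must be strictly bifurcating")
                for child in node.children:
                    if not node.time > child.time:
                        raise ValueError(
                            f"node time {node.time} does not exceed child time {child.time}"
                        )
        if len(set(labels)) != tips:
            raise ValueError("duplicate tip labels")
        if internals != tips - 1:
            raise ValueError(f"{tips} tips require {tips - 1} internal nodes, found {internals}")

    # ------------------------------------------------------------------ #
    # unit conversion
    # ------------------------------------------------------------------ #
    def scaled(self, factor: float, units: Optional[str] = None) -> "Genealogy":
        """Return a copy with all node times multiplied by ``factor``."""

        def copy(node: GenealogyNode) -> GenealogyNode:
            new = GenealogyNode(time=node.time * factor, label=node.label)
            for child in node.children:
                new.add_child(copy(child))
            return new

        return Genealogy(copy(self.root), units=units or self.units)

    # ------------------------------------------------------------------ #
    # Newick I/O (branch lengths are time differences; a bracketed
    # comment on the tree statement records the time units)
    # ------------------------------------------------------------------ #
    def to_newick(self) -> str:
        def fmt(node: GenealogyNode) -> str:
            if node.is_tip:
                body = node.label
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is None:
                return body
            return f"{body}:{node.parent.time - node.time:.10g}"

        return f"[&units={self.units}]{fmt(self.root)};"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(
        cls,
        source: str,
        tip_ages: Optional[dict[str, float]] = None,
        units: Optional[str] = None,
    ) -> "Genealogy":
        """Parse a Newick string or file path.

        Node times are reconstructed from branch lengths plus the declared
        tip ages (default: all tips contemporaneous at 0).  Inconsistent
        branch lengths (the same internal node implying two different
        times via its two children beyond tolerance) are rejected.
        """
        text = source
        if "(" not in source:  # looks like a path
            with open(source) as fh:
                text = fh.read()
        text = text.strip()
        if text.startswith("[&units="):
            end = text.index("]")
            declared = text[8:end]
            text = text[end + 1 :]
            if units is None:
                units = declared
        units = units or "years"
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        tip_ages = tip_ages or {}

        def convert(dnode) -> tuple[GenealogyNode, float]:
            """Return (node, time) bottom-up."""
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else dnode.label
                age = float(tip_ages.get(label, 0.0))
                return GenealogyNode(time=age, label=label), age
            child_nodes = []
            implied_times = []
            for dchild in dnode.child_nodes():
                cnode, ctime = convert(dchild)
                blen = dchild.edge.length or 0.0
                child_nodes.append(cnode)
                implied_times.append(ctime + blen)
            t = implied_times[0]
            scale = max(abs(x) for x in implied_times) or 1.0
            for other in implied_times[1:]:
                if abs(other - t) > _AGE_RTOL * scale + 1e-9:
                    raise ValueError(
                        f"non-ultrametric branch lengths: node times {implied_times} disagree"
                    )
            node = GenealogyNode(time=t)
            for cnode in child_nodes:
                node.add_child(cnode)
            return node, t

        root, _ = convert(tree.seed_node)
        return cls(root, units=units)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Genealogy n_tips={self.n_tips} tmrca={self.tmrca:.6g} units={self.units}>"
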