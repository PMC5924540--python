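"""Collapse aligned sequences into haplotypes over their variable sites.

Sequences identical across the variable positions of an alignment are
grouped into one haplotype, mirroring the DnaSP-style workflow of feeding
all variable nucleotide sites into a haplotype caller.  Sequences with
missing data at a variable position are assigned to an existing haplotype
only when compatible with exactly one; otherwise they stand alone and are
flagged ambiguous (the rule is ours and is logged — programs differ here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import AlignedSequenceSet, MISSING, variable_sites

logger = logging.getLogger(__name__)

__all__ = ["Haplotype", "HaplotypeTable", "collapse_haplotypes"]


@dataclass
class Haplotype:
    haplotype_id: str
    sites: str              # states over the variable positions
    members: list[str]
    ambiguous: bool = False

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    """Haplotypes over the variable positions of an alignment.

    Invariants: member lists partition the input ids; counts sum to n;
    no two haplotypes share an identical variable-site string (ambiguous
    singletons may be *compatible* with several, which is why they were
    not merged).
    """

    haplotypes: list[Haplotype]
    variable_positions: list[int]
    n_sequences: int
    populations: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> list[int]:
        return [h.count for h in self.haplotypes]

    def membership(self) -> dict[str, str]:
        """Map sequence id -> haplotype id."""
        out = {}
        for h in self.haplotypes:
            for m in h.members:
                out[m] = h.haplotype_id
        return out

    def by_id(self, haplotype_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.haplotype_id == haplotype_id:
                return h
        raise KeyError(f"unknown haplotype {haplotype_id!r}")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("haplotype_id\tcount\tambiguous\tmembers\tsites\n")
            for h in self.haplotypes:
                fh.write(
                    f"{h.haplotype_id}\t{h.count}\t{int(h.ambiguous)}\t"
                    f"{','.join(h.members)}\t{h.sites}\n"
                )


def _compatible(a: str, b: str) -> bool:
    """True if strings agree at every position where both are observed."""
    return all(x == y or x in MISSING or y in MISSING for x, y in zip(a, b))


def collapse_haplotypes(
    aln: AlignedSequenceSet,
    missing_policy: str = "exclude-missing",
    populations: dict[str, str] | None = None,
) -> HaplotypeTable:
    """Group sequences sharing a variable-site string into haplotypes.

    Haplotype ids ``H1, H2, ...`` are assigned in order of first
    occurrence, so the result is deterministic for a given input order.
    """
    positions = variable_sites(aln, missing_policy)
    # map original coordinates back to current columns via provenance
    src = {int(c): j for j, c in enumerate(aln.source_columns)}
    cols = [src[p] for p in positions]

    haps: list[Haplotype] = []
    for i, sid in enumerate(aln.ids):
        s = "".join(aln.matrix[i, cols])
        if any(c in MISSING for c in s):
            matches = [h for h in haps if not h.ambiguous and _compatible(s, h.sites)]
            if len(matches) == 1:
                matches[0].members.append(sid)
            else:
                logger.info(
                    "sequence %s has missing data at variable sites and is "
                    "compatible with %d haplotypes; kept separate (ambiguous)",
                    sid, len(matches),
                )
                haps.append(Haplotype(f"H{len(haps) + 1}", s, [sid], ambiguous=True))
            continue
        for h in haps:
            if not h.ambiguous and h.sites == s:
                h.members.append(sid)
                break
        else:
            haps.append(Haplotype(f"H{len(haps) + 1}", s, [sid]))

    return HaplotypeTable(
        haplotypes=haps,
        variable_positions=positions,
        n_sequences=aln.n_sequences,
        populations=dict(populations or {}),
    )
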