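"""Aligned sequence sets: I/O, missing-data handling, variable sites.

Conventions
-----------
* Alphabet ``{A, C, G, T, N, -}``; the gap character and ``N`` are both
  treated as *missing* for variable-site and distance purposes (small
  mtDNA indels are not modelled).  IUPAC ambiguity codes are accepted on
  read and recoded to ``N`` (the number recoded is logged).
* Column coordinates are 0-based half-open internally; reports add 1.
* Every sequence carries a tip age in years BP (0 for modern samples).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedSequenceSet",
    "read_alignment",
    "write_alignment",
    "remove_missing_columns",
    "variable_sites",
    "MISSING",
]

BASES = ("A", "C", "G", "T")
MISSING = ("N", "-")
_VALID = set(BASES) | set(MISSING)


@dataclass
class AlignedSequenceSet:
    """A gapped multiple alignment with per-sequence sampling ages.

    Attributes
    ----------
    ids
        Unique sequence labels, in input order.
    matrix
        ``(n, L)`` array of single characters over ``{A,C,G,T,N,-}``.
    ages
        Tip age in years BP per sequence (0 = modern).
    partitions
        Optional named, non-overlapping column ranges ``name -> (start, stop)``
        (0-based half-open), e.g. ``{"coding": (0, 4054), "dloop": (4054, 4709)}``.
    source_columns
        Original column index of each current column; identity for a
        freshly read alignment, a provenance map after column filtering.
    """

    ids: list[str]
    matrix: np.ndarray
    ages: np.ndarray
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)
    source_columns: Optional[np.ndarray] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids and matrix row count differ")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.shape != (len(self.ids),):
            raise ValueError("ages must have one entry per sequence")
        if np.any(self.ages < 0):
            raise ValueError("tip ages must be >= 0")
        if self.source_columns is None:
            self.source_columns = np.arange(self.matrix.shape[1])
        self._check_partitions()

    def _check_partitions(self) -> None:
        L = self.n_sites
        spans = sorted(self.partitions.values())
        for (s, e) in spans:
            if not (0 <= s < e <= L):
                raise ValueError(f"partition ({s}, {e}) outside [0, {L})")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("partitions overlap")

    # ------------------------------------------------------------------ #
    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def index_of(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def sequence(self, seq_id: str) -> str:
        return "".join(self.matrix[self.index_of(seq_id)])

    def age_of(self, seq_id: str) -> float:
        return float(self.ages[self.index_of(seq_id)])

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask of missing cells (N or gap)."""
        return (self.matrix == "N") | (self.matrix == "-")

    def subset(self, ids: Sequence[str]) -> "AlignedSequenceSet":
        idx = [self.index_of(i) for i in ids]
        return AlignedSequenceSet(
            ids=list(ids),
            matrix=self.matrix[idx].copy(),
            ages=self.ages[idx].copy(),
            partitions=dict(self.partitions),
            source_columns=self.source_columns.copy(),
        )

    def drop(self, seq_id: str) -> "AlignedSequenceSet":
        keep = [i for i in self.ids if i != seq_id]
        if len(keep) == len(self.ids):
            raise KeyError(f"unknown sequence id {seq_id!r}")
        return self.subset(keep)

    def restrict_columns(self, columns: np.ndarray) -> "AlignedSequenceSet":
        columns = np.asarray(columns, dtype=int)
        return AlignedSequenceSet(
            ids=list(self.ids),
            matrix=self.matrix[:, columns].copy(),
            ages=self.ages.copy(),
            partitions={},  # partition frames do not survive column filtering
            source_columns=self.source_columns[columns].copy(),
        )

    def partition(self, name: str) -> "AlignedSequenceSet":
        s, e = self.partitions[name]
        sub = self.restrict_columns(np.arange(s, e))
        sub.partitions = {name: (0, e - s)}
        return sub


# ---------------------------------------------------------------------- #
# I/O
# ---------------------------------------------------------------------- #
def read_dates(path) -> dict[str, float]:
    """Read a two-column TSV ``id <TAB> age_years_BP``."""
    ages: dict[str, float] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"malformed dates row: {row!r}")
            try:
                age = float(row[1])
            except ValueError:
                raise ValueError(f"unparseable age {row[1]!r} for id {row[0]!r}") from None
            ages[row[0]] = age
    return ages


def read_alignment(
    fasta_path,
    dates_path=None,
    partitions: Optional[dict[str, tuple[int, int]]] = None,
) -> AlignedSequenceSet:
    """Read an aligned multi-FASTA, optionally with a tip-date table.

    Sequences are uppercased; IUPAC ambiguity codes are recoded to ``N``
    with a logged count.  Ids in the dates file must be a subset of the
    FASTA ids; sequences without a date default to 0 years BP.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in FASTA")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    matrix = np.array([list(str(r.seq).upper()) for r in records], dtype="U1")
    ambiguous = ~np.isin(matrix, list(_VALID))
    n_amb = int(ambiguous.sum())
    if n_amb:
        logger.info("recoded %d ambiguous/unknown characters to N", n_amb)
        matrix[ambiguous] = "N"

    ages = np.zeros(len(ids))
    if dates_path is not None:
        dates = read_dates(dates_path)
        unknown = set(dates) - set(ids)
        if unknown:
            raise ValueError(f"dates file ids absent from FASTA: {sorted(unknown)}")
        for i, sid in enumerate(ids):
            ages[i] = dates.get(sid, 0.0)

    return AlignedSequenceSet(ids=ids, matrix=matrix, ages=ages, partitions=partitions or {})


def write_alignment(aln: AlignedSequenceSet, fasta_path, dates_path=None) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=sid, description="")
        for sid, row in zip(aln.ids, aln.matrix)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if dates_path is not None:
        with open(dates_path, "w") as fh:
            for sid, age in zip(aln.ids, aln.ages):
                fh.write(f"{sid}\t{age:g}\n")


# ---------------------------------------------------------------------- #
# column operations
# ---------------------------------------------------------------------- #
def remove_missing_columns(aln: AlignedSequenceSet) -> AlignedSequenceSet:
    """Delete every column with at least one missing cell in any row.

    This is the conservative treatment for alignments mixing ancient
    (gappy) and modern sequences: analyses then run on positions observed
    in *all* individuals.  The returned alignment's ``source_columns``
    maps surviving columns back to input coordinates.
    """
    keep = ~aln.missing_mask().any(axis=0)
    if not keep.any():
        logger.warning("all columns contain missing data; returning empty alignment")
    return aln.restrict_columns(np.nonzero(keep)[0])


def variable_sites(aln: AlignedSequenceSet, missing_policy: str = "exclude-missing") -> list[int]:
    """Columns with >= 2 distinct non-missing bases (0-based, sorted).

    ``missing_policy``:

    * ``"exclude-missing"`` (default): missing cells are simply ignored
      when counting distinct bases in a column.
    * ``"strict"``: columns containing any missing data are first removed
      (positions are then reported in the *original* coordinate frame via
      the provenance map).
    """
    if missing_policy == "strict":
        aln = remove_missing_columns(aln)
    elif missing_policy != "exclude-missing":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    positions = []
    miss = aln.missing_mask()
    for j in range(aln.n_sites):
        col = aln.matrix[~miss[:, j], j]
        if len(set(col.tolist())) >= 2:
            positions.append(int(aln.source_columns[j]))
    return positions


def count_segregating_sites(aln: AlignedSequenceSet, missing_policy: str = "exclude-missing") -> int:
    return len(variable_sites(aln, missing_policy))
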