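"""Pedigree algebra.

Builds the numerator relationship matrix (NRM, classically denoted A) for a
set of animals from parentage records, with unknown parents treated as
unrelated, non-inbred founders.  The diagonal of A is 1 + F (F = pedigree
inbreeding coefficient) and off-diagonals are twice the kinship, so
parent-offspring pairs from unrelated parents score 0.5, full sibs 0.5 and
half sibs 0.25.

Also provides relatedness diagnostics for cross-validation designs: for a
grouping of animals, each animal's maximum relationship to members of its
own group (a_max within) and to members of all other groups (a_max between),
summarised per group as mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "Pedigree",
    "PedigreeError",
    "RelationshipMatrix",
    "AmaxReport",
    "build_nrm",
    "subset_relationships",
    "amax_report",
]

#: sentinel for an unknown parent in CSV files
UNKNOWN = 0


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate ids...)."""


def _is_unknown(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value == 0 or value == "0"


@dataclass
class Pedigree:
    """Parentage records: one row per animal with sire, dam and birth year.

    ``frame`` holds columns ``animal``, ``sire``, ``dam``, ``birth_year``
    (optionally ``sex``); 0 / NaN mark an unknown parent.  Records are
    validated (unique ids, parents recorded before use, no cycles) on
    construction.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal", "sire", "dam", "birth_year"}
        missing = required - set(self.frame.columns)
        if missing:
            raise PedigreeError(f"pedigree frame missing columns {sorted(missing)}")
        animals = self.frame["animal"]
        if animals.duplicated().any():
            dupes = animals[animals.duplicated()].tolist()
            raise PedigreeError(f"duplicate animal ids: {dupes[:5]}")
        self._index = {a: i for i, a in enumerate(animals)}
        self._topo = self._topological_order()

    # -- structure ---------------------------------------------------------

    def _topological_order(self) -> list[int]:
        """Kahn peeling; raises PedigreeError naming a cycle member."""
        n = len(self.frame)
        parents = []
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i, (s, d) in enumerate(zip(self.frame["sire"], self.frame["dam"])):
            row = []
            for p in (s, d):
                if not _is_unknown(p):
                    if p not in self._index:
                        # parent not recorded as an animal: treat as unknown founder
                        continue
                    j = self._index[p]
                    row.append(j)
                    children[j].append(i)
                    indeg[i] += 1
            parents.append(row)
        order: list[int] = [i for i in range(n) if indeg[i] == 0]
        head = 0
        while head < len(order):
            i = order[head]
            head += 1
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(order) < n:
            stuck = [self.frame["animal"].iloc[i] for i in range(n) if indeg[i] > 0]
            raise PedigreeError(f"pedigree contains a cycle involving animals {stuck[:5]}")
        return order

    @property
    def animals(self) -> np.ndarray:
        return self.frame["animal"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, animal) -> bool:
        return animal in self._index

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(topo_order, sire_idx, dam_idx) with -1 for unknown, indices into
        topologically sorted order."""
        order = np.asarray(self._topo, dtype=np.int64)
        pos_in_topo = np.empty(len(order), dtype=np.int64)
        pos_in_topo[order] = np.arange(len(order))
        sires = np.full(len(order), -1, dtype=np.int64)
        dams = np.full(len(order), -1, dtype=np.int64)
        s_col = self.frame["sire"].to_numpy()
        d_col = self.frame["dam"].to_numpy()
        for rank, i in enumerate(order):
            s, d = s_col[i], d_col[i]
            if not _is_unknown(s) and s in self._index:
                sires[rank] = pos_in_topo[self._index[s]]
            if not _is_unknown(d) and d in self._index:
                dams[rank] = pos_in_topo[self._index[d]]
        return order, sires, dams

    def ancestor_closure(self, ids: Iterable) -> list:
        """All requested animals plus every known ancestor, pedigree order."""
        want = set()
        stack = [a for a in ids]
        s_col = self.frame["sire"].to_numpy()
        d_col = self.frame["dam"].to_numpy()
        while stack:
            a = stack.pop()
            if a in want or a not in self._index:
                continue
            want.add(a)
            i = self._index[a]
            for p in (s_col[i], d_col[i]):
                if not _is_unknown(p):
                    stack.append(p)
        return [a for a in self.frame["animal"] if a in want]

    def parents_of(self, animal):
        """(sire, dam) with None for unknown."""
        i = self._index[animal]
        s = self.frame["sire"].iloc[i]
        d = self.frame["dam"].iloc[i]
        return (None if _is_unknown(s) else s, None if _is_unknown(d) else d)

    def subset(self, ids: Sequence) -> "Pedigree":
        keep = set(ids)
        sub = self.frame[self.frame["animal"].isin(keep)].copy()
        return Pedigree(sub.reset_index(drop=True))

    # -- io ----------------------------------------------------------------

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        frame = pd.read_csv(path)
        return cls(frame)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        for col in ("sire", "dam"):
            out[col] = [UNKNOWN if _is_unknown(v) else v for v in out[col]]
        out.to_csv(path, index=False)


@njit(cache=True)
def _tabular_nrm(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Tabular-method recursion over a topologically sorted pedigree."""
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s = sire[i]
        d = dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = a
            A[j, i] = a
    return A


@dataclass
class RelationshipMatrix:
    """Symmetric matrix of additive relationship coefficients.

    ``ids`` orders the rows/columns; ``values`` is dense float64.
    """

    ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape inconsistent with id list")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def loc(self, i, j) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def inbreeding(self) -> pd.Series:
        return pd.Series(np.diag(self.values) - 1.0, index=self.ids, name="F")

    def indices_of(self, ids: Sequence) -> np.ndarray:
        try:
            return np.asarray([self._index[a] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown animal id {exc.args[0]!r} in relationship matrix") from None

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "RelationshipMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=frame.index.to_numpy(), values=frame.to_numpy())


def build_nrm(pedigree: Pedigree, ids: Sequence | None = None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    When ``ids`` is given, the recursion runs over the ancestor closure of
    those animals only (the classical "genotyped animals and all their known
    ancestors" restriction) and the returned matrix is subset to ``ids`` in
    the requested order.
    """
    if ids is not None:
        closure = pedigree.ancestor_closure(ids)
        ped = pedigree.subset(closure)
    else:
        ped = pedigree
    order, sire, dam = ped.parent_indices()
    A = _tabular_nrm(sire, dam)
    topo_ids = ped.frame["animal"].to_numpy()[order]
    full = RelationshipMatrix(ids=topo_ids, values=A)
    if ids is None:
        # return in original pedigree order
        return subset_relationships(full, pedigree.animals if ped is pedigree else ped.animals)
    return subset_relationships(full, ids)


def subset_relationships(A: RelationshipMatrix, ids: Sequence) -> RelationshipMatrix:
    """Principal submatrix of A in the requested id order."""
    idx = A.indices_of(ids)
    return RelationshipMatrix(ids=np.asarray(ids), values=A.values[np.ix_(idx, idx)])


@dataclass
class AmaxReport:
    """Within/between-group maximum-relationship diagnostics.

    ``per_animal`` has one row per animal (a_max_within is NaN for members of
    singleton groups); ``per_group`` carries group size and mean +/- SD of
    both a_max statistics, computed over group members with a defined value.
    """

    per_animal: pd.DataFrame
    per_group: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.per_group.to_csv(path, sep="\t", index=False)


def amax_report(A: RelationshipMatrix, assignment) -> AmaxReport:
    """Per-animal and per-group a_max within and between CV groups.

    ``assignment`` is a mapping animal id -> group label (or a
    ``ClusterAssignment``).  a_max uses off-diagonal relationships only: the
    self-relationship (>= 1) is never a candidate.
    """
    groups = getattr(assignment, "as_mapping", lambda: assignment)()
    ids = list(A.ids)
    missing = [a for a in ids if a not in groups]
    if missing:
        raise KeyError(f"assignment does not cover animals {missing[:5]}")
    labels = np.asarray([groups[a] for a in ids])
    V = A.values.copy()
    np.fill_diagonal(V, -np.inf)
    rows = []
    for i, a in enumerate(ids):
        same = labels == labels[i]
        same[i] = False
        within = float(V[i, same].max()) if same.any() else np.nan
        other = ~(labels == labels[i])
        between = float(V[i, other].max()) if other.any() else np.nan
        rows.append((a, labels[i], within, between))
    per_animal = pd.DataFrame(rows, columns=["animal", "group", "a_max_within", "a_max_between"])
    per_group = (
        per_animal.groupby("group")
        .agg(
            n=("animal", "size"),
            a_max_within_mean=("a_max_within", "mean"),
            a_max_within_sd=("a_max_within", "std"),
            a_max_between_mean=("a_max_between", "mean"),
            a_max_between_sd=("a_max_between", "std"),
        )
        .reset_index()
    )
    return AmaxReport(per_animal=per_animal, per_group=per_group)
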