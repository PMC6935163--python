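"""Pedigree handling for breeding populations.

Provides the numerator relationship matrix A via the tabular method, pedigree
topological ordering, inbreeding coefficients F = a_ii - 1, and the status
number Ns = 0.5 / (group coancestry), the effective-population-size measure
customarily reported for tree-breeding training populations.

Individuals are referenced by string labels; an unknown parent is the
sentinel :data:`UNKNOWN` (the literal ``"0"``, matching the common pedigree
CSV convention where 0 or an empty field means unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = "0"

_UNKNOWN_TOKENS = {"", "0", "0.0", "na", "nan", "none", "unknown", ".", "*"}


class PedigreeError(ValueError):
    """Raised for structural pedigree problems (cycles, duplicates, bad refs)."""


def _norm_label(x) -> str:
    """Normalize a parent/id cell to a string label; unknown tokens -> UNKNOWN."""
    if x is None:
        return UNKNOWN
    if isinstance(x, float) and np.isnan(x):
        return UNKNOWN
    s = str(x).strip()
    if s.lower() in _UNKNOWN_TOKENS:
        return UNKNOWN
    # integer-valued floats from pandas CSV parsing ("12.0" -> "12")
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


@dataclass
class Pedigree:
    """An ordered pedigree: one (id, sire, dam) record per individual.

    ``sorted`` is True when every parent precedes its offspring (generation
    order), which the tabular method requires.
    """

    records: list[tuple[str, str, str]]
    sorted: bool = False

    def __post_init__(self) -> None:
        self.records = [
            (_norm_label(i), _norm_label(s), _norm_label(d)) for i, s, d in self.records
        ]
        ids = [r[0] for r in self.records]
        if UNKNOWN in ids:
            raise PedigreeError(f"individual id may not be the unknown sentinel {UNKNOWN!r}")
        dup = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
        if dup:
            raise PedigreeError(f"duplicate individual ids: {sorted(dup)}")
        self._add_missing_founders()

    def _add_missing_founders(self) -> None:
        known = {r[0] for r in self.records}
        extra: list[str] = []
        for _, s, d in self.records:
            for p in (s, d):
                if p != UNKNOWN and p not in known:
                    known.add(p)
                    extra.append(p)
        if extra:
            logger.warning(
                "adding %d individuals appearing only as parents as founders: %s%s",
                len(extra), extra[:10], "..." if len(extra) > 10 else "",
            )
            # founders go first so an already-ordered pedigree stays ordered
            self.records = [(p, UNKNOWN, UNKNOWN) for p in extra] + self.records

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def parents(self) -> dict[str, tuple[str, str]]:
        return {i: (s, d) for i, s, d in self.records}

    def founders(self) -> list[str]:
        return [i for i, s, d in self.records if s == UNKNOWN and d == UNKNOWN]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["id", "sire", "dam"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "Pedigree":
        return cls(list(df[["id", "sire", "dam"]].itertuples(index=False, name=None)), **kw)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and set(self.records) == set(other.records)


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Return a generation-ordered copy (parents before offspring).

    Kahn's algorithm, stable with respect to the input order, so a pedigree
    that is already ordered comes back in the identical order. Raises
    :class:`PedigreeError` naming an individual on a cycle.
    """
    parents = ped.parents
    ids = ped.ids
    pos = {i: k for k, i in enumerate(ids)}
    n_unplaced_parents = {
        i: sum(1 for p in parents[i] if p != UNKNOWN) for i in ids
    }
    children: dict[str, list[str]] = {i: [] for i in ids}
    for i, (s, d) in parents.items():
        for p in {s, d} - {UNKNOWN}:
            children[p].append(i)

    ready = sorted((i for i in ids if n_unplaced_parents[i] == 0), key=pos.get)
    out: list[str] = []
    import heapq

    heap = [pos[i] for i in ready]
    heapq.heapify(heap)
    while heap:
        i = ids[heapq.heappop(heap)]
        out.append(i)
        # selfed offspring have the same parent twice; decrement once per slot
        seen: set[str] = set()
        for c in children[i]:
            dec = sum(1 for p in parents[c] if p == i) if c not in seen else 0
            seen.add(c)
            if dec:
                n_unplaced_parents[c] -= dec
                if n_unplaced_parents[c] == 0:
                    heapq.heappush(heap, pos[c])
    if len(out) != len(ids):
        stuck = next(i for i in ids if i not in set(out))
        raise PedigreeError(f"pedigree contains a cycle involving {stuck!r}")
    recmap = {i: (i, *parents[i]) for i in ids}
    return Pedigree([recmap[i] for i in out], sorted=True)


def is_sorted(ped: Pedigree) -> bool:
    pos = {i: k for k, i in enumerate(ped.ids)}
    for k, (i, s, d) in enumerate(ped.records):
        for p in (s, d):
            if p != UNKNOWN and pos[p] >= k:
                return False
    return True


def build_A(ped: Pedigree) -> pd.DataFrame:
    """Numerator relationship matrix A by the tabular method.

    For individuals ordered parents-first:

        a_ii = 1 + 0.5 * a_{sire(i), dam(i)}      (0 if either parent unknown)
        a_ij = 0.5 * (a_{j, sire(i)} + a_{j, dam(i)})   for j earlier than i

    Returns a labelled symmetric DataFrame with diagonal 1 + F.
    """
    if not (ped.sorted and is_sorted(ped)):
        raise PedigreeError("pedigree is not generation-ordered; call sort_pedigree() first")
    ids = ped.ids
    n = len(ids)
    idx = {i: k for k, i in enumerate(ids)}
    A = np.zeros((n, n))
    for k, (_, s, d) in enumerate(ped.records):
        si = idx.get(s, -1) if s != UNKNOWN else -1
        di = idx.get(d, -1) if d != UNKNOWN else -1
        row = np.zeros(k)
        if si >= 0:
            row += A[si, :k]
        if di >= 0:
            row += A[di, :k]
        A[k, :k] = 0.5 * row
        A[:k, k] = A[k, :k]
        A[k, k] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return pd.DataFrame(A, index=ids, columns=ids)


def inbreeding(A: pd.DataFrame) -> pd.Series:
    """Inbreeding coefficients F_i = a_ii - 1 from a numerator relationship matrix."""
    return pd.Series(np.diag(A.values) - 1.0, index=A.index, name="F")


def status_number(ped: Pedigree, group: set[str] | list[str] | None = None,
                  A: pd.DataFrame | None = None) -> float:
    """Status number Ns = 0.5 / group coancestry.

    The group coancestry Theta is the mean coancestry f_ij = a_ij / 2 over all
    ordered pairs (i, j) in the group including i = j. For n unrelated,
    non-inbred individuals Theta = 0.5/n so Ns = n.
    """
    if A is None:
        A = build_A(ped if ped.sorted and is_sorted(ped) else sort_pedigree(ped))
    if group is None:
        group = list(A.index)
    group = list(group)
    if not group:
        raise PedigreeError("status_number: group is empty")
    missing = set(group) - set(A.index)
    if missing:
        raise PedigreeError(f"status_number: group members not in pedigree: {sorted(missing)}")
    sub = A.loc[group, group].values
    theta = sub.mean() / 2.0
    return 0.5 / theta
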