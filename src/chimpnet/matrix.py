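"""Labeled dyadic matrices.

A :class:`DyadMatrix` is the in-memory container for every behavioral network in this
package: an ``n x n`` array of nonnegative rates (minutes/hour or events/hour) over a
fixed, ordered list of individual IDs. The diagonal is undefined by construction (an
individual has no dyadic rate with itself) and off-diagonal cells may be *missing* —
encoded as ``NaN`` — when a dyad was never observed in the relevant denominator state.
Missing is deliberately distinct from zero: a zero rate is an observed absence, a
missing cell carries no information and is excluded pairwise downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass
class DyadMatrix:
    """Square labeled matrix over named individuals.

    Parameters
    ----------
    ids:
        Ordered node labels; row/column ``i`` refers to ``ids[i]``.
    values:
        Float array of shape ``(n, n)``; ``NaN`` marks missing cells. The diagonal is
        forced to ``NaN`` on construction.
    label:
        Behavior the matrix measures (e.g. ``"proximity"``, ``"grooming:mutual"``).
    directed:
        Whether cell ``(i, j)`` may legitimately differ from ``(j, i)``.
    """

    ids: list[str]
    values: np.ndarray
    label: str = ""
    directed: bool = True
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float).copy()
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids")
        np.fill_diagonal(self.values, np.nan)
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("negative cell values")
        self._index = {name: i for i, name in enumerate(self.ids)}

    # -- basic access ------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, a: str, b: str) -> float:
        """Cell value for the ordered dyad (a, b); NaN if missing."""
        return float(self.values[self._index[a], self._index[b]])

    def set(self, a: str, b: str, value: float) -> None:
        if a == b:
            raise ValueError("diagonal cells are undefined")
        self.values[self._index[a], self._index[b]] = value

    def offdiag_mask(self) -> np.ndarray:
        """Boolean mask of off-diagonal cells."""
        return ~np.eye(self.n, dtype=bool)

    def present_mask(self) -> np.ndarray:
        """Boolean mask of nonmissing (off-diagonal) cells."""
        return ~np.isnan(self.values) & self.offdiag_mask()

    def offdiag_values(self) -> np.ndarray:
        """1-D array of the nonmissing off-diagonal values (row-major order)."""
        return self.values[self.present_mask()]

    def copy(self) -> "DyadMatrix":
        return DyadMatrix(list(self.ids), self.values.copy(), self.label, self.directed)

    def is_symmetric(self) -> bool:
        a, b = self.values, self.values.T
        both = ~np.isnan(a) & ~np.isnan(b)
        same_nan = np.isnan(a) == np.isnan(b)
        return bool(np.all(same_nan) and np.allclose(a[both], b[both]))

    def reorder(self, ids: Sequence[str]) -> "DyadMatrix":
        """Return a copy with rows/columns arranged in the given id order."""
        if sorted(ids) != sorted(self.ids):
            raise ValueError("reorder ids must be a permutation of matrix ids")
        idx = [self._index[i] for i in ids]
        return DyadMatrix(list(ids), self.values[np.ix_(idx, idx)], self.label, self.directed)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def empty(cls, ids: Iterable[str], label: str = "", directed: bool = True) -> "DyadMatrix":
        """All-missing matrix over the given ids."""
        ids = list(ids)
        return cls(ids, np.full((len(ids), len(ids)), np.nan), label, directed)

    def __eq__(self, other: object) -> bool:  # value equality incl. NaN pattern
        if not isinstance(other, DyadMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.values.shape == other.values.shape
            and bool(
                np.all(
                    (np.isnan(self.values) & np.isnan(other.values))
                    | (self.values == other.values)
                )
            )
        )
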