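"""Network construction, proximity-bond classification and degree centrality.

Weighted directed behavioral matrices are transformed three ways:

* **dichotomize** — any positive rate becomes a tie (1), zero stays absent (0);
* **symmetrize_or** — an undirected tie is present if either directed cell has one;
* **classify_bonds** — each ordered proximity dyad is classed against thresholds at
  the mean +/- half a standard deviation of the directed off-diagonal values:
  at or above ``mu + sigma/2`` in both directions = *preferred reciprocated*; at or
  above in one direction only = *preferred non-reciprocated*; at or below
  ``mu - sigma/2`` = *non-preferred*; at or above the upper threshold regardless of
  the partner's value = *preferred partner* (the reciprocation-agnostic network used
  for centrality).

Centrality is normalized degree — the mean of a node's nonmissing row (out) or column
(in) cells, which on a binary network is the proportion of potential partners with a
tie. Degree is preferred to eigenvector-style measures here because only part of the
community is sampled and degree is robust to partial sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import DyadMatrix

__all__ = [
    "BondThresholds",
    "BondNetwork",
    "build_matrix",
    "dichotomize",
    "symmetrize_or",
    "classify_bonds",
    "degree_centrality",
    "mean_degree",
    "similarity_matrix",
    "DegenerateThresholdError",
]

BOND_CLASSES = (
    "preferred_reciprocated",
    "preferred_nonreciprocated",
    "non_preferred",
    "preferred_partner",
)


class DegenerateThresholdError(ValueError):
    """All proximity values identical: the half-SD band collapses to a point."""


@dataclass(frozen=True)
class BondThresholds:
    """Half-SD band around the mean of the directed proximity values."""

    mean: float
    sd: float

    @property
    def upper(self) -> float:
        return self.mean + self.sd / 2.0

    @property
    def lower(self) -> float:
        return self.mean - self.sd / 2.0


@dataclass
class BondNetwork:
    """The four binary proximity-bond networks plus the thresholds that made them."""

    preferred_reciprocated: DyadMatrix  # symmetric
    preferred_nonreciprocated: DyadMatrix  # directed
    non_preferred: DyadMatrix  # directed
    preferred_partner: DyadMatrix  # directed, reciprocation-agnostic
    thresholds: BondThresholds

    def __getitem__(self, name: str) -> DyadMatrix:
        if name not in BOND_CLASSES:
            raise KeyError(name)
        return getattr(self, name)


def build_matrix(
    table: pd.DataFrame, ids: list[str], label: str = "", directed: bool = True
) -> DyadMatrix:
    """Assemble a DyadMatrix from a long-format (a, b, value) table.

    Cells not mentioned stay missing; duplicate dyad rows are an error.
    """
    m = DyadMatrix.empty(ids, label=label, directed=directed)
    seen: set[tuple[str, str]] = set()
    known = set(ids)
    for row in table.itertuples(index=False):
        a, b, v = str(row.a), str(row.b), float(row.value)
        if a not in known or b not in known:
            raise ValueError(f"dyad ({a}, {b}) references unknown id")
        if (a, b) in seen:
            raise ValueError(f"duplicate dyad row ({a}, {b})")
        seen.add((a, b))
        m.set(a, b, v)
    return m


def dichotomize(m: DyadMatrix) -> DyadMatrix:
    """Any value over zero scores 1 (tie present), zero scores 0; missing stays missing."""
    out = m.copy()
    present = m.present_mask()
    out.values[present] = (m.values[present] > 0).astype(float)
    out.label = f"{m.label}:binary" if m.label and not m.label.endswith(":binary") else m.label
    return out


def symmetrize_or(m: DyadMatrix) -> DyadMatrix:
    """Undirected tie present if either directed cell is 1.

    A single observed 1 dominates a missing opposite cell; the result is missing only
    where both directed cells are missing.
    """
    vals = m.values
    a = np.nan_to_num(vals, nan=0.0)
    sym = np.maximum(a, a.T)
    both_missing = np.isnan(vals) & np.isnan(vals.T)
    sym[both_missing] = np.nan
    out = DyadMatrix(list(m.ids), sym, label=m.label, directed=False)
    return out


def classify_bonds(proximity: DyadMatrix) -> tuple[BondNetwork, BondThresholds]:
    """Classify every ordered dyad of the proximity matrix into bond classes.

    Thresholds are the mean +/- half SD (population SD) of the directed nonmissing
    off-diagonal proximity values. Threshold comparisons are inclusive ("equal or
    above" / "equal or below"). Raises :class:`DegenerateThresholdError` when the SD
    is zero, since then every dyad would sit at both thresholds simultaneously.
    """
    vals = proximity.offdiag_values()
    if vals.size < 2:
        raise ValueError("need at least 2 nonmissing off-diagonal proximity values")
    thr = BondThresholds(mean=float(np.mean(vals)), sd=float(np.std(vals)))
    if thr.sd == 0.0:
        raise DegenerateThresholdError(
            "all proximity values identical; half-SD thresholds are degenerate"
        )
    ids = list(proximity.ids)
    nets = {
        c: DyadMatrix.empty(ids, label=f"bond:{c}", directed=c != "preferred_reciprocated")
        for c in BOND_CLASSES
    }
    for a in ids:
        for b in ids:
            if a == b:
                continue
            v_ab = proximity.loc(a, b)
            v_ba = proximity.loc(b, a)
            if math.isnan(v_ab):
                continue
            pref = v_ab >= thr.upper
            recip = pref and not math.isnan(v_ba) and v_ba >= thr.upper
            nets["preferred_reciprocated"].set(a, b, 1.0 if recip else 0.0)
            nets["preferred_nonreciprocated"].set(a, b, 1.0 if pref and not recip else 0.0)
            nets["non_preferred"].set(a, b, 1.0 if v_ab <= thr.lower else 0.0)
            nets["preferred_partner"].set(a, b, 1.0 if pref else 0.0)
    bn = BondNetwork(thresholds=thr, **{c: nets[c] for c in BOND_CLASSES})
    return bn, thr


def degree_centrality(m: DyadMatrix, direction: str = "out") -> pd.Series:
    """Normalized degree: mean of a node's nonmissing row (out) or column (in) cells.

    On a binary network this is the proportion of potential partners with a tie.
    Normalization divides by the number of *observed* potential partners, so partial
    sampling does not deflate centrality. A node with an all-missing row/column gets
    a missing centrality.
    """
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    if m.n < 2:
        raise ValueError("need at least 2 nodes")
    vals = m.values if direction == "out" else m.values.T
    out = {}
    for i, node in enumerate(m.ids):
        row = vals[i]
        present = ~np.isnan(row)
        out[node] = float(np.mean(row[present])) if present.any() else math.nan
    return pd.Series(out, name=f"degree_{direction}")


def mean_degree(m: DyadMatrix) -> tuple[float, tuple[float, float]]:
    """Mean proportion of possible ties present in a binary symmetric network.

    Returns the mean of per-node normalized degrees as a percentage, with the
    (min, max) per-node range, also in percent.
    """
    vals = m.offdiag_values()
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("mean_degree expects a binary matrix")
    deg = degree_centrality(m, "out") * 100.0
    return float(deg.mean()), (float(deg.min()), float(deg.max()))


def similarity_matrix(attributes: pd.DataFrame, kind: str) -> DyadMatrix:
    """Binary symmetric attribute-similarity matrix over the table's individuals.

    kinds: ``kin`` (pair listed in each other's kin ids), ``age_class`` (age
    difference of 5 years or less, inclusive), ``sex`` (same sex), ``reproductive``
    (same oestrous status).
    """
    ids = [str(i) for i in attributes["id"]]
    at = attributes.set_index("id")
    m = DyadMatrix.empty(ids, label=f"similarity:{kind}", directed=False)
    kin_sets: dict[str, set[str]] = {}
    if kind == "kin":
        if "kin_ids" not in at.columns:
            raise ValueError("attribute table lacks 'kin_ids' column")
        kin_sets = {
            i: set(str(at.loc[i, "kin_ids"] or "").split(";")) - {""} for i in ids
        }
    for a in ids:
        for b in ids:
            if a == b:
                continue
            if kind == "kin":
                same = b in kin_sets[a]
            elif kind == "age_class":
                same = abs(float(at.loc[a, "age_years"]) - float(at.loc[b, "age_years"])) <= 5
            elif kind == "sex":
                same = at.loc[a, "sex"] == at.loc[b, "sex"]
            elif kind == "reproductive":
                same = bool(at.loc[a, "oestrous"]) == bool(at.loc[b, "oestrous"])
            else:
                raise ValueError(f"unknown similarity kind {kind!r}")
            m.set(a, b, 1.0 if same else 0.0)
    return m
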