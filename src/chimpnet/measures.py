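"""Dyadic behavioral rate measures from scan and event records.

All measures are focal-perspective ordered-dyad rates built from instantaneous scan
counts:

* **DA** — dyadic association: minutes per hour the focal A spends within 10 m of B,
  per hour spent in the same party: ``DA = ((P10 * 2) * 60) / (PSP * 2) = 60 * P10/PSP``
  where P10 and PSP count 2-minute scans. Bounded on [0, 60]. **DAK** and **DAR** are
  the same quantity restricted to maternal-kin dyads and to rows whose focal is an
  oestrous female, respectively.
* **GA** — dyadic grooming: minutes per hour grooming with B per hour within 10 m:
  ``GA = 60 * GR/P10``, computed separately for grooming given/received/mutual.
* **CA** — dyadic communication: gesture sequences (or call events) directed at B per
  hour within 10 m: ``CA = (C * 60) / (P10 * 2) = 30 * C/P10``.

Numerators and denominators condition on different states, so the three families are
mutually independent: DA reflects the choice to be close when co-present in a party,
GA and CA reflect behavior given closeness. A dyad with zero denominator carries no
information and yields *missing*, never zero.

The module also implements the event-processing rules: gesture-sequence assembly
(consecutive gestures by one signaller to one recipient, same goal and context, gaps
of at most 30 s), the 60% intentionality repertoire criterion, and Cohen's kappa for
inter-coder reliability of categorical labels.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .matrix import DyadMatrix
from .records import (
    CommEvent,
    GROOMING_CATEGORIES,
    PANT_GRUNT,
    PANT_HOOT_FUNCTIONS,
    SEQUENCE_FUNCTIONS,
    ScanRecord,
)

__all__ = [
    "DyadCounts",
    "GestureSequence",
    "count_dyads",
    "dyadic_association",
    "dyadic_grooming",
    "dyadic_communication",
    "assemble_sequences",
    "count_sequences",
    "combined_gesture_matrix",
    "repertoire_filter",
    "cohens_kappa",
    "association_matrix",
    "grooming_matrix",
    "communication_matrix",
    "measure_table",
]

SCAN_MINUTES = 2  # duration of the instantaneous subsample interval
MAX_SEQUENCE_GAP_S = 30.0  # inclusive


@dataclass
class DyadCounts:
    """Scan and sequence counts per ordered focal-perspective dyad.

    Only dyads whose first member was followed as a focal are populated; other
    ordered dyads are structurally missing downstream.
    """

    ids: tuple[str, ...]
    focal_ids: tuple[str, ...]
    p10: Counter = field(default_factory=Counter)  # (A, B) -> scans within 10 m
    psp: Counter = field(default_factory=Counter)  # (A, B) -> scans in same party
    grooming: dict[str, Counter] = field(
        default_factory=lambda: {c: Counter() for c in GROOMING_CATEGORIES}
    )
    sequences: dict[str, Counter] = field(default_factory=dict)  # category -> (A,B) -> n
    scans_per_focal: Counter = field(default_factory=Counter)

    def validate(self) -> None:
        for dyad, n10 in self.p10.items():
            if n10 > self.psp[dyad]:
                raise ValueError(f"P10 > PSP for dyad {dyad}")
        for cat, ctr in self.grooming.items():
            for dyad, g in ctr.items():
                if g > self.p10[dyad]:
                    raise ValueError(f"grooming[{cat}] > P10 for dyad {dyad}")


def count_dyads(scans: list[ScanRecord]) -> DyadCounts:
    """Tally P10/PSP/grooming scan counts over all ordered focal dyads."""
    focal_ids = tuple(sorted({s.focal_id for s in scans}))
    ids = tuple(
        sorted(set(focal_ids) | {b for s in scans for b in s.party_ids})
    )
    counts = DyadCounts(ids=ids, focal_ids=focal_ids)
    for scan in scans:
        a = scan.focal_id
        counts.scans_per_focal[a] += 1
        for b in scan.party_ids:
            counts.psp[(a, b)] += 1
        for b in scan.within10_ids:
            counts.p10[(a, b)] += 1
        if scan.grooming != "none":
            counts.grooming[scan.grooming][(a, scan.grooming_partner)] += 1
    counts.validate()
    return counts


def _rate(numerator: float, denominator: float, scale: float) -> float:
    """rate = scale * numerator / denominator; NaN when the denominator is zero."""
    if denominator <= 0:
        return math.nan
    return scale * numerator / denominator


def dyadic_association(
    counts: DyadCounts,
    a: str,
    b: str,
    *,
    kin_pairs: set[frozenset[str]] | None = None,
    oestrous_ids: set[str] | None = None,
) -> float:
    """DA for the ordered dyad (a, b), minutes within 10 m per hour in the same party.

    With ``kin_pairs`` given, this is DAK: defined only for maternal-kin dyads
    (missing otherwise). With ``oestrous_ids`` given, this is DAR: defined only when
    the focal ``a`` is an oestrous female.
    """
    if a == b:
        return math.nan
    if kin_pairs is not None and frozenset({a, b}) not in kin_pairs:
        return math.nan
    if oestrous_ids is not None and a not in oestrous_ids:
        return math.nan
    if a not in counts.focal_ids:
        return math.nan
    # ((P10 * 2) * 60) / (PSP * 2) == 60 * P10 / PSP
    return _rate(counts.p10[(a, b)], counts.psp[(a, b)], 60.0)


def dyadic_grooming(counts: DyadCounts, a: str, b: str, category: str) -> float:
    """GA for the ordered dyad (a, b): grooming minutes per hour within 10 m."""
    if category not in GROOMING_CATEGORIES:
        raise ValueError(f"unknown grooming category {category!r}")
    if a == b or a not in counts.focal_ids:
        return math.nan
    # ((GR * 2) * 60) / (P10 * 2) == 60 * GR / P10
    return _rate(counts.grooming[category][(a, b)], counts.p10[(a, b)], 60.0)


@dataclass
class GestureSequence:
    """Maximal run of gestures by one signaller to one recipient, one goal/context."""

    signaller_id: str
    recipient_id: str
    goal: str | None
    context: str | None
    category: str
    event_ids: list[str]
    start: "datetime"
    end: "datetime"

    def __len__(self) -> int:
        return len(self.event_ids)


def assemble_sequences(events: list[CommEvent]) -> list[GestureSequence]:
    """Greedy left-to-right grouping of gesture events into sequences.

    A new sequence starts whenever the signaller, recipient, goal or context changes,
    or the gap to the previous gesture exceeds 30 s (30 s exactly still joins). Only
    gesture-function events participate; calls are counted per event elsewhere. Every
    gesture event belongs to exactly one sequence.
    """
    gestures = [e for e in events if e.category in SEQUENCE_FUNCTIONS]
    by_signaller: dict[str, list[CommEvent]] = defaultdict(list)
    for e in gestures:
        by_signaller[e.signaller_id].append(e)
    sequences: list[GestureSequence] = []
    for signaller in sorted(by_signaller):
        stream = sorted(by_signaller[signaller], key=lambda e: (e.timestamp, e.event_id))
        current: list[CommEvent] = []
        for e in stream:
            recipient = min(e.recipient_ids)  # gesture events carry one recipient
            if current:
                prev = current[-1]
                gap = (e.timestamp - prev.timestamp).total_seconds()
                same = (
                    recipient == min(prev.recipient_ids)
                    and e.goal == prev.goal
                    and e.context == prev.context
                    and gap <= MAX_SEQUENCE_GAP_S
                )
                if not same:
                    sequences.append(_close_sequence(current))
                    current = []
            current.append(e)
        if current:
            sequences.append(_close_sequence(current))
    return sequences


def _close_sequence(run: list[CommEvent]) -> GestureSequence:
    first, last = run[0], run[-1]
    cats = Counter(e.category for e in run)
    return GestureSequence(
        signaller_id=first.signaller_id,
        recipient_id=min(first.recipient_ids),
        goal=first.goal,
        context=first.context,
        category=cats.most_common(1)[0][0],
        event_ids=[e.event_id for e in run],
        start=first.timestamp,
        end=last.timestamp,
    )


def count_sequences(
    sequences: list[GestureSequence], events: list[CommEvent]
) -> dict[str, Counter]:
    """Dyadic communication counts per functional category.

    Gesture functions are counted per assembled *sequence*; pant-hoot categories
    count each (signaller, recipient) dyad once per *event* (a broadcast call with k
    recipients increments k ordered dyads); pant-grunts count once per call event.
    """
    per_cat: dict[str, Counter] = defaultdict(Counter)
    for seq in sequences:
        per_cat[seq.category][(seq.signaller_id, seq.recipient_id)] += 1
    for e in events:
        if e.category in PANT_HOOT_FUNCTIONS or e.category == PANT_GRUNT:
            for r in e.recipient_ids:
                per_cat[e.category][(e.signaller_id, r)] += 1
    return dict(per_cat)


def dyadic_communication(
    comm_counts: dict[str, Counter], counts: DyadCounts, a: str, b: str, category: str
) -> float:
    """CA for the ordered dyad (a, b): sequences/events per hour within 10 m."""
    if a == b or a not in counts.focal_ids:
        return math.nan
    c = comm_counts.get(category, Counter())[(a, b)]
    # (C * 60) / (P10 * 2) == 30 * C / P10
    return _rate(c, counts.p10[(a, b)], 30.0)


def repertoire_filter(
    events: list[CommEvent], candidate_types: set[str] | None = None
) -> set[str]:
    """Gesture types admitted to the intentional repertoire.

    A morphological gesture type is admitted iff at least 60% of its cases show at
    least one of the five intentionality criteria (boundary inclusive). When an
    explicit candidate list is given, candidates with zero coded cases are excluded
    with a warning.
    """
    cases: dict[str, list[bool]] = defaultdict(list)
    for e in events:
        if e.gesture_type is None:
            continue
        cases[e.gesture_type].append(any(e.intentionality_flags))
    if candidate_types is None:
        candidate_types = set(cases)
    admitted: set[str] = set()
    for gtype in candidate_types:
        flags = cases.get(gtype, [])
        if not flags:
            warnings.warn(f"gesture type {gtype!r} has no coded cases; excluded")
            continue
        if sum(flags) / len(flags) >= 0.60:
            admitted.add(gtype)
    return admitted


def cohens_kappa(labels1: list, labels2: list) -> float:
    """Chance-corrected agreement between two coders of the same items.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the product of
    the coders' marginal label frequencies. Undefined (NaN) when p_e = 1, i.e. both
    coders used a single, identical label throughout.
    """
    if len(labels1) != len(labels2):
        raise ValueError("label vectors differ in length")
    n = len(labels1)
    if n < 2:
        raise ValueError("need at least 2 paired items")
    agree = sum(1 for x, y in zip(labels1, labels2) if x == y)
    p_o = agree / n
    m1, m2 = Counter(labels1), Counter(labels2)
    labels = set(m1) | set(m2)
    p_e = sum((m1[c] / n) * (m2[c] / n) for c in labels)
    if p_e >= 1.0:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# Matrix builders
# ---------------------------------------------------------------------------


def association_matrix(
    counts: DyadCounts,
    ids: list[str] | None = None,
    *,
    kin_pairs: set[frozenset[str]] | None = None,
    oestrous_ids: set[str] | None = None,
    label: str = "proximity",
) -> DyadMatrix:
    """DA (or DAK/DAR) as a weighted directed matrix over the focal individuals."""
    ids = list(ids) if ids is not None else list(counts.focal_ids)
    m = DyadMatrix.empty(ids, label=label)
    for a in ids:
        for b in ids:
            if a != b:
                m.set(
                    a, b,
                    dyadic_association(
                        counts, a, b, kin_pairs=kin_pairs, oestrous_ids=oestrous_ids
                    ),
                )
    return m


def grooming_matrix(
    counts: DyadCounts, category: str, ids: list[str] | None = None
) -> DyadMatrix:
    ids = list(ids) if ids is not None else list(counts.focal_ids)
    m = DyadMatrix.empty(ids, label=f"grooming:{category}")
    for a in ids:
        for b in ids:
            if a != b:
                m.set(a, b, dyadic_grooming(counts, a, b, category))
    return m


def communication_matrix(
    comm_counts: dict[str, Counter],
    counts: DyadCounts,
    category: str,
    ids: list[str] | None = None,
) -> DyadMatrix:
    ids = list(ids) if ids is not None else list(counts.focal_ids)
    m = DyadMatrix.empty(ids, label=f"communication:{category}")
    for a in ids:
        for b in ids:
            if a != b:
                m.set(a, b, dyadic_communication(comm_counts, counts, a, b, category))
    return m


def combined_gesture_matrix(
    comm_counts: dict[str, Counter],
    counts: DyadCounts,
    ids: list[str] | None = None,
    categories: tuple[str, ...] = SEQUENCE_FUNCTIONS + PANT_HOOT_FUNCTIONS,
) -> DyadMatrix:
    """All gesture-accompanied communication combined (excludes pant-grunt calls)."""
    ids = list(ids) if ids is not None else list(counts.focal_ids)
    total: Counter = Counter()
    for cat in categories:
        total.update(comm_counts.get(cat, Counter()))
    m = DyadMatrix.empty(ids, label="communication:all-gestures")
    for a in ids:
        for b in ids:
            if a != b:
                m.set(a, b, dyadic_communication({"_": total}, counts, a, b, "_"))
    return m


def measure_table(matrices: list[DyadMatrix]) -> pd.DataFrame:
    """Long-format table (dyad A, dyad B, measure label, value) over matrices."""
    rows = []
    for m in matrices:
        for i, a in enumerate(m.ids):
            for j, b in enumerate(m.ids):
                if i == j:
                    continue
                v = m.values[i, j]
                if not math.isnan(v):
                    rows.append({"a": a, "b": b, "measure": m.label, "value": v})
    return pd.DataFrame(rows, columns=["a", "b", "measure", "value"])
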