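"""Reading and writing scan/event/attribute tables, matrices and networks.

All on-disk formats are plain text:

* scans — CSV, one row per (scan, party member); a scan with an empty party keeps a
  single anchor row with an empty ``other_id``. Within-10-m membership and the
  grooming partner are flags on the party-member rows, which makes the containment
  invariants (within 10 m implies same party; grooming partner within 10 m)
  structurally checkable at parse time.
* events — CSV, one row per (event, recipient); a broadcast pant-hoot to k
  recipients is k rows sharing an ``event_id``.
* attributes — CSV, one row per individual.
* matrices — labeled square CSV (first column = row ids), empty cell = missing, with
  a one-line header comment carrying the behavior label and directedness so
  write/read round-trips reproduce the object exactly; GraphML via networkx for
  interchange with standard graph tools.

Readers are strict: schema mismatches and invariant violations fail loudly with the
offending row numbers rather than silently coercing.
"""

from __future__ import annotations

import csv
import math
from datetime import datetime
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import DyadMatrix
from .records import CommEvent, RecordValidationError, ScanRecord

__all__ = [
    "SchemaError",
    "write_scans",
    "read_scans",
    "write_events",
    "read_events",
    "write_attributes",
    "read_attributes",
    "write_matrix",
    "read_matrix",
    "export_edges",
    "write_graphml",
    "read_graphml",
]

SCAN_COLUMNS = [
    "focal_id",
    "follow_id",
    "scan_index",
    "timestamp",
    "other_id",
    "within10",
    "grooming",
]
EVENT_COLUMNS = [
    "event_id",
    "timestamp",
    "signaller_id",
    "recipient_id",
    "category",
    "gesture_type",
    "goal",
    "context",
    "response",
    "int1",
    "int2",
    "int3",
    "int4",
    "int5",
]
ATTRIBUTE_COLUMNS = [
    "id",
    "sex",
    "age_years",
    "is_focal",
    "minutes_observed",
    "oestrous",
    "rank",
    "kin_ids",
]



class SchemaError(ValueError):
    """File header or row content does not match the documented schema."""


def _check_header(actual: list[str], expected: list[str], path) -> None:
    if list(actual) != expected:
        raise SchemaError(
            f"{path}: header {actual} does not match expected schema {expected}"
        )


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------


def write_scans(scans: list[ScanRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SCAN_COLUMNS)
        for s in scans:
            base = [s.focal_id, s.follow_id, s.scan_index, s.timestamp.isoformat()]
            if not s.party_ids:
                w.writerow(base + ["", "", ""])
                continue
            for other in sorted(s.party_ids):
                w.writerow(
                    base
                    + [
                        other,
                        1 if other in s.within10_ids else 0,
                        s.grooming if other == s.grooming_partner else "",
                    ]
                )


def read_scans(path, known_ids: set[str] | None = None) -> list[ScanRecord]:
    """Parse and validate scan records; raises with row numbers on any violation."""
    path = Path(path)
    groups: dict[tuple, dict] = {}
    bad_ids: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header expected") from None
        _check_header(header, SCAN_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(SCAN_COLUMNS):
                raise SchemaError(f"{path}:{lineno}: expected {len(SCAN_COLUMNS)} fields")
            focal, follow, scan_idx, ts, other, within10, grooming = row
            key = (focal, follow, scan_idx, ts)
            g = groups.setdefault(
                key, {"party": set(), "within10": set(), "grooming": [], "rows": []}
            )
            g["rows"].append(lineno)
            if known_ids is not None and focal not in known_ids:
                bad_ids.append(lineno)
            if other:
                if known_ids is not None and other not in known_ids:
                    bad_ids.append(lineno)
                g["party"].add(other)
                if within10 == "1":
                    g["within10"].add(other)
                elif within10 not in ("0", ""):
                    raise SchemaError(f"{path}:{lineno}: within10 must be 0 or 1")
                if grooming:
                    g["grooming"].append((grooming, other, lineno))
    if bad_ids:
        raise SchemaError(
            f"{path}: unknown individual ids on rows {sorted(set(bad_ids))}"
        )
    records = []
    for (focal, follow, scan_idx, ts), g in groups.items():
        if len(g["grooming"]) > 1:
            rows = [ln for *_ , ln in g["grooming"]]
            raise SchemaError(f"{path}: multiple grooming partners on rows {rows}")
        grooming, partner = ("none", None)
        if g["grooming"]:
            grooming, partner, _ = g["grooming"][0]
        try:
            records.append(
                ScanRecord(
                    focal_id=focal,
                    follow_id=follow,
                    scan_index=int(scan_idx),
                    timestamp=datetime.fromisoformat(ts),
                    party_ids=frozenset(g["party"]),
                    within10_ids=frozenset(g["within10"]),
                    grooming=grooming,
                    grooming_partner=partner,
                )
            )
        except (RecordValidationError, ValueError) as exc:
            raise SchemaError(f"{path}: rows {g['rows']}: {exc}") from exc
    records.sort(key=lambda s: (s.timestamp, s.focal_id, s.scan_index))
    return records


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------


def write_events(events: list[CommEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for e in events:
            for r in sorted(e.recipient_ids):
                w.writerow(
                    [
                        e.event_id,
                        e.timestamp.isoformat(),
                        e.signaller_id,
                        r,
                        e.category,
                        e.gesture_type or "",
                        e.goal or "",
                        e.context or "",
                        e.response or "",
                    ]
                    + [int(f) for f in e.intentionality_flags]
                )


def read_events(path, known_ids: set[str] | None = None) -> list[CommEvent]:
    path = Path(path)
    groups: dict[str, dict] = {}
    bad_ids: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header expected") from None
        _check_header(header, EVENT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(EVENT_COLUMNS):
                raise SchemaError(f"{path}:{lineno}: expected {len(EVENT_COLUMNS)} fields")
            (eid, ts, sig, rec, cat, gtype, goal, context, response, *flags) = row
            if known_ids is not None:
                bad_ids.extend(ln for i, ln in ((sig, lineno), (rec, lineno)) if i not in known_ids)
            g = groups.setdefault(
                eid,
                {
                    "timestamp": ts,
                    "signaller": sig,
                    "recipients": set(),
                    "category": cat,
                    "gesture_type": gtype,
                    "goal": goal,
                    "context": context,
                    "response": response,
                    "flags": flags,
                    "rows": [],
                },
            )
            g["recipients"].add(rec)
            g["rows"].append(lineno)
            if (g["category"], g["signaller"], g["timestamp"]) != (cat, sig, ts):
                raise SchemaError(
                    f"{path}:{lineno}: rows of event {eid} disagree on "
                    f"category/signaller/timestamp"
                )
    if bad_ids:
        raise SchemaError(f"{path}: unknown individual ids on rows {sorted(set(bad_ids))}")
    events = []
    for eid, g in groups.items():
        try:
            events.append(
                CommEvent(
                    event_id=eid,
                    timestamp=datetime.fromisoformat(g["timestamp"]),
                    signaller_id=g["signaller"],
                    recipient_ids=frozenset(g["recipients"]),
                    category=g["category"],
                    gesture_type=g["gesture_type"] or None,
                    goal=g["goal"] or None,
                    context=g["context"] or None,
                    response=g["response"] or None,
                    intentionality_flags=tuple(f == "1" for f in g["flags"]),
                )
            )
        except RecordValidationError as exc:
            raise SchemaError(f"{path}: rows {g['rows']}: {exc}") from exc
    events.sort(key=lambda e: (e.timestamp, e.event_id))
    return events


# ---------------------------------------------------------------------------
# Attributes
# ---------------------------------------------------------------------------


def write_attributes(attributes: pd.DataFrame, path) -> None:
    attributes.to_csv(path, index=False, columns=ATTRIBUTE_COLUMNS)


def read_attributes(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str, "kin_ids": str}, keep_default_na=False)
    _check_header(list(df.columns), ATTRIBUTE_COLUMNS, path)
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"])
        raise SchemaError(f"{path}: duplicate ids {dupes}")
    df["is_focal"] = df["is_focal"].astype(bool)
    df["oestrous"] = df["oestrous"].astype(bool)
    df["age_years"] = df["age_years"].astype(float)
    if (df["age_years"] <= 0).any():
        raise SchemaError(f"{path}: nonpositive ages")
    return df


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def write_matrix(m: DyadMatrix, path) -> None:
    """Labeled square CSV; empty cell = missing; header comment keeps metadata."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# chimpnet-matrix label={m.label} directed={int(m.directed)}\n")
        w = csv.writer(fh)
        w.writerow(["id"] + list(m.ids))
        for i, a in enumerate(m.ids):
            row = [a]
            for j in range(m.n):
                v = m.values[i, j]
                row.append("" if math.isnan(v) else repr(float(v)))
            w.writerow(row)


def read_matrix(path) -> DyadMatrix:
    path = Path(path)
    with open(path, newline="") as fh:
        meta = fh.readline().strip()
        if not meta.startswith("# chimpnet-matrix"):
            raise SchemaError(f"{path}: missing matrix metadata header")
        fields = dict(kv.split("=", 1) for kv in meta.split()[2:] if "=" in kv)
        reader = csv.reader(fh)
        header = next(reader)
        if header[0] != "id":
            raise SchemaError(f"{path}: first header column must be 'id'")
        ids = header[1:]
        values = np.full((len(ids), len(ids)), np.nan)
        for i, row in enumerate(reader):
            if row[0] != ids[i]:
                raise SchemaError(
                    f"{path}: row label {row[0]!r} does not match column order"
                )
            for j, cell in enumerate(row[1:]):
                if cell != "":
                    values[i, j] = float(cell)
    return DyadMatrix(
        ids, values, label=fields.get("label", ""), directed=fields.get("directed", "1") == "1"
    )


def export_edges(m: DyadMatrix, path, include_zeros: bool = False) -> None:
    """One row per ordered dyad with a nonmissing tie, for standard graph tools.

    Zero-valued cells are observed non-edges and are skipped unless
    ``include_zeros`` is set.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["from", "to", "value"])
        for i, a in enumerate(m.ids):
            for j, b in enumerate(m.ids):
                if i == j:
                    continue
                v = m.values[i, j]
                if math.isnan(v) or (v == 0 and not include_zeros):
                    continue
                w.writerow([a, b, repr(float(v))])


def _to_graph(m: DyadMatrix) -> "nx.Graph | nx.DiGraph":
    g = nx.DiGraph() if m.directed else nx.Graph()
    g.add_nodes_from(m.ids)
    for i, a in enumerate(m.ids):
        for j, b in enumerate(m.ids):
            if i == j or (not m.directed and j < i):
                continue
            v = m.values[i, j]
            if not math.isnan(v) and v != 0:
                g.add_edge(a, b, weight=float(v))
    g.graph["label"] = m.label
    return g


def write_graphml(m: DyadMatrix, path) -> None:
    nx.write_graphml(_to_graph(m), path)


def read_graphml(path, label: str = "", directed: bool | None = None) -> DyadMatrix:
    g = nx.read_graphml(path)
    is_directed = g.is_directed() if directed is None else directed
    ids = list(g.nodes())
    m = DyadMatrix.empty(ids, label=label or g.graph.get("label", ""), directed=is_directed)
    for a, b, data in g.edges(data=True):
        m.set(a, b, float(data.get("weight", 1.0)))
        if not is_directed:
            m.set(b, a, float(data.get("weight", 1.0)))
    return m
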