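"""Readers and writers for profile and relation-table files.

Two mirror formats are supported, selected by file extension:

* **CSV** (UTF-8, comma, dot decimals).  SVNS profiles: columns
  ``criterion,T,I,F``; IVNS profiles: ``criterion,TL,TU,IL,IU,FL,FU``.
  Relation tables prepend a ``diagnosis`` column and hold one row per
  (diagnosis, criterion) pair.
* **JSON**: ``{"kind": ..., "entries": [{"criterion": ..., "t": ...}]}``
  for profiles, with nested interval objects for IVNS readability;
  tables add a ``diagnoses`` list of row objects.

Validation is strict by default; ``clamp=True`` clips out-of-range
components into [0, 1] and sorts inverted interval endpoints, logging
each repair.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import IVNSElement, Profile, RelationTable, SVNSElement

__all__ = [
    "read_profile",
    "read_relation_table",
    "write_profile",
    "write_relation_table",
]

_SVNS_COLS = ["T", "I", "F"]
_IVNS_COLS = ["TL", "TU", "IL", "IU", "FL", "FU"]


def _element(values, kind: str, clamp: bool, where: str):
    cls = SVNSElement if kind == "svns" else IVNSElement
    try:
        return cls.clamped(*values) if clamp else cls(*values)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid element at {where}: {exc}") from exc


def _columns(kind: str) -> list:
    if kind == "svns":
        return _SVNS_COLS
    if kind == "ivns":
        return _IVNS_COLS
    raise ValueError(f"unknown kind {kind!r}")


def _check_columns(frame: pd.DataFrame, label_cols: list, value_cols: list, path) -> None:
    missing = [c for c in [*label_cols, *value_cols] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad = frame[value_cols].map(lambda v: pd.isna(pd.to_numeric(v, errors="coerce")))
    if bad.to_numpy().any():
        rows = frame.index[bad.any(axis=1)].tolist()
        raise ValueError(f"{path}: non-numeric cell(s) in data row(s) {rows}")


def read_profile(path, kind: str, clamp: bool = False) -> Profile:
    """Read a single profile from a CSV or JSON file."""
    path = Path(path)
    cols = _columns(kind)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        entries = []
        for k, entry in enumerate(doc["entries"]):
            name = entry["criterion"]
            if kind == "svns":
                vals = [entry["t"], entry["i"], entry["f"]]
            else:
                vals = [*entry["t"], *entry["i"], *entry["f"]]
            entries.append((name, _element(vals, kind, clamp, f"entry {k} ({name})")))
        return Profile(tuple(entries))
    frame = pd.read_csv(path)
    _check_columns(frame, ["criterion"], cols, path)
    entries = []
    for k, row in frame.iterrows():
        entries.append(
            (
                str(row["criterion"]),
                _element(
                    [float(row[c]) for c in cols], kind, clamp, f"row {k} ({row['criterion']})"
                ),
            )
        )
    return Profile(tuple(entries))


def read_relation_table(path, kind: str, clamp: bool = False) -> RelationTable:
    """Read a diagnoses x criteria relation table from CSV or JSON.

    Row and column order is preserved from the file; every diagnosis must
    cover the same criteria in the same order.
    """
    path = Path(path)
    cols = _columns(kind)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        diagnoses, criteria, cells = [], None, []
        for block in doc["diagnoses"]:
            diagnoses.append(block["diagnosis"])
            names, elements = [], []
            for k, entry in enumerate(block["entries"]):
                names.append(entry["criterion"])
                if kind == "svns":
                    vals = [entry["t"], entry["i"], entry["f"]]
                else:
                    vals = [*entry["t"], *entry["i"], *entry["f"]]
                elements.append(
                    _element(vals, kind, clamp, f"{block['diagnosis']} entry {k}")
                )
            if criteria is None:
                criteria = names
            elif names != criteria:
                raise ValueError(f"{path}: criteria differ across diagnoses")
            cells.append(tuple(elements))
        return RelationTable(tuple(diagnoses), tuple(criteria), tuple(cells))
    frame = pd.read_csv(path)
    _check_columns(frame, ["diagnosis", "criterion"], cols, path)
    diagnoses = list(dict.fromkeys(frame["diagnosis"].astype(str)))
    criteria = None
    cells = []
    for diag in diagnoses:
        sub = frame[frame["diagnosis"].astype(str) == diag]
        names = [str(c) for c in sub["criterion"]]
        if criteria is None:
            criteria = names
        elif names != criteria:
            raise ValueError(f"{path}: criteria differ across diagnoses (at {diag!r})")
        cells.append(
            tuple(
                _element([float(row[c]) for c in cols], kind, clamp, f"({diag}, {row['criterion']})")
                for _, row in sub.iterrows()
            )
        )
    return RelationTable(tuple(diagnoses), tuple(criteria), tuple(cells))


def _profile_records(profile: Profile) -> list:
    records = []
    for name, el in profile.entries:
        if profile.kind == "svns":
            records.append({"criterion": name, "T": el.t, "I": el.i, "F": el.f})
        else:
            records.append(
                {
                    "criterion": name,
                    "TL": el.t_lo,
                    "TU": el.t_hi,
                    "IL": el.i_lo,
                    "IU": el.i_hi,
                    "FL": el.f_lo,
                    "FU": el.f_hi,
                }
            )
    return records


def _profile_json_entries(profile: Profile) -> list:
    entries = []
    for name, el in profile.entries:
        if profile.kind == "svns":
            entries.append({"criterion": name, "t": el.t, "i": el.i, "f": el.f})
        else:
            entries.append(
                {
                    "criterion": name,
                    "t": [el.t_lo, el.t_hi],
                    "i": [el.i_lo, el.i_hi],
                    "f": [el.f_lo, el.f_hi],
                }
            )
    return entries


def write_profile(profile: Profile, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({"kind": profile.kind, "entries": _profile_json_entries(profile)}, indent=1)
        )
        return
    pd.DataFrame(_profile_records(profile)).to_csv(path, index=False)


def write_relation_table(table: RelationTable, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "kind": table.kind,
            "diagnoses": [
                {"diagnosis": d, "entries": _profile_json_entries(profile)}
                for d, profile in table.rows()
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
        return
    records = []
    for d, profile in table.rows():
        for rec in _profile_records(profile):
            records.append({"diagnosis": d, **rec})
    pd.DataFrame(records).to_csv(path, index=False)
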