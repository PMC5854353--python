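"""Specimen table I/O.

User specimens arrive as CSV/TSV, one row per specimen, columns named by
character id; empty cells mean "not measured".  Unknown columns are kept
as free-text metadata (collector, locality, ...) with a warning.
"""
from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Union

from .characters import CharacterKind, Registry
from .ratios import Specimen

_NUMBER = re.compile(r"^-?\d+(\.\d+)?([eE][+-]?\d+)?$")


class SpecimenTableError(ValueError):
    pass


def parse_specimen_table(path: Union[str, Path], registry: Registry
                         ) -> tuple[list[Specimen], list[str]]:
    """Parse a specimen CSV/TSV into Specimen records.

    Decimal separator is "." only; a comma decimal ("0,44") is a row-level
    error with the line number.  Duplicate specimen ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise SpecimenTableError(f"specimen table not found: {path}")
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    warnings: list[str] = []
    specimens: list[Specimen] = []
    seen_ids: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return [], warnings
        known = {c for c in reader.fieldnames if c in registry}
        special = {"id", "specimen_id", "morph"}
        unknown = [c for c in reader.fieldnames
                   if c not in known and c not in special]
        for col in unknown:
            warnings.append(f"unknown column {col!r} kept as metadata")
        for lineno, row in enumerate(reader, start=2):
            sid = row.get("id") or row.get("specimen_id") or f"row{lineno}"
            if sid in seen_ids:
                raise SpecimenTableError(f"line {lineno}: duplicate specimen "
                                         f"id {sid!r}")
            seen_ids.add(sid)
            morph = (row.get("morph") or "").strip()
            if not morph:
                raise SpecimenTableError(f"line {lineno}: missing morph")
            linear: dict[str, float] = {}
            counts: dict[str, int] = {}
            states: dict[str, str] = {}
            metadata = {c: row[c] for c in unknown if row.get(c)}
            for cid in known:
                cell = (row.get(cid) or "").strip()
                if not cell:
                    continue
                cdef = registry[cid]
                if cdef.kind is CharacterKind.categorical:
                    if cell not in cdef.allowed_states:
                        raise SpecimenTableError(
                            f"line {lineno}: state {cell!r} not allowed for "
                            f"{cid}")
                    states[cid] = cell
                    continue
                if cdef.kind is CharacterKind.ratio:
                    raise SpecimenTableError(
                        f"line {lineno}: ratio character {cid} cannot be a "
                        "raw input column")
                if not _NUMBER.match(cell):
                    raise SpecimenTableError(
                        f"line {lineno}: unparseable numeric cell {cell!r} in "
                        f"column {cid} (decimal separator must be '.')")
                if cdef.kind is CharacterKind.count:
                    value = float(cell)
                    if value != int(value):
                        raise SpecimenTableError(
                            f"line {lineno}: count {cid} must be an integer, "
                            f"got {cell!r}")
                    counts[cid] = int(value)
                else:
                    linear[cid] = float(cell)
            specimens.append(Specimen(id=sid, morph=morph, linear=linear,
                                      counts=counts, states=states,
                                      metadata=metadata))
    return specimens, warnings


def write_specimen_table(specimens: list[Specimen], path: Union[str, Path],
                         registry: Registry) -> None:
    """Write specimens in the same schema the parser reads (round-trippable)."""
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    columns: list[str] = []
    for spec in specimens:
        for cid in list(spec.linear) + list(spec.counts) + list(spec.states):
            if cid not in columns:
                columns.append(cid)
    columns.sort()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["id", "morph"] + columns)
        for spec in specimens:
            row = [spec.id, spec.morph]
            for cid in columns:
                v = spec.linear.get(cid)
                if v is None and cid in spec.counts:
                    v = spec.counts[cid]
                if v is None:
                    v = spec.states.get(cid, "")
                row.append(v)
            writer.writerow(row)
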