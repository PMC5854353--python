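"""Reference dataset: taxon records, per-morph range profiles, and the
consistency audit.

The bundled dataset transcribes the measurement tables and description
ranges of the revision of *Myzaphis* and its allies (*Richardsaphis
canadensis*, *Ericaphis avariolosa*) into one row per
taxon x morph x character.  Two layers are exposed:

``as_printed``
    the verbatim transcription, typographic anomalies included
    (e.g. an inverted "0.3–0.20" span);
``curated``
    the same data with a small set of documented corrections applied
    (see ``data/curated.csv``); all analysis defaults to this layer.

The audit (:func:`validate_dataset`) is deliberately run on the as-printed
layer in tests: it must rediscover the printed anomalies.
"""
from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from pydantic import BaseModel, Field

from .characters import CharacterDef, CharacterKind, Interval, Registry

MORPHS = ("fundatrix", "aptera", "alata", "ovipara", "male")
TABLE_FILES = ["table1.csv", "table2.csv", "table3.csv", "table4.csv",
               "table5.csv", "table6.csv"]
DATA_FILES = TABLE_FILES + ["description_ranges.csv", "states.csv",
                            "curated.csv", "profiles.csv"]

#: relative tolerance used to expand "about X" phrasings into an interval
ABOUT_TOLERANCE = 0.05


class LoadError(ValueError):
    """Raised when the reference bundle does not parse cleanly."""


class LookupError_(KeyError):
    """Raised by query_range when taxon / morph / character is unknown."""


class RangeEntry(BaseModel):
    lo: float
    hi: float
    provenance: str
    as_printed: str

    def interval(self) -> Interval:
        return Interval(lo=self.lo, hi=self.hi)

    @property
    def valid(self) -> bool:
        return 0 <= self.lo <= self.hi


class StateEntry(BaseModel):
    state: str
    provenance: str
    as_printed: str


class TaxonRecord(BaseModel):
    genus: str
    species: str
    authority: str
    status: str
    note: str = ""

    @property
    def full_name(self) -> str:
        return f"{self.genus} {self.species}"


class RangeProfile(BaseModel):
    taxon: str
    morph: str
    n_examined: int
    entries: dict[str, RangeEntry] = Field(default_factory=dict)
    states: dict[str, StateEntry] = Field(default_factory=dict)

    def interval(self, cid: str) -> Interval:
        return self.entries[cid].interval()

    def characters(self) -> list[str]:
        return sorted(set(self.entries) | set(self.states))


class AuditFinding(BaseModel):
    severity: str  # "error" | "warning"
    taxon: str
    morph: str
    character_id: str
    message: str
    as_printed: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"[{self.severity}] {self.taxon}/{self.morph}/"
                f"{self.character_id}: {self.message}")


class CuratedOverride(BaseModel):
    taxon: str
    morph: str
    character_id: str
    action: str  # replace | drop | remap
    lo: Optional[float] = None
    hi: Optional[float] = None
    new_character_id: str = ""
    justification: str


class ReferenceDataset(BaseModel):
    model_config = {"arbitrary_types_allowed": True}

    layer: str
    registry: Registry
    taxa: dict[str, TaxonRecord]
    genus_level_traits: dict[str, dict[str, tuple[int, int]]]
    genus_terminals: list[str]
    examined_material: dict[str, int]
    profiles: dict[str, RangeProfile]  # keyed "taxon/morph"
    overrides: list[CuratedOverride]
    raw_frames: dict[str, pd.DataFrame]

    @staticmethod
    def key(taxon: str, morph: str) -> str:
        return f"{taxon}/{morph}"

    def profile(self, taxon: str, morph: str) -> RangeProfile:
        if taxon not in self.taxa:
            raise LookupError_(f"unknown taxon {taxon!r}")
        if morph not in MORPHS:
            raise LookupError_(f"unknown morph {morph!r}")
        k = self.key(taxon, morph)
        if k not in self.profiles:
            have = sorted(p.morph for p in self.profiles.values()
                          if p.taxon == taxon)
            raise LookupError_(
                f"no {morph} profile described for {taxon} (known morphs: {have})")
        return self.profiles[k]

    def profiles_of_morph(self, morph: str) -> list[RangeProfile]:
        return sorted((p for p in self.profiles.values() if p.morph == morph),
                      key=lambda p: p.taxon)


def default_data_path() -> Path:
    return Path(str(resources.files("aphidkey").joinpath("data")))


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _parse_float(text: str, where: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise LoadError(f"{where}: unparseable numeric value {text!r}") from None


def load_reference(path: Union[str, Path, None] = None,
                   layer: str = "curated") -> ReferenceDataset:
    """Load the bundled (or an external) reference bundle.

    Parameters
    ----------
    path
        Directory holding the bundle; defaults to the packaged dataset.
    layer
        ``"curated"`` (default) or ``"as_printed"``.
    """
    if layer not in ("curated", "as_printed"):
        raise LoadError(f"unknown data layer {layer!r}")
    root = Path(path) if path is not None else default_data_path()
    if not root.is_dir():
        raise LoadError(f"reference bundle directory not found: {root}")

    reg_file = root / "registry.json"
    taxa_file = root / "taxa.json"
    for f in [reg_file, taxa_file] + [root / n for n in DATA_FILES]:
        if not f.exists():
            raise LoadError(f"reference bundle incomplete: missing {f.name}")

    registry = Registry.from_list(
        [CharacterDef(**c) for c in
         json.loads(reg_file.read_text())["characters"]])
    taxa_doc = json.loads(taxa_file.read_text())
    taxa = {t["species"]: TaxonRecord(**t) for t in taxa_doc["species"]}
    glt = {g: {cid: (int(v[0]), int(v[1])) for cid, v in traits.items()}
           for g, traits in taxa_doc["genus_level_traits"].items()}

    raw_frames: dict[str, pd.DataFrame] = {}
    for name in DATA_FILES:
        raw_frames[name] = _read_csv(root / name)

    nrows = raw_frames["profiles.csv"]
    n_examined = {(r.taxon, r.morph): int(r.n_examined)
                  for r in nrows.itertuples()}

    profiles: dict[str, RangeProfile] = {}

    def get_profile(taxon: str, morph: str, where: str) -> RangeProfile:
        if taxon not in taxa:
            raise LoadError(f"{where}: unknown taxon {taxon!r}")
        if morph not in MORPHS:
            raise LoadError(f"{where}: unknown morph {morph!r}")
        k = ReferenceDataset.key(taxon, morph)
        if k not in profiles:
            if (taxon, morph) not in n_examined:
                raise LoadError(f"{where}: ({taxon}, {morph}) missing from profiles.csv")
            profiles[k] = RangeProfile(taxon=taxon, morph=morph,
                                       n_examined=n_examined[(taxon, morph)])
        return profiles[k]

    for name in TABLE_FILES + ["description_ranges.csv"]:
        for i, r in enumerate(raw_frames[name].itertuples(), start=2):
            where = f"{name}:{i}"
            if r.character_id not in registry:
                raise LoadError(f"{where}: unknown character {r.character_id!r}")
            kind = registry[r.character_id].kind
            if kind is CharacterKind.categorical:
                raise LoadError(f"{where}: categorical character in a range table")
            prof = get_profile(r.taxon, r.morph, where)
            if r.character_id in prof.entries:
                raise LoadError(
                    f"{where}: duplicate entry ({r.taxon}, {r.morph}, {r.character_id})")
            prof.entries[r.character_id] = RangeEntry(
                lo=_parse_float(r.lo, where), hi=_parse_float(r.hi, where),
                provenance=r.provenance, as_printed=r.as_printed)

    for i, r in enumerate(raw_frames["states.csv"].itertuples(), start=2):
        where = f"states.csv:{i}"
        if r.character_id not in registry:
            raise LoadError(f"{where}: unknown character {r.character_id!r}")
        cdef = registry[r.character_id]
        if cdef.kind is not CharacterKind.categorical:
            raise LoadError(f"{where}: {r.character_id} is not categorical")
        if r.state not in cdef.allowed_states:
            raise LoadError(f"{where}: state {r.state!r} not allowed for {r.character_id}")
        prof = get_profile(r.taxon, r.morph, where)
        if r.character_id in prof.states:
            raise LoadError(
                f"{where}: duplicate state ({r.taxon}, {r.morph}, {r.character_id})")
        prof.states[r.character_id] = StateEntry(
            state=r.state, provenance=r.provenance, as_printed=r.as_printed)

    overrides = []
    for i, r in enumerate(raw_frames["curated.csv"].itertuples(), start=2):
        where = f"curated.csv:{i}"
        if r.action not in ("replace", "drop", "remap"):
            raise LoadError(f"{where}: unknown action {r.action!r}")
        overrides.append(CuratedOverride(
            taxon=r.taxon, morph=r.morph, character_id=r.character_id,
            action=r.action,
            lo=_parse_float(r.lo, where) if r.lo else None,
            hi=_parse_float(r.hi, where) if r.hi else None,
            new_character_id=r.new_character_id,
            justification=r.justification))

    if layer == "curated":
        for ov in overrides:
            k = ReferenceDataset.key(ov.taxon, ov.morph)
            if k not in profiles or ov.character_id not in profiles[k].entries:
                raise LoadError(
                    f"curated.csv: override targets missing entry "
                    f"({ov.taxon}, {ov.morph}, {ov.character_id})")
            prof = profiles[k]
            entry = prof.entries[ov.character_id]
            if ov.action == "replace":
                prof.entries[ov.character_id] = entry.model_copy(
                    update={"lo": ov.lo, "hi": ov.hi})
            elif ov.action == "drop":
                del prof.entries[ov.character_id]
            elif ov.action == "remap":
                if ov.new_character_id not in registry:
                    raise LoadError(
                        f"curated.csv: remap to unknown id {ov.new_character_id!r}")
                del prof.entries[ov.character_id]
                prof.entries[ov.new_character_id] = entry

    return ReferenceDataset(
        layer=layer, registry=registry, taxa=taxa, genus_level_traits=glt,
        genus_terminals=list(taxa_doc["genus_terminals"]),
        examined_material={k: int(v)
                           for k, v in taxa_doc["examined_material"].items()},
        profiles=profiles, overrides=overrides, raw_frames=raw_frames)


def save_reference(ds: ReferenceDataset, out_dir: Union[str, Path]) -> None:
    """Re-serialize the raw bundle (identity round trip on the CSV tables)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    src = default_data_path()
    for name in ("registry.json", "taxa.json"):
        (out / name).write_text((src / name).read_text())
    for name, frame in ds.raw_frames.items():
        frame.to_csv(out / name, index=False)


def query_range(ds: ReferenceDataset, taxon: str, morph: str,
                character_id: str) -> Union[Interval, str]:
    """Return the transcribed interval (or categorical state) for one cell."""
    prof = ds.profile(taxon, morph)
    if character_id not in ds.registry:
        raise LookupError_(f"unknown character {character_id!r}")
    if character_id in prof.entries:
        return prof.entries[character_id].interval()
    if character_id in prof.states:
        return prof.states[character_id].state
    raise LookupError_(
        f"character {character_id} not recorded for ({taxon}, {morph})")


# ---------------------------------------------------------------------------
# consistency audit

_SEGMENTS_6 = ["ANT_III", "ANT_IV", "ANT_V", "ANT_VI", "BASE", "PT"]
_SEGMENTS_5 = ["ANT_III", "ANT_IV", "ANT_V", "BASE", "PT"]
_LINEAR_SANITY_MM = 5.0


def validate_dataset(ds: ReferenceDataset) -> list[AuditFinding]:
    """Deterministic consistency audit of every profile entry.

    Checks, per entry: lo <= hi, non-negativity, count integrality,
    unit sanity for lengths (< 5 mm; the largest printed body length is
    2.60 mm), antennal part-vs-whole plausibility, PT+BASE versus the
    last antennal segment, zero-specimen profiles, and (on the curated
    layer) a reminder for every override applied.
    Findings are ordered by (taxon, morph, character).
    """
    findings: list[AuditFinding] = []

    def add(severity, prof, cid, message, as_printed=""):
        findings.append(AuditFinding(
            severity=severity, taxon=prof.taxon, morph=prof.morph,
            character_id=cid, message=message, as_printed=as_printed))

    for prof in ds.profiles.values():
        if prof.n_examined == 0:
            add("warning", prof, "", "profile with n_examined = 0")
        segments = None
        if "ANT_SEGMENTS" in prof.entries:
            segments = int(prof.entries["ANT_SEGMENTS"].lo)
        for cid, e in sorted(prof.entries.items()):
            cdef = ds.registry[cid]
            if e.lo > e.hi:
                add("error", prof, cid,
                    f"inverted interval: lo {e.lo} > hi {e.hi}", e.as_printed)
                continue
            if e.lo < 0:
                add("error", prof, cid, f"negative lower bound {e.lo}",
                    e.as_printed)
            if cdef.kind is CharacterKind.count:
                if e.lo != int(e.lo) or e.hi != int(e.hi):
                    add("error", prof, cid,
                        f"non-integer count bounds [{e.lo}, {e.hi}]",
                        e.as_printed)
            if cdef.kind is CharacterKind.linear and e.hi >= _LINEAR_SANITY_MM:
                add("error", prof, cid,
                    f"length {e.hi} mm exceeds the {_LINEAR_SANITY_MM} mm "
                    "sanity bound", e.as_printed)

        # part vs whole: no antennal segment can exceed the whole antenna
        ant = prof.entries.get("ANT")
        if ant is not None and ant.valid:
            for cid in _SEGMENTS_6:
                seg = prof.entries.get(cid)
                if seg is None:
                    continue
                if min(seg.lo, seg.hi) > ant.hi or max(seg.lo, seg.hi) > ant.hi:
                    add("error", prof, cid,
                        f"antennal segment [{seg.lo}, {seg.hi}] exceeds the "
                        f"whole antenna (ANT hi {ant.hi})", seg.as_printed)

        # PT + BASE must be compatible with the last antennal segment
        base, pt = prof.entries.get("BASE"), prof.entries.get("PT")
        last = None
        if segments == 5:
            last = prof.entries.get("ANT_V")
        elif segments == 6:
            last = prof.entries.get("ANT_VI")
        if base and pt and last and base.valid and pt.valid and last.valid:
            lo, hi = base.lo + pt.lo, base.hi + pt.hi
            eps = 1e-6  # printed precision is 0.01 mm; absorb float rounding
            if hi < last.lo - eps or lo > last.hi + eps:
                add("error", prof, "PT",
                    f"BASE+PT span [{round(lo, 3)}, {round(hi, 3)}] is disjoint "
                    f"from the last antennal segment [{last.lo}, {last.hi}]")

        # 5-segmented profiles carrying ANT VI-based characters (printed quirk)
        if segments == 5:
            for cid in sorted(prof.entries):
                if cid == "ANT_VI" or cid.endswith("ANT_VI"):
                    add("warning", prof, cid,
                        "ANT VI-based character on a 5-segmented profile "
                        "(encoded as printed)",
                        prof.entries[cid].as_printed)

    if ds.layer == "curated":
        for ov in ds.overrides:
            prof = ds.profiles.get(ReferenceDataset.key(ov.taxon, ov.morph))
            if prof is not None:
                add("warning", prof, ov.character_id,
                    f"curated override applied ({ov.action}): {ov.justification}")

    findings.sort(key=lambda f: (f.taxon, f.morph, f.character_id, f.severity))
    return findings


def material_counts(ds: ReferenceDataset) -> dict[str, int]:
    """Examined-specimen counts per morph plus their sum and printed total."""
    per_morph = {m: ds.examined_material[m] for m in MORPHS}
    return {**per_morph,
            "sum": sum(per_morph.values()),
            "printed_total": ds.examined_material["total_individuals"]}
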