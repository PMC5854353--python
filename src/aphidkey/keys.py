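"""Dichotomous key engine.

A key is a rooted binary decision structure: each couplet offers two
contrasting leads, each lead a conjunction of predicates over registered
characters, ending either at another couplet or at a terminal taxon.

Traversal semantics (deliberately explicit about ambiguity):

* a lead is *true* when every predicate holds, *false* when any predicate
  fails, *unknown* when a predicate's character is missing and none fails;
* at a couplet, (true, false) follows lead a, (false, true) lead b;
  (true, true) or any unknown follows **both** leads and unions the
  terminals; (false, false) contributes nothing ("neither").

Predicate intervals are closed: a specimen exactly at a printed bound
satisfies the lead. "X or less" / "X or more" phrasings become half-open
intervals [0, X] / [X, inf).
"""
from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

from pydantic import BaseModel, Field

from .characters import CharacterKind, Interval, Registry
from .ratios import Specimen
from .reference import AuditFinding, RangeProfile, ReferenceDataset


class KeyDefinitionError(ValueError):
    """Raised at load time for malformed keys (never during traversal)."""


class ScopeError(ValueError):
    pass


class Predicate(BaseModel):
    character_id: str
    op: str  # in | le | ge | eq | state_in | present
    lo: Optional[float] = None
    hi: Optional[float] = None
    state: Optional[str] = None
    states: list[str] = Field(default_factory=list)
    curated: Optional[dict] = None

    def bounds(self, layer: str = "curated") -> tuple[float, float]:
        """Effective closed interval for quantitative ops."""
        lo, hi = self.lo, self.hi
        if layer == "curated" and self.curated:
            lo = self.curated.get("lo", lo)
            hi = self.curated.get("hi", hi)
        if self.op == "le":
            return 0.0, float(hi)
        if self.op == "ge":
            return float(lo), math.inf
        return float(lo), float(hi)

    def allowed_states(self) -> list[str]:
        return [self.state] if self.op == "eq" else list(self.states)

    def is_quantitative(self) -> bool:
        return self.op in ("in", "le", "ge")

    def evaluate(self, specimen: Specimen, layer: str = "curated") -> Optional[bool]:
        """True / False / None (= character missing)."""
        if self.op == "present":
            return self.character_id in specimen.present_characters()
        if self.is_quantitative():
            value = specimen.value(self.character_id)
            if value is None:
                return None
            lo, hi = self.bounds(layer)
            return lo <= value <= hi
        state = specimen.states.get(self.character_id)
        if state is None:
            return None
        return state in self.allowed_states()


class Lead(BaseModel):
    predicates: list[Predicate]
    next: Optional[str] = None
    taxon: Optional[str] = None
    as_printed: str = ""

    @property
    def terminal(self) -> bool:
        return self.taxon is not None

    def evaluate(self, specimen: Specimen, layer: str = "curated") -> Optional[bool]:
        saw_unknown = False
        for pred in self.predicates:
            v = pred.evaluate(specimen, layer)
            if v is False:
                return False
            if v is None:
                saw_unknown = True
        return None if saw_unknown else True


class Couplet(BaseModel):
    a: Lead
    b: Lead


class Key(BaseModel):
    id: str
    name: str
    morph: str
    root: str
    couplets: dict[str, Couplet]
    terminals_are_genera: bool = False

    def terminals(self) -> list[str]:
        out = []
        for c in self.couplets.values():
            for lead in (c.a, c.b):
                if lead.terminal:
                    out.append(lead.taxon)
        return sorted(out)

    def path_to(self, terminal: str) -> list[tuple[str, str]]:
        """The (couplet_id, lead_name) path from the root to a terminal."""
        def dfs(cid: str, acc: list[tuple[str, str]]) -> Optional[list]:
            couplet = self.couplets[cid]
            for name, lead in (("a", couplet.a), ("b", couplet.b)):
                step = acc + [(cid, name)]
                if lead.terminal and lead.taxon == terminal:
                    return step
                if lead.next is not None:
                    found = dfs(lead.next, step)
                    if found is not None:
                        return found
            return None

        path = dfs(self.root, [])
        if path is None:
            raise KeyDefinitionError(f"terminal {terminal!r} unreachable in key {self.id}")
        return path


class TraversalResult(BaseModel):
    key_id: str
    terminals: list[str]
    trace: list[tuple[str, str]]  # (couplet_id, verdict in {a, b, both, neither})
    notes: list[str] = Field(default_factory=list)


def validate_key(key: Key, registry: Registry,
                 known_terminals: Optional[set[str]] = None) -> None:
    """Structural validation: registered characters, acyclicity from the
    root, full reachability, resolvable terminals, two leads per couplet."""
    for cid, couplet in key.couplets.items():
        for lead in (couplet.a, couplet.b):
            if (lead.next is None) == (lead.taxon is None):
                raise KeyDefinitionError(
                    f"{key.id}/{cid}: lead must end at exactly one of "
                    "couplet or taxon")
            if not lead.predicates:
                raise KeyDefinitionError(f"{key.id}/{cid}: lead without predicates")
            if lead.next is not None and lead.next not in key.couplets:
                raise KeyDefinitionError(
                    f"{key.id}/{cid}: unknown next couplet {lead.next!r}")
            for pred in lead.predicates:
                if pred.character_id not in registry:
                    raise KeyDefinitionError(
                        f"{key.id}/{cid}: unregistered character "
                        f"{pred.character_id!r}")
                cdef = registry[pred.character_id]
                if pred.op in ("eq", "state_in"):
                    bad = [s for s in pred.allowed_states()
                           if s not in cdef.allowed_states]
                    if cdef.kind is not CharacterKind.categorical or bad:
                        raise KeyDefinitionError(
                            f"{key.id}/{cid}: invalid states {bad} for "
                            f"{pred.character_id}")
                elif pred.is_quantitative():
                    lo, hi = pred.bounds("as_printed")
                    if lo > hi or lo < 0:
                        raise KeyDefinitionError(
                            f"{key.id}/{cid}: invalid interval [{lo}, {hi}]")
            if lead.taxon is not None and known_terminals is not None:
                if lead.taxon not in known_terminals:
                    raise KeyDefinitionError(
                        f"{key.id}/{cid}: terminal {lead.taxon!r} not in taxonomy")

    if key.root not in key.couplets:
        raise KeyDefinitionError(f"{key.id}: root couplet {key.root!r} missing")

    # acyclicity + reachability from the root
    colour: dict[str, int] = {}

    def visit(cid: str) -> None:
        if colour.get(cid) == 1:
            raise KeyDefinitionError(f"{key.id}: cycle through couplet {cid}")
        if colour.get(cid) == 2:
            return
        colour[cid] = 1
        couplet = key.couplets[cid]
        for lead in (couplet.a, couplet.b):
            if lead.next is not None:
                visit(lead.next)
        colour[cid] = 2

    visit(key.root)
    unreachable = set(key.couplets) - set(colour)
    if unreachable:
        raise KeyDefinitionError(f"{key.id}: unreachable couplets {sorted(unreachable)}")


def load_key(path: Union[str, Path], registry: Registry,
             known_terminals: Optional[set[str]] = None) -> Key:
    doc = json.loads(Path(path).read_text())
    try:
        key = Key(**doc)
    except Exception as exc:
        raise KeyDefinitionError(f"{path}: {exc}") from exc
    validate_key(key, registry, known_terminals)
    return key


def bundled_key_dir() -> Path:
    from .reference import default_data_path
    return default_data_path() / "keys"


BUNDLED_KEY_IDS = ["fundatrix", "apterae", "alatae", "oviparae", "males",
                   "genera_222"]


def load_bundled_keys(ds: ReferenceDataset) -> dict[str, Key]:
    known = set(ds.taxa) | set(ds.genus_terminals)
    return {kid: load_key(bundled_key_dir() / f"{kid}.json", ds.registry, known)
            for kid in BUNDLED_KEY_IDS}


def evaluate_lead(specimen: Specimen, lead: Lead,
                  layer: str = "curated") -> Optional[bool]:
    """Verdict for one lead: True, False, or None (unknown)."""
    return lead.evaluate(specimen, layer)


def traverse(specimen: Specimen, key: Key, layer: str = "curated",
             check_scope: bool = True) -> TraversalResult:
    """Run a specimen through a key; see the module docstring for the
    branching semantics.  Terminal output ordering is alphabetical."""
    if check_scope and specimen.morph != key.morph:
        raise ScopeError(
            f"specimen morph {specimen.morph!r} does not match key scope "
            f"{key.morph!r}")
    terminals: set[str] = set()
    trace: list[tuple[str, str]] = []
    notes: list[str] = []
    stack = [key.root]
    seen: set[str] = set()
    while stack:
        cid = stack.pop(0)
        if cid in seen:
            continue
        seen.add(cid)
        couplet = key.couplets[cid]
        va = couplet.a.evaluate(specimen, layer)
        vb = couplet.b.evaluate(specimen, layer)
        if va is True and vb is False:
            verdict, follow = "a", [couplet.a]
        elif vb is True and va is False:
            verdict, follow = "b", [couplet.b]
        elif va is False and vb is False:
            verdict, follow = "neither", []
            notes.append(f"couplet {cid}: neither lead fits")
        else:
            verdict, follow = "both", [couplet.a, couplet.b]
        trace.append((cid, verdict))
        for lead in follow:
            if lead.terminal:
                terminals.add(lead.taxon)
            else:
                stack.append(lead.next)
    return TraversalResult(key_id=key.id, terminals=sorted(terminals),
                           trace=trace, notes=notes)


# ---------------------------------------------------------------------------
# auditing a key against the reference profiles

def _predicate_vs_profile(pred: Predicate, profile: RangeProfile,
                          layer: str) -> str:
    """'holds' | 'partial' | 'fails' | 'missing' for one predicate,
    interpreting the profile interval-wise (containment / overlap /
    disjointness)."""
    if pred.is_quantitative():
        if pred.character_id not in profile.entries:
            return "missing"
        entry = profile.entries[pred.character_id]
        if not entry.valid:
            return "missing"
        lo, hi = pred.bounds(layer)
        if entry.lo >= lo and entry.hi <= hi:
            return "holds"
        if entry.hi < lo or entry.lo > hi:
            return "fails"
        return "partial"
    if pred.op == "present":
        return "holds" if pred.character_id in profile.characters() else "missing"
    state = profile.states.get(pred.character_id)
    if state is None:
        return "missing"
    return "holds" if state.state in pred.allowed_states() else "fails"


def terminal_profile(ds: ReferenceDataset, key: Key,
                     terminal: str) -> Optional[RangeProfile]:
    """Profile backing a terminal; genus terminals map to their type species
    where one is in the dataset (Richardsaphis -> canadensis)."""
    taxon = terminal
    if key.terminals_are_genera:
        by_genus = {t.genus: t.species for t in ds.taxa.values()}
        taxon = by_genus.get(terminal)
        if taxon is None:
            return None
    return ds.profiles.get(ReferenceDataset.key(taxon, key.morph))


def audit_key(key: Key, ds: ReferenceDataset) -> list[AuditFinding]:
    """Replay the key, terminal by terminal, against each terminal's own
    range profile and report every lead on its path that fails or only
    partially overlaps."""
    findings: list[AuditFinding] = []
    for terminal in key.terminals():
        profile = terminal_profile(ds, key, terminal)
        if profile is None:
            continue
        for cid, lead_name in key.path_to(terminal):
            lead = getattr(key.couplets[cid], lead_name)
            for pred in lead.predicates:
                status = _predicate_vs_profile(pred, profile, ds.layer)
                if status == "holds":
                    continue
                severity = "error" if status == "fails" else "warning"
                findings.append(AuditFinding(
                    severity=severity, taxon=profile.taxon, morph=key.morph,
                    character_id=pred.character_id,
                    message=(f"key {key.id} couplet {cid}{lead_name}: "
                             f"predicate {status} against the profile"),
                    as_printed=lead.as_printed))
    findings.sort(key=lambda f: (f.taxon, f.morph, f.character_id))
    return findings


def path_status(key: Key, ds: ReferenceDataset, terminal: str) -> list[str]:
    """Per-predicate statuses along a terminal's path (audit helper)."""
    profile = terminal_profile(ds, key, terminal)
    if profile is None:
        raise LookupError(f"no profile behind terminal {terminal!r}")
    out = []
    for cid, lead_name in key.path_to(terminal):
        lead = getattr(key.couplets[cid], lead_name)
        for pred in lead.predicates:
            out.append(_predicate_vs_profile(pred, profile, ds.layer))
    return out
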