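"""Seedable synthetic specimens honoring the printed ranges.

The generator draws raw measurements inside the printed table intervals
and, on request, also enforces the description's per-specimen ratio ranges
(``ratio_constrained``) or the conjunction of predicates along a key path
(``path_constrained``).  Joint constraints are handled by:

1. interval constraint propagation (a ratio range R on num/den tightens
   num to R*den and den to num/R), iterated to a near-fixpoint;
2. sampling denominators before numerators, so each numerator can be drawn
   directly inside the intersection of its table interval and its
   ratio-induced interval;
3. per-specimen rejection (capped) for residual conflicts.

BD III — the basal diameter of antennal segment III — has no printed
absolute interval anywhere; it exists in the data only through the
LS III/BD III and HLS/BD III ratios.  Its sampling interval is therefore
derived per profile from those ratios and the absolute seta lengths
(propagation step 1), with a biologically plausible fallback of
0.012–0.035 mm; the derived interval is logged in the generation report.
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from .characters import CharacterKind, Interval, Registry
from .keys import Key
from .ratios import Specimen, ratio_closure
from .reference import RangeProfile, ReferenceDataset

_DEFAULTS = {
    "BD_III": (0.005, 0.040),
    "LS_III": (0.003, 0.040),
    "HLS": (0.004, 0.090),
    "GENITAL_PLATE_SETAE": (2, 20),
}
_GENERIC_LINEAR = (0.001, 3.0)
_GENERIC_COUNT = (0, 40)
_MARGIN = 1e-9  # relative shrink to keep sampled ratios strictly inside bounds


class GenerationError(RuntimeError):
    pass


class GeneratorConfig(BaseModel):
    taxon: str
    morph: str
    n: int = 1
    seed: int = 0
    mode: str = "table_only"  # table_only | ratio_constrained | path_constrained
    key_id: Optional[str] = None
    terminal: Optional[str] = None
    distribution: str = "uniform"  # uniform | truncated_normal
    sd_fraction: float = 0.25
    max_rejections: int = 1000

    def model_post_init(self, __context) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.max_rejections < 1:
            raise ValueError("max_rejections must be >= 1")
        if self.mode not in ("table_only", "ratio_constrained", "path_constrained"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "path_constrained" and not self.terminal:
            raise ValueError("path_constrained mode needs a terminal")


class GenerationReport(BaseModel):
    n_requested: int
    n_emitted: int
    rejections: int
    rejection_rate: float
    derived_intervals: dict[str, tuple[float, float]] = Field(default_factory=dict)
    notes: list[str] = Field(default_factory=list)


class _Constraints:
    """Mutable interval/state constraint store for one generation run."""

    def __init__(self, registry: Registry):
        self.registry = registry
        self.allowed: dict[str, Interval] = {}
        self.exclusions: dict[str, list[Interval]] = {}
        self.states: dict[str, str] = {}
        self.notes: list[str] = []

    def base(self, cid: str) -> Interval:
        if cid in self.allowed:
            return self.allowed[cid]
        lo, hi = _DEFAULTS.get(
            cid,
            _GENERIC_COUNT if self.registry[cid].kind is CharacterKind.count
            else _GENERIC_LINEAR)
        return Interval(lo=float(lo), hi=float(hi))

    def intersect(self, cid: str, lo: float, hi: float, origin: str) -> None:
        hi = min(hi, 1e9)
        new = Interval(lo=lo, hi=hi)
        cur = self.allowed.get(cid)
        merged = new if cur is None else cur.intersect(new)
        if merged is None:
            self.notes.append(
                f"{origin}: constraint [{lo}, {hi}] on {cid} conflicts with "
                f"{cur}; key-path constraint takes precedence")
            merged = new
        self.allowed[cid] = merged

    def exclude(self, cid: str, lo: float, hi: float) -> bool:
        """Register an exclusion; return False if nothing would remain."""
        base = self.base(cid)
        if base.hi < lo or base.lo > hi:
            return True  # already disjoint
        left = (base.lo, min(base.hi, lo)) if base.lo < lo else None
        right = (max(base.lo, hi), base.hi) if base.hi > hi else None
        pieces = [p for p in (left, right) if p is not None and p[0] < p[1]]
        if not pieces:
            return False
        lo2, hi2 = max(pieces, key=lambda p: p[1] - p[0])
        width = hi2 - lo2
        pad = _MARGIN + 1e-4 * width
        if lo2 > base.lo:
            lo2 += pad
        if hi2 < base.hi:
            hi2 -= pad
        self.allowed[cid] = Interval(lo=lo2, hi=hi2)
        return True


def _profile_constraints(cons: _Constraints, profile: RangeProfile,
                         registry: Registry, with_ratios: bool) -> None:
    for cid, entry in profile.entries.items():
        if not entry.valid:
            continue
        kind = registry[cid].kind
        if kind is CharacterKind.ratio and not with_ratios:
            continue
        cons.intersect(cid, entry.lo, entry.hi, f"profile:{cid}")
    for cid, sentry in profile.states.items():
        cons.states.setdefault(cid, sentry.state)


def _lead_is_falsified(cons: _Constraints, pred) -> bool:
    if pred.op in ("eq", "state_in"):
        assigned = cons.states.get(pred.character_id)
        return assigned is not None and assigned not in pred.allowed_states()
    if pred.op == "present":
        return False
    lo, hi = pred.bounds()
    cur = cons.allowed.get(pred.character_id)
    return cur is not None and (cur.hi < lo or cur.lo > hi)


def _path_constraints(cons: _Constraints, key: Key, terminal: str) -> None:
    path = key.path_to(terminal)
    for cid, lead_name in path:
        couplet = key.couplets[cid]
        chosen = getattr(couplet, lead_name)
        sibling = couplet.b if lead_name == "a" else couplet.a
        for pred in chosen.predicates:
            if pred.is_quantitative():
                lo, hi = pred.bounds()
                cons.intersect(pred.character_id, lo, hi,
                               f"{key.id}:{cid}{lead_name}")
            elif pred.op in ("eq", "state_in"):
                wanted = pred.allowed_states()
                cur = cons.states.get(pred.character_id)
                if cur not in wanted:
                    cons.states[pred.character_id] = wanted[0]
        if any(_lead_is_falsified(cons, p) for p in sibling.predicates):
            continue
        # must actively falsify one conjunct of the sibling lead
        done = False
        for pred in sibling.predicates:
            if pred.op in ("eq", "state_in"):
                continue  # states are fixed by the chosen lead
            if pred.op == "present":
                continue
            lo, hi = pred.bounds()
            if cons.exclude(pred.character_id, lo, hi):
                done = True
                break
        if not done:
            raise GenerationError(
                f"cannot construct a specimen separating couplet {cid} "
                f"lead {lead_name} of key {key.id} from its sibling")


def _propagate(cons: _Constraints, registry: Registry,
               rounds: int = 4) -> dict[str, Interval]:
    """Interval propagation across active ratio constraints; returns the
    per-character sampling intervals (raw characters only get entries once
    they participate)."""
    active = [registry[cid] for cid in cons.allowed
              if registry[cid].kind is CharacterKind.ratio]
    intervals: dict[str, Interval] = {}
    for cid in cons.allowed:
        if registry[cid].kind is not CharacterKind.ratio:
            intervals[cid] = cons.allowed[cid]
    for rdef in active:
        for part in (rdef.numerator_id, rdef.denominator_id):
            intervals.setdefault(part, cons.base(part))
    for _ in range(rounds):
        for rdef in active:
            r = cons.allowed[rdef.id]
            num, den = intervals[rdef.numerator_id], intervals[rdef.denominator_id]
            new_num = num.intersect(Interval(lo=r.lo * den.lo, hi=r.hi * den.hi))
            if new_num is None:
                raise GenerationError(
                    f"unsatisfiable: {rdef.id} in {r} forces "
                    f"{rdef.numerator_id} outside {num}")
            new_den = den.intersect(
                Interval(lo=num.lo / r.hi if r.hi > 0 else 0.0,
                         hi=num.hi / r.lo if r.lo > 0 else 1e9))
            if new_den is None:
                raise GenerationError(
                    f"unsatisfiable: {rdef.id} in {r} forces "
                    f"{rdef.denominator_id} outside {den}")
            intervals[rdef.numerator_id] = new_num
            intervals[rdef.denominator_id] = new_den
    return intervals


def _topo_order(chars: list[str], cons: _Constraints,
                registry: Registry) -> list[str]:
    """Denominators before numerators (Kahn); arbitrary order on cycles."""
    active = [registry[cid] for cid in cons.allowed
              if registry[cid].kind is CharacterKind.ratio]
    succ: dict[str, set[str]] = {c: set() for c in chars}
    indeg: dict[str, int] = {c: 0 for c in chars}
    for rdef in active:
        d, n = rdef.denominator_id, rdef.numerator_id
        if d in succ and n in succ and n not in succ[d]:
            succ[d].add(n)
            indeg[n] += 1
    order, queue = [], sorted(c for c in chars if indeg[c] == 0)
    while queue:
        c = queue.pop(0)
        order.append(c)
        for n in sorted(succ[c]):
            indeg[n] -= 1
            if indeg[n] == 0:
                queue.append(n)
    order += sorted(c for c in chars if c not in order)  # cycle fallback
    return order


def _draw(rng: np.random.Generator, interval: Interval, is_count: bool,
          distribution: str, sd_fraction: float) -> Optional[float]:
    if is_count:
        lo, hi = math.ceil(interval.lo - 1e-9), math.floor(interval.hi + 1e-9)
        if lo > hi:
            return None
        return float(rng.integers(lo, hi + 1))
    lo, hi = interval.lo, interval.hi
    if distribution == "truncated_normal" and hi > lo:
        mid, sd = 0.5 * (lo + hi), sd_fraction * 0.5 * (hi - lo)
        for _ in range(100):
            v = rng.normal(mid, sd)
            if lo <= v <= hi:
                return v
        return mid
    return rng.uniform(lo, hi)


def generate(cfg: GeneratorConfig, ds: ReferenceDataset,
             keys: Optional[dict[str, Key]] = None
             ) -> tuple[list[Specimen], GenerationReport]:
    """Generate ``cfg.n`` specimens; same (cfg, dataset) => identical output."""
    registry = ds.registry
    cons = _Constraints(registry)
    profile = ds.profiles.get(ReferenceDataset.key(cfg.taxon, cfg.morph))
    key = None
    if cfg.mode == "path_constrained":
        if keys is None or cfg.key_id not in (keys or {}):
            raise GenerationError(f"path_constrained mode: key {cfg.key_id!r} "
                                  "not supplied")
        key = keys[cfg.key_id]
    if profile is None and cfg.mode != "path_constrained":
        raise GenerationError(f"no profile for ({cfg.taxon}, {cfg.morph})")

    if profile is not None:
        # path mode enforces the key's own ratio bands; layering the
        # description ratio ranges on top can shrink the admissible set to a
        # boundary point when a key band and a description range only touch.
        _profile_constraints(cons, profile, registry,
                             with_ratios=cfg.mode == "ratio_constrained")
    if key is not None:
        _path_constraints(cons, key, cfg.terminal)

    intervals = _propagate(cons, registry)
    derived = {cid: (iv.lo, iv.hi) for cid, iv in intervals.items()
               if cid not in cons.allowed}
    raw_chars = [cid for cid in intervals
                 if registry[cid].kind is not CharacterKind.ratio]
    order = _topo_order(raw_chars, cons, registry)
    active_ratios = [registry[cid] for cid in cons.allowed
                     if registry[cid].kind is CharacterKind.ratio]

    rng = np.random.default_rng(cfg.seed)
    out: list[Specimen] = []
    rejections = 0

    def one_attempt(index: int) -> Optional[Specimen]:
        values: dict[str, float] = {}
        for cid in order:
            iv = intervals[cid]
            for rdef in active_ratios:
                r = cons.allowed[rdef.id]
                if rdef.numerator_id == cid and rdef.denominator_id in values:
                    den = values[rdef.denominator_id]
                    iv2 = iv.intersect(Interval(lo=r.lo * den, hi=r.hi * den))
                    if iv2 is None:
                        return None
                    iv = iv2
                elif rdef.denominator_id == cid and rdef.numerator_id in values:
                    num = values[rdef.numerator_id]
                    iv2 = iv.intersect(Interval(lo=num / r.hi, hi=num / r.lo))
                    if iv2 is None:
                        return None
                    iv = iv2
            if registry[cid].kind is CharacterKind.linear and iv.width > 0:
                pad = _MARGIN + 1e-7 * iv.width
                iv = Interval(lo=iv.lo + pad, hi=iv.hi - pad)
            v = _draw(rng, iv, registry[cid].kind is CharacterKind.count,
                      cfg.distribution, cfg.sd_fraction)
            if v is None:
                return None
            values[cid] = v
        linear = {c: v for c, v in values.items()
                  if registry[c].kind is CharacterKind.linear}
        counts = {c: int(v) for c, v in values.items()
                  if registry[c].kind is CharacterKind.count}
        spec = Specimen(
            id=f"{cfg.taxon}-{cfg.morph}-{cfg.mode}-{index}",
            morph=cfg.morph, linear=linear, counts=counts,
            states=dict(cons.states))
        spec = ratio_closure(spec, registry)
        for rdef in active_ratios:
            r = cons.allowed[rdef.id]
            value = spec.derived.get(rdef.id)
            if value is None or not (r.lo <= value <= r.hi):
                return None
        return spec

    for i in range(cfg.n):
        spec = None
        for _ in range(cfg.max_rejections):
            spec = one_attempt(i)
            if spec is not None:
                break
            rejections += 1
        if spec is None:
            binding = ", ".join(sorted(c.id for c in active_ratios)) or "table ranges"
            raise GenerationError(
                f"({cfg.taxon}, {cfg.morph}, {cfg.mode}): no admissible "
                f"specimen after {cfg.max_rejections} rejections; binding "
                f"constraints: {binding}")
        out.append(spec)

    attempts = len(out) + rejections
    return out, GenerationReport(
        n_requested=cfg.n, n_emitted=len(out), rejections=rejections,
        rejection_rate=rejections / attempts if attempts else 0.0,
        derived_intervals=derived, notes=cons.notes)


def check_satisfiability(ds: ReferenceDataset, taxon: str, morph: str,
                         seed: int = 0, n: int = 5) -> tuple[bool, str]:
    """Dataset health check: are a profile's table ranges and ratio ranges
    jointly satisfiable?  Returns (feasible, message)."""
    cfg = GeneratorConfig(taxon=taxon, morph=morph, n=n, seed=seed,
                          mode="ratio_constrained", max_rejections=2000)
    try:
        generate(cfg, ds)
        return True, "feasible"
    except GenerationError as exc:
        return False, str(exc)


def corrupt(specimens: list[Specimen], missing_fraction: float,
            noise_fraction: float, seed: int,
            noise_sd: float = 0.05) -> list[Specimen]:
    """Degrade specimens: mask characters at ``missing_fraction`` and
    perturb surviving quantitative values multiplicatively (lognormal-ish,
    sd ``noise_sd``) at ``noise_fraction``.  Seeded and reproducible."""
    if not 0 <= missing_fraction <= 1 or not 0 <= noise_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for spec in specimens:
        linear, counts, states = {}, {}, {}
        for cid, v in sorted(spec.linear.items()):
            if rng.random() < missing_fraction:
                continue
            if noise_fraction and rng.random() < noise_fraction:
                v = v * math.exp(rng.normal(0.0, noise_sd))
            linear[cid] = v
        for cid, v in sorted(spec.counts.items()):
            if rng.random() < missing_fraction:
                continue
            if noise_fraction and rng.random() < noise_fraction:
                v = max(0, int(round(v * math.exp(rng.normal(0.0, noise_sd)))))
            counts[cid] = v
        for cid, s in sorted(spec.states.items()):
            if rng.random() < missing_fraction:
                continue
            states[cid] = s
        out.append(spec.model_copy(update={
            "linear": linear, "counts": counts, "states": states,
            "derived": {}}))
    return out
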