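"""Derived ratio characters.

Keys and descriptions work almost entirely in ratios (SIPH/cauda,
PT/BASE, URS/ANT III, ...).  A :class:`Specimen` carries raw values only;
:func:`compute_ratios` derives every registered ratio whose numerator and
denominator are both measured, and :func:`ratio_closure` returns a specimen
augmented with them.  Ratios are computed at full floating precision;
rounding happens only at display time.
"""
from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .characters import CharacterKind, Registry


class Specimen(BaseModel):
    id: str
    morph: str
    linear: dict[str, float] = Field(default_factory=dict)
    counts: dict[str, int] = Field(default_factory=dict)
    states: dict[str, str] = Field(default_factory=dict)
    derived: dict[str, float] = Field(default_factory=dict)
    metadata: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "Specimen":
        for name, mapping in (("linear", self.linear), ("counts", self.counts)):
            for cid, v in mapping.items():
                if v < 0:
                    raise ValueError(f"{self.id}: negative {name} value {cid}={v}")
        return self

    def value(self, cid: str) -> Optional[float]:
        """Raw or derived quantitative value, None when missing."""
        if cid in self.linear:
            return self.linear[cid]
        if cid in self.counts:
            return float(self.counts[cid])
        if cid in self.derived:
            return self.derived[cid]
        return None

    def present_characters(self) -> set[str]:
        return (set(self.linear) | set(self.counts) | set(self.states)
                | set(self.derived))


class RatioResult(BaseModel):
    values: dict[str, float]
    errors: dict[str, str] = Field(default_factory=dict)


def compute_ratios(specimen: Specimen, registry: Registry) -> RatioResult:
    """Compute all registered ratios computable from the specimen's raw values.

    A ratio is emitted only when both parts are present and the denominator
    is positive; a zero denominator is recorded as a per-ratio error and
    does not affect the other ratios.  Missing parts simply yield no entry.
    """
    for cid in list(specimen.linear) | specimen.counts.keys():
        if cid in registry and registry[cid].kind is CharacterKind.ratio:
            raise ValueError(f"ratio id {cid} supplied as a raw measurement")
    values: dict[str, float] = {}
    errors: dict[str, str] = {}
    for rdef in registry.ratios():
        num = specimen.value(rdef.numerator_id)
        den = specimen.value(rdef.denominator_id)
        if num is None or den is None:
            continue
        if den == 0:
            errors[rdef.id] = f"denominator {rdef.denominator_id} is 0"
            continue
        values[rdef.id] = num / den
    return RatioResult(values=values, errors=errors)


def ratio_closure(specimen: Specimen, registry: Registry) -> Specimen:
    """Return the specimen augmented with all computable ratios (idempotent)."""
    result = compute_ratios(specimen, registry)
    return specimen.model_copy(update={"derived": result.values})


def display_ratio(value: float, decimals: int = 3) -> float:
    """Ratios are reported to 3 decimals for display; comparisons always use
    the full-precision value."""
    return round(value, decimals)
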