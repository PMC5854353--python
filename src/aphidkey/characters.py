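"""Character registry: the measurable, countable, derived and categorical
characters used in aphid descriptions and keys.

Characters are identified by short tokens modelled on the conventional
abbreviations of aphid taxonomy (BL = body length, HW = head width across
the compound eyes, ANT_III = third antennal segment, URS = ultimate rostral
segment, SIPH = siphunculus, ...).  Ratio characters are first-class
registry entries that name their numerator and denominator, e.g.
``SIPH_CAUDA`` = SIPH / CAUDA, the classic siphunculus-to-cauda ratio.
"""
from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator


class CharacterKind(str, Enum):
    linear = "linear"
    count = "count"
    ratio = "ratio"
    categorical = "categorical"


class Interval(BaseModel):
    """A closed interval [lo, hi]; the printed "a–b" span of a description."""

    lo: float
    hi: float

    @model_validator(mode="after")
    def _check(self) -> "Interval":
        if self.lo > self.hi:
            raise ValueError(f"interval lo {self.lo} > hi {self.hi}")
        if self.lo < 0:
            raise ValueError(f"interval lo {self.lo} < 0")
        return self

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi

    def intersect(self, other: "Interval") -> Optional["Interval"]:
        lo, hi = max(self.lo, other.lo), min(self.hi, other.hi)
        if lo > hi:
            return None
        return Interval(lo=lo, hi=hi)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.lo}, {self.hi}]"


class CharacterDef(BaseModel):
    id: str
    name: str
    kind: CharacterKind
    unit: str = ""
    numerator_id: Optional[str] = None
    denominator_id: Optional[str] = None
    allowed_states: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "CharacterDef":
        if self.kind is CharacterKind.ratio:
            if not (self.numerator_id and self.denominator_id):
                raise ValueError(f"{self.id}: ratio without numerator/denominator")
        elif self.numerator_id or self.denominator_id:
            raise ValueError(f"{self.id}: numerator/denominator on non-ratio")
        if self.kind is CharacterKind.categorical:
            if not self.allowed_states:
                raise ValueError(f"{self.id}: categorical without allowed states")
        elif self.allowed_states:
            raise ValueError(f"{self.id}: states on non-categorical")
        if self.kind is CharacterKind.linear and self.unit != "mm":
            raise ValueError(f"{self.id}: linear characters are in mm")
        return self


class Registry(BaseModel):
    """Immutable lookup of character definitions, keyed by id."""

    characters: dict[str, CharacterDef]

    @classmethod
    def from_list(cls, defs: list[CharacterDef]) -> "Registry":
        seen: dict[str, CharacterDef] = {}
        for d in defs:
            if d.id in seen:
                raise ValueError(f"duplicate character id {d.id}")
            seen[d.id] = d
        reg = cls(characters=seen)
        # ratio parts must resolve to non-ratio characters
        for d in defs:
            if d.kind is CharacterKind.ratio:
                for part in (d.numerator_id, d.denominator_id):
                    if part not in seen:
                        raise ValueError(f"{d.id}: unknown ratio part {part}")
                    if seen[part].kind is CharacterKind.ratio:
                        raise ValueError(f"{d.id}: ratio part {part} is itself a ratio")
        return reg

    def __contains__(self, cid: str) -> bool:
        return cid in self.characters

    def __getitem__(self, cid: str) -> CharacterDef:
        try:
            return self.characters[cid]
        except KeyError:
            raise KeyError(f"unknown character id {cid!r}") from None

    def ratios(self) -> list[CharacterDef]:
        return [c for c in self.characters.values() if c.kind is CharacterKind.ratio]

    def of_kind(self, kind: CharacterKind) -> list[CharacterDef]:
        return [c for c in self.characters.values() if c.kind is kind]
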