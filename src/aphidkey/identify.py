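"""Multi-access (matrix) interval identification.

Instead of walking a key, a specimen is scored against every range profile
of its morph: each character present in both specimen and profile yields a
verdict ("in" when the value lies in the closed profile interval, or the
state token matches; "out" otherwise), and the score is the fraction of
"in" verdicts.  Candidates are ranked by score; profiles sharing too few
characters with the specimen are reported as insufficient rather than
ranked.  Because printed ranges overlap heavily between congeners, a top
score is a membership statement, not a proof of identity.
"""
from __future__ import annotations

from pydantic import BaseModel, Field

from .characters import CharacterKind
from .ratios import Specimen
from .reference import RangeProfile, ReferenceDataset

#: minimum shared characters for a candidate to be ranked at all;
#: a one-character match is taxonomically meaningless.
MIN_CHARACTERS = 3


class ScoringError(ValueError):
    pass


class CandidateScore(BaseModel):
    taxon: str
    score: float
    n_evaluated: int
    verdicts: dict[str, str]  # character -> "in" | "out"


class IdentificationResult(BaseModel):
    morph: str
    specimen_id: str
    ranked: list[CandidateScore]
    warnings: list[str] = Field(default_factory=list)

    def top_taxa(self) -> list[str]:
        if not self.ranked:
            return []
        best = self.ranked[0].score
        return [c.taxon for c in self.ranked if c.score == best]


def score_profile(specimen: Specimen,
                  profile: RangeProfile) -> tuple[float, dict[str, str]]:
    """Score one specimen against one profile of the same morph.

    Returns (|in| / |evaluable|, per-character verdicts).  Raises
    :class:`ScoringError` when specimen and profile share no characters.
    """
    if specimen.morph != profile.morph:
        raise ScoringError(
            f"specimen morph {specimen.morph!r} != profile morph "
            f"{profile.morph!r}")
    verdicts: dict[str, str] = {}
    for cid, entry in profile.entries.items():
        if not entry.valid:
            continue
        value = specimen.value(cid)
        if value is None:
            continue
        verdicts[cid] = "in" if entry.lo <= value <= entry.hi else "out"
    for cid, sentry in profile.states.items():
        state = specimen.states.get(cid)
        if state is None:
            continue
        verdicts[cid] = "in" if state == sentry.state else "out"
    if not verdicts:
        raise ScoringError(
            f"specimen {specimen.id} shares no characters with profile "
            f"{profile.taxon}/{profile.morph}")
    n_in = sum(1 for v in verdicts.values() if v == "in")
    return n_in / len(verdicts), verdicts


def identify(specimen: Specimen, ds: ReferenceDataset, morph: str,
             min_characters: int = MIN_CHARACTERS) -> IdentificationResult:
    """Rank every profile of the given morph against the specimen.

    Profiles with fewer than ``min_characters`` evaluable characters are
    listed in warnings, not ranked.  Ties are broken alphabetically.
    """
    profiles = ds.profiles_of_morph(morph)
    if not profiles:
        available = sorted({p.morph for p in ds.profiles.values()})
        raise ScoringError(f"no profiles for morph {morph!r}; available: "
                           f"{available}")
    ranked: list[CandidateScore] = []
    warnings: list[str] = []
    for profile in profiles:
        try:
            score, verdicts = score_profile(specimen, profile)
        except ScoringError:
            warnings.append(f"{profile.taxon}: no shared characters")
            continue
        if len(verdicts) < min_characters:
            warnings.append(
                f"{profile.taxon}: insufficient data "
                f"({len(verdicts)} < {min_characters} characters)")
            continue
        ranked.append(CandidateScore(taxon=profile.taxon, score=score,
                                     n_evaluated=len(verdicts),
                                     verdicts=verdicts))
    ranked.sort(key=lambda c: (-c.score, c.taxon))
    return IdentificationResult(morph=morph, specimen_id=specimen.id,
                                ranked=ranked, warnings=warnings)


def midpoint_specimen(profile: RangeProfile, ds: ReferenceDataset,
                      specimen_id: str = "") -> Specimen:
    """The idealized specimen sitting at the midpoint of every raw (table)
    interval of a profile, with the profile's categorical states.

    Ratio characters are left to :func:`aphidkey.ratios.ratio_closure`;
    only raw linear and count characters are materialized.
    """
    linear: dict[str, float] = {}
    counts: dict[str, int] = {}
    for cid, entry in profile.entries.items():
        if not entry.valid:
            continue
        kind = ds.registry[cid].kind
        if kind is CharacterKind.linear:
            linear[cid] = entry.interval().midpoint
        elif kind is CharacterKind.count:
            mid = entry.interval().midpoint
            value = int(round(mid))
            value = min(max(value, int(entry.lo)), int(entry.hi))
            counts[cid] = value
    states = {cid: s.state for cid, s in profile.states.items()}
    return Specimen(id=specimen_id or f"mid-{profile.taxon}-{profile.morph}",
                    morph=profile.morph, linear=linear, counts=counts,
                    states=states)
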