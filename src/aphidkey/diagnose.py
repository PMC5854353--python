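"""Pairwise diagnosability: which characters separate which species pairs.

The printed Diagnosis paragraphs argue species apart by citing characters
whose ranges do not overlap ("URS/ANT III 0.70–0.87 (0.32–0.51 in
M. turanica)").  This module systematizes that argument: for every pair of
profiles of one morph it enumerates the shared characters and reports the
ones whose intervals are disjoint, with the gap between them.  A shared
endpoint counts as overlap — a specimen sitting exactly on the boundary is
genuinely ambiguous — so diagnosability here is conservative.
"""
from __future__ import annotations

from itertools import combinations
from typing import Optional

from pydantic import BaseModel, Field

from .characters import Interval
from .reference import ReferenceDataset


class DiagnosisError(ValueError):
    pass


def disjoint(a: Interval, b: Interval) -> tuple[bool, float]:
    """Strict disjointness and the gap between the nearer endpoints.

    Intervals touching at an endpoint are NOT disjoint (gap 0).
    """
    if a.hi < b.lo:
        return True, b.lo - a.hi
    if b.hi < a.lo:
        return True, a.lo - b.hi
    return False, 0.0


class Discriminator(BaseModel):
    character_id: str
    kind: str  # "interval" | "state"
    interval_a: Optional[Interval] = None
    interval_b: Optional[Interval] = None
    state_a: Optional[str] = None
    state_b: Optional[str] = None
    gap: float
    relative_gap: float


class DiagnosisReport(BaseModel):
    morph: str
    taxon_a: str
    taxon_b: str
    discriminators: list[Discriminator]
    n_overlapping: int
    verdict: str  # "diagnosable" | "not-diagnosable-on-encoded-characters"

    def characters(self) -> list[str]:
        return [d.character_id for d in self.discriminators]


def diagnose_pair(ds: ReferenceDataset, taxon_a: str, taxon_b: str,
                  morph: str) -> DiagnosisReport:
    """Disjoint-interval analysis of one unordered species pair.

    Quantitative characters discriminate when their intervals are strictly
    disjoint; categorical characters when the state tokens differ.
    Discriminators are sorted by descending relative gap
    (gap / pooled span of the pair), ties alphabetically.
    """
    taxon_a, taxon_b = sorted((taxon_a, taxon_b))
    pa = ds.profile(taxon_a, morph)
    pb = ds.profile(taxon_b, morph)
    discriminators: list[Discriminator] = []
    n_overlapping = 0
    for cid in sorted(set(pa.entries) & set(pb.entries)):
        ea, eb = pa.entries[cid], pb.entries[cid]
        if not (ea.valid and eb.valid):
            continue
        ia, ib = ea.interval(), eb.interval()
        is_disjoint, gap = disjoint(ia, ib)
        if not is_disjoint:
            n_overlapping += 1
            continue
        pooled = max(ia.hi, ib.hi) - min(ia.lo, ib.lo)
        discriminators.append(Discriminator(
            character_id=cid, kind="interval", interval_a=ia, interval_b=ib,
            gap=gap, relative_gap=gap / pooled if pooled > 0 else 1.0))
    for cid in sorted(set(pa.states) & set(pb.states)):
        sa, sb = pa.states[cid].state, pb.states[cid].state
        if sa == sb:
            n_overlapping += 1
            continue
        discriminators.append(Discriminator(
            character_id=cid, kind="state", state_a=sa, state_b=sb,
            gap=1.0, relative_gap=1.0))
    discriminators.sort(key=lambda d: (-d.relative_gap, d.character_id))
    if taxon_a == taxon_b:
        discriminators, n_overlapping = [], n_overlapping
    verdict = ("diagnosable" if discriminators
               else "not-diagnosable-on-encoded-characters")
    return DiagnosisReport(morph=morph, taxon_a=taxon_a, taxon_b=taxon_b,
                           discriminators=discriminators,
                           n_overlapping=n_overlapping, verdict=verdict)


def pairwise_count(ds: ReferenceDataset, morph: str, character_id: str,
                   genus: Optional[str] = None) -> int:
    """Number of unordered profile pairs whose intervals for one character
    are strictly disjoint; optionally restricted to one genus."""
    carriers = [(p.taxon, p.entries[character_id].interval())
                for p in ds.profiles_of_morph(morph)
                if character_id in p.entries
                and p.entries[character_id].valid
                and (genus is None or ds.taxa[p.taxon].genus == genus)]
    if len(carriers) < 2:
        raise DiagnosisError(
            f"character {character_id} carried by {len(carriers)} profile(s) "
            f"of morph {morph}; need at least 2")
    return sum(1 for (_, ia), (_, ib) in combinations(carriers, 2)
               if disjoint(ia, ib)[0])


def full_matrix(ds: ReferenceDataset, morph: str) -> list[DiagnosisReport]:
    taxa = [p.taxon for p in ds.profiles_of_morph(morph)]
    return [diagnose_pair(ds, a, b, morph) for a, b in combinations(taxa, 2)]
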