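# Methods

## The knowledge base

The unit of reference data is a closed interval `[lo, hi]` attached to one
taxon × morph × character cell, carrying its provenance tag (`T1`–`T6` for
the measurement tables, `D` for a description paragraph, `K:<key>` for a
value only stated inside a key couplet, `S` for genus-level shared
characters) and the verbatim printed string (`as_printed`, en-dashes
preserved).  Characters are registered once, with a kind:

* `linear` — lengths in mm, stored exactly as printed (2–3 decimals);
* `count` — integers (rhinaria, pseudosensoria, setae, antennal segments);
* `ratio` — derived characters naming numerator and denominator (both
  non-ratio); e.g. `SIPH_CAUDA = SIPH / CAUDA`;
* `categorical` — closed vocabularies (frontal tubercle
  absent/rounded/quadrate/rectangular, siphunculus form, etc.).

Single printed values (n = 1 columns, "PT 0.10") become degenerate
intervals `[x, x]`.  "about X" phrasings become `[0.95·X, 1.05·X]`
(`ABOUT_TOLERANCE = 0.05`): the source gives no precision, and ±5% spans
neighbouring printed ranges without merging key leads.

Two notational conventions had to be fixed while transcribing:

* "ANT a–b × HW" in the descriptions denotes **HW/ANT** (checking the
  quotients of the table endpoints makes this unambiguous, and the
  diagnosis texts say "ratio of HW/ANT" for the same numbers);
* in 5-segmented morphs the last segment is ANT V, but the source
  sometimes labels last-segment ratios "× ANT VI".  Each such entry is
  encoded under the character id the corresponding key couplet uses, and
  the dataset audit flags ANT VI-based characters on 5-segmented profiles
  as warnings.

### Data layers

The **as-printed** layer is a faithful transcription including its
anomalies (an inverted "0.3–0.20" span, an antennal segment "0.08–1.10"
exceeding its own antenna, a whole-antenna range equal to the ANT III
range).  The **curated** layer applies the corrections listed in
`data/curated.csv`, one per line with its justification; three kinds:

* `replace` — obvious typographic slips (decimal shifts, dropped digits,
  inverted bounds) restored from internal evidence;
* `replace` (rounding) — lengths printed at 0.01 mm hide up to half a unit
  of rounding; where a printed ratio range is provably incompatible with
  the degenerate table values it summarizes (e.g. a printed URS/HT II
  0.82–0.87 against URS = 0.07 and HT II = 0.08, quotient exactly 0.875),
  the affected lengths get their half-unit rounding width back
  (±0.005 mm).  The generator's satisfiability check (below) is what
  detects these cases;
* `drop` / `remap` — entries that cannot be reconciled at all (left
  absent) or whose segment label is demonstrably slipped.

All analysis defaults to the curated layer; the audit in the test suite
runs on the as-printed layer and must rediscover the anomalies.

One key couplet is also layered: the alate key's final couplet prints
ANT IV/ANT III 1.00–1.45 for *M. bucktoni*, unreachable after the previous
couplet (0.33–0.46) and contradicting the species description (0.40–0.46);
the curated bounds use the description range, the as-printed bounds remain
in the key file and fail the key audit, as they should.

## The consistency audit

`validate_dataset` is deterministic and ordered by (taxon, morph,
character): interval orientation (`lo ≤ hi`), non-negativity, count
integrality, a 5 mm unit-sanity bound on lengths (largest printed body is
2.60 mm), part-vs-whole plausibility (no antennal segment may exceed the
whole antenna), and BASE + PT versus the last antennal segment (with a
1e-6 tolerance absorbing float rounding of sums of 2-decimal values).
Findings are values, not exceptions; `error` marks impossible data,
`warning` marks suspicious-but-usable data (including a reminder for every
curated override applied).

## Keys

Keys are data (JSON), never code: couplets with two leads, each lead a
conjunction of predicates `(character, op, bounds/states)` with
`op ∈ {in, le, ge, eq, state_in, present}`.  Predicate intervals are
closed; "X or less"/"X or more" become `[0, X]` / `[X, ∞)`.  Structural
validation (acyclicity from the root, reachability, two leads per couplet,
registered characters, resolvable terminals) happens at load time.

Traversal verdicts per couplet: follow `a` on (true, false), `b` on
(false, true), **both** on (true, true) or any unknown, **neither** on
(false, false).  Branching on unknowns is deliberate: a key is a routing
device, and pretending that a missing character resolves a couplet would
convert ignorance into error.  Consequently a specimen with no characters
at all returns every terminal.

The key audit replays each key against the range profile of each of its
own terminals, interval-wise: a predicate *holds* if the profile interval
is contained in the predicate interval, *fails* if disjoint, *partial*
otherwise.  Partial overlaps are common (the keys often quote slightly
narrower ranges than the descriptions) and are reported as warnings.

## Interval identification

`score_profile` evaluates every character present in both specimen and
profile: "in" iff the value lies in the closed interval (or the state
matches), score = |in| / |evaluable|.  Candidates sharing fewer than
`min_characters = 3` characters with the specimen are reported as
insufficient, not ranked; a one-character match is taxonomically
meaningless.  Categorical mismatches weigh the same as quantitative ones;
no information-content weighting is attempted in this version.  Ratio
characters are scored only against description-derived ratio ranges —
quotients of table endpoints deliberately are **not** used as bounds,
because the ratio of two column extremes overstates the per-specimen
ratio range.  Because printed ranges of congeners overlap broadly, a top
score asserts membership in the plausible set, not uniqueness; the tests
therefore check top-set membership, never sole-winner rank.

## Diagnosability

`disjoint` is strict: intervals touching at an endpoint are *not* disjoint
(gap 0) — a specimen sitting on the shared boundary is genuinely
ambiguous.  `diagnose_pair` enumerates characters shared by both profiles,
lists the disjoint ones with absolute gap and relative gap
(gap / pooled span of the pair), and treats categorical characters as
discriminating iff the state tokens differ (reported with gap 1.0).
`pairwise_count` is the brute-force pair count for a single character,
optionally restricted to one genus.

## Synthetic specimens

`generate` draws raw values inside the profile intervals, in three modes:

* `table_only` — raw table ranges and states only;
* `ratio_constrained` — additionally every encoded ratio range must hold
  per specimen.  Implementation: (1) interval constraint propagation
  (num ← R·den, den ← num/R, a few rounds to near-fixpoint); (2) sampling
  in dependency order, denominators before numerators, so each numerator
  is drawn directly inside table-range ∩ ratio-induced range; (3) a
  per-specimen rejection loop (default cap 1000) for residual conflicts.
  Sampled linear intervals are shrunk by a ~1e-7 relative margin so
  float rounding cannot push a derived ratio epsilon outside a closed
  bound;
* `path_constrained(key, terminal)` — the conjunction of the chosen leads
  along the path to a terminal, intersected with the raw table intervals;
  at each couplet one conjunct of the sibling lead is actively falsified
  (by state conflict, or by excluding the sibling's interval from the
  sampling range) so traversal lands on exactly the requested terminal.
  Description ratio ranges are not layered on top in this mode: where a
  key band and a description range only touch at a point, their
  intersection has measure zero and the mode's contract is the key path,
  not the description.

BD III (basal articular diameter of ANT III) has no printed absolute
interval anywhere; it exists only inside the LS III/BD III and HLS/BD III
ratios.  Its sampling interval is derived per profile by the same
propagation step from the absolute seta lengths and the printed ratio
bands, with a fallback of 0.005–0.040 mm, and is logged in the generation
report.  Unsatisfiable constraint systems raise an error naming the
binding constraints; `check_satisfiability` exposes this as a per-profile
dataset health check (all 34 bundled profiles pass on the curated layer).

Distributions: uniform (default) or truncated normal centred at the
interval midpoint with sd = `sd_fraction` × half-width, clipped by
resampling.  `corrupt` masks characters Bernoulli(missing_fraction) and
perturbs surviving values multiplicatively with lognormal noise
(sd 0.05 by default) at `noise_fraction`; everything is driven by a single
integer seed, and identical (config, dataset) pairs give identical output.

### What the generator does and does not emulate

Synthetic specimens honour the printed marginal ranges and ratio ranges,
which is exactly what the identification logic consumes.  They do **not**
model allometric covariance between characters (no covariance is
published), measurement error, preparation artefacts, or geographic
variation.  Passing round trips therefore certify the internal coherence
of the knowledge base and the correctness of the engines — not field-level
identification accuracy on real material.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses 3 path-constrained specimens per key terminal
(38 terminals across the six keys), 100 ratio-constrained specimens per
profile (34 profiles) for the matrix round trip, and 20 specimens per
profile with half the characters masked for the degradation rate; the
whole script completes in a few seconds on one CPU.

## Known limitations

* The curated layer resolves printed inconsistencies by explicit,
  per-entry judgement; other readings are possible and the as-printed
  layer is retained precisely so they can be re-derived.
* Frontal-tubercle seta length is mapped onto the head-longest-seta
  character (HLS is defined on the median frontal tubercle); where a key
  quotes tubercle-seta bounds narrower than a species' full HLS range the
  key audit reports partial overlap rather than failure.
* The genera key beyond *Richardsaphis* is backed by couplet states only
  (no measurement tables exist for the other genera), so those terminals
  are exercised by path-constrained specimens, not by profiles.
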