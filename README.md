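# aphidkey

An identification engine for the rose-feeding aphid genus *Myzaphis* and its
close allies (*Richardsaphis canadensis*, *Ericaphis avariolosa*), built on an
interval knowledge base of their published morphometry.

Rose aphids are told apart not by single measurements but by morphometric
*ratio* characters — SIPH/cauda (siphunculus to cauda length), PT/BASE
(terminal process to base of the last antennal segment), URS/ANT III
(ultimate rostral segment to third antennal segment) — together with counts
(secondary rhinaria, pseudosensoria on the hind tibiae of oviparae, caudal
setae, first-tarsal chaetotaxy 5-5-5 vs 2-2-2) and a handful of categorical
states (frontal-tubercle shape, siphunculus form, pleural stripes).  Every
published statement of the form "URS/ANT III 0.70–0.87 (0.32–0.51 in
*M. turanica*)" is an interval-disjointness argument; `aphidkey` makes those
intervals, and all the logic built on them, machine-checkable.

## What's inside

* **Reference dataset** (`aphidkey.reference`) — one row per taxon × morph ×
  character transcribed from the published measurement tables (fundatrices,
  apterous and alate viviparous females, oviparae, males, plus the four
  *R. canadensis* morphs; 34 profiles) and from the description paragraphs
  (ratio ranges, seta lengths, counts, states).  Two layers: `as_printed`
  (verbatim, typos included) and `curated` (documented corrections,
  `data/curated.csv`).  `validate_dataset` audits either layer and
  rediscovers the printed anomalies deterministically.
* **Ratio engine** (`aphidkey.ratios`) — derives every registered ratio from
  a specimen's raw measurements; scale-invariant, missing-data aware.
* **Key engine** (`aphidkey.keys`) — the six dichotomous keys (fundatrices,
  apterae, alatae, oviparae, males, and the Macrosiphini genera with 2-2-2
  first-tarsal chaetotaxy) as data files with executable predicates;
  traversal with explicit ambiguity semantics (unknown or doubly-true
  couplets branch to both leads) and an audit that replays each key against
  the profiles of its own terminals.
* **Interval identifier** (`aphidkey.identify`) — multi-access
  identification: a specimen is scored against every profile of its morph
  by interval containment.
* **Diagnosability** (`aphidkey.diagnose`) — pairwise disjoint-interval
  analysis reproducing the published Diagnosis arguments, with gaps and
  relative gaps; shared endpoints count as overlap.
* **Synthetic specimens** (`aphidkey.simulate`) — seeded generation of
  specimens inside the printed intervals, optionally constrained by the
  printed ratio ranges (rejection sampling with constraint propagation) or
  by a key path, plus a `corrupt` step for missing-data experiments.

## Worked example

A female caught on a rose in October: egg-laying morph, swollen dark hind
tibiae with 72 pseudosensoria, 6-segmented antennae.

```csv
id,morph,ANT_SEGMENTS,PSEUDOSENSORIA,TIBIA_III_SWELLING,PT,BASE,ANT_III,ANT_IV,ANT_V,URS,HT_II
ov1,ovipara,6,72,swollen,0.09,0.08,0.14,0.07,0.07,0.07,0.08
```

```sh
$ aphidkey keyrun ex.csv --key-id oviparae
terminals: ['oezdemirae']        trace: 1b -> 3b -> 4b
$ aphidkey identify ex.csv --morph ovipara
oezdemirae   0.882  (17 characters)
rosarum      0.778  (18 characters)
bucktoni     0.278  (18 characters)
turanica     0.263  (19 characters)
```

The key walks couplet 1 (6-segmented antennae) → 3 (ANT V/ANT III = 0.50)
→ 4, where 72 pseudosensoria on swollen tibiae settle it: *M. oezdemirae*.
The matrix identifier agrees: 88% of the 17 characters it could evaluate sit
inside the *M. oezdemirae* oviparous ranges, comfortably ahead of
*M. rosarum* (whose oviparae carry 20–52 pseudosensoria).  Asking why the
two species are separable at all:

```sh
$ aphidkey diagnose --morph ovipara --pair oezdemirae,turanica
verdict: diagnosable
ANT_SEGMENTS         gap 1.0   (6 vs 5)
TIBIA_III_SWELLING   gap 1.0   (swollen vs not-swollen)
ANT_V_ANT_III        gap 0.40  (0.48-0.50 vs 0.90-1.03)
...
```

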