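{
  "id": "males",
  "name": "Key to known males",
  "morph": "male",
  "root": "1",
  "couplets": {
    "1": {
      "a": {"predicates": [
             {"character_id": "WINGS", "op": "eq", "state": "present"},
             {"character_id": "ANT_IV_ANT_III", "op": "in", "lo": 0.51, "hi": 0.59}],
            "taxon": "oezdemirae",
            "as_printed": "Wings present; ANT IV/ANT III 0.51–0.59"},
      "b": {"predicates": [
             {"character_id": "WINGS", "op": "eq", "state": "absent"},
             {"character_id": "ANT_IV_ANT_III", "op": "in", "lo": 0.32, "hi": 0.48}],
            "next": "2",
            "as_printed": "Wings absent; ANT IV/ANT III 0.32–0.48"}
    },
    "2": {
      "a": {"predicates": [
             {"character_id": "ANT_SEGMENTS", "op": "in", "lo": 5, "hi": 5},
             {"character_id": "PT_BASE", "op": "in", "lo": 0.58, "hi": 1.37}],
            "next": "3",
            "as_printed": "ANT 5-segmented; PT/BASE 0.58–1.37"},
      "b": {"predicates": [
             {"character_id": "ANT_SEGMENTS", "op": "in", "lo": 6, "hi": 6},
             {"character_id": "PT_BASE", "op": "in", "lo": 1.42, "hi": 2.05}],
            "next": "4",
            "as_printed": "ANT 6-segmented; PT/BASE 1.42–2.05"}
    },
    "3": {
      "a": {"predicates": [
             {"character_id": "PT_BASE", "op": "in", "lo": 0.58, "hi": 0.81},
             {"character_id": "ANT_V_ANT_III", "op": "in", "lo": 0.62, "hi": 0.63},
             {"character_id": "URS_ANT_V", "op": "in", "lo": 0.65, "hi": 0.70}],
            "taxon": "rezwanii",
            "as_printed": "PT/BASE 0.58–0.81; ANT V/ANT III 0.62–0.63; URS/ANT V 0.65–0.70"},
      "b": {"predicates": [
             {"character_id": "PT_BASE", "op": "in", "lo": 1.20, "hi": 1.37},
             {"character_id": "ANT_V_ANT_III", "op": "in", "lo": 0.78, "hi": 0.86},
             {"character_id": "URS_ANT_V", "op": "in", "lo": 0.26, "hi": 0.31}],
            "taxon": "turanica",
            "as_printed": "PT/BASE 1.20–1.37; ANT V/ANT III 0.78–0.86; URS/ANT V 0.26–0.31"}
    },
    "4": {
      "a": {"predicates": [
             {"character_id": "RHIN_ANT_III", "op": "in", "lo": 17, "hi": 30},
             {"character_id": "RHIN_ANT_IV", "op": "in", "lo": 2, "hi": 6},
             {"character_id": "ANT_BL", "op": "in", "lo": 0.70, "hi": 0.85}],
            "taxon": "rosarum",
            "as_printed": "ANT III with 17–30, ANT IV with 2–6 secondary rhinaria; ANT/BL 0.70–0.85"},
      "b": {"predicates": [
             {"character_id": "RHIN_ANT_III", "op": "in", "lo": 5, "hi": 15},
             {"character_id": "RHIN_ANT_IV", "op": "in", "lo": 0, "hi": 1},
             {"character_id": "ANT_BL", "op": "in", "lo": 0.61, "hi": 0.64}],
            "taxon": "bucktoni",
            "as_printed": "ANT III with 5–15, ANT IV with 0–1 secondary rhinaria; ANT/BL 0.61–0.64"}
    }
  }
}
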