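{
  "id": "oviparae",
  "name": "Key to known oviparous females",
  "morph": "ovipara",
  "root": "1",
  "couplets": {
    "1": {
      "a": {"predicates": [
             {"character_id": "ANT_SEGMENTS", "op": "in", "lo": 5, "hi": 5}],
            "next": "2",
            "as_printed": "ANT 5-segmented"},
      "b": {"predicates": [
             {"character_id": "ANT_SEGMENTS", "op": "in", "lo": 6, "hi": 6}],
            "next": "3",
            "as_printed": "ANT 6-segmented"}
    },
    "2": {
      "a": {"predicates": [
             {"character_id": "PT_BASE", "op": "in", "lo": 0.66, "hi": 1.00},
             {"character_id": "URS_HT_II", "op": "in", "lo": 1.00, "hi": 1.15},
             {"character_id": "URS_ANT_V", "op": "in", "lo": 0.60, "hi": 0.83}],
            "taxon": "rezwanii",
            "as_printed": "PT/BASE 0.66–1.00; URS/HT II 1.00–1.15; URS/ANT V 0.60–0.83"},
      "b": {"predicates": [
             {"character_id": "PT_BASE", "op": "in", "lo": 1.20, "hi": 1.37},
             {"character_id": "URS_HT_II", "op": "in", "lo": 0.70, "hi": 0.75},
             {"character_id": "URS_ANT_VI", "op": "in", "lo": 0.35, "hi": 0.36}],
            "taxon": "turanica",
            "as_printed": "PT/BASE 1.20–1.37; URS/HT II 0.70–0.75; URS/ANT VI 0.35–0.36"}
    },
    "3": {
      "a": {"predicates": [
             {"character_id": "ANT_V_ANT_III", "op": "in", "lo": 0.33, "hi": 0.40},
             {"character_id": "ANT_IV_ANT_III", "op": "in", "lo": 0.33, "hi": 0.40}],
            "taxon": "bucktoni",
            "as_printed": "ANT V/ANT III 0.33–0.40; ANT IV/ANT III 0.33–0.40"},
      "b": {"predicates": [
             {"character_id": "ANT_V_ANT_III", "op": "in", "lo": 0.48, "hi": 0.62},
             {"character_id": "ANT_IV_ANT_III", "op": "in", "lo": 0.43, "hi": 0.57}],
            "next": "4",
            "as_printed": "ANT V/ANT III 0.48–0.62; ANT IV/ANT III 0.43–0.57"}
    },
    "4": {
      "a": {"predicates": [
             {"character_id": "PSEUDOSENSORIA", "op": "in", "lo": 20, "hi": 52},
             {"character_id": "ANT_V_ANT_III", "op": "in", "lo": 0.54, "hi": 0.62}],
            "taxon": "rosarum",
            "as_printed": "TIBIAE III with 20–52 pseudosensoria; ANT V/ANT III 0.54–0.62"},
      "b": {"predicates": [
             {"character_id": "PSEUDOSENSORIA", "op": "in", "lo": 61, "hi": 80},
             {"character_id": "ANT_V_ANT_III", "op": "in", "lo": 0.48, "hi": 0.50}],
            "taxon": "oezdemirae",
            "as_printed": "TIBIAE III with 61–80 pseudosensoria; ANT V/ANT III 0.48–0.50"}
    }
  }
}
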