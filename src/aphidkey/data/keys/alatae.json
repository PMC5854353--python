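{
  "id": "alatae",
  "name": "Key to known alate viviparous females",
  "morph": "alata",
  "root": "1",
  "couplets": {
    "1": {
      "a": {"predicates": [
             {"character_id": "PT_BASE", "op": "in", "lo": 0.60, "hi": 0.75},
             {"character_id": "URS_ANT_III", "op": "in", "lo": 0.33, "hi": 0.34},
             {"character_id": "HT_II_ANT_III", "op": "in", "lo": 0.46, "hi": 0.50}],
            "taxon": "juchnevitschae",
            "as_printed": "PT/BASE 0.60–0.75; URS/ANT III 0.33–0.34; HT II/ANT III 0.46–0.50"},
      "b": {"predicates": [
             {"character_id": "PT_BASE", "op": "in", "lo": 0.95, "hi": 1.76},
             {"character_id": "URS_ANT_III", "op": "in", "lo": 0.19, "hi": 0.31},
             {"character_id": "HT_II_ANT_III", "op": "in", "lo": 0.26, "hi": 0.45}],
            "next": "2",
            "as_printed": "PT/BASE 0.95–1.76; URS/ANT III 0.19–0.31; HT II/ANT III 0.26–0.45"}
    },
    "2": {
      "a": {"predicates": [
             {"character_id": "ANT_V_ANT_III", "op": "in", "lo": 0.61, "hi": 0.63},
             {"character_id": "HT_II_ANT_VI", "op": "in", "lo": 0.30, "hi": 0.32}],
            "taxon": "tianshanica",
            "as_printed": "ANT V/ANT III 0.61–0.63; HT II/ANT VI 0.30–0.32"},
      "b": {"predicates": [
             {"character_id": "ANT_V_ANT_III", "op": "in", "lo": 0.28, "hi": 0.51},
             {"character_id": "HT_II_ANT_VI", "op": "in", "lo": 0.36, "hi": 0.72}],
            "next": "3",
            "as_printed": "ANT V/ANT III 0.28–0.51; HT II/ANT VI 0.36–0.72"}
    },
    "3": {
      "a": {"predicates": [
             {"character_id": "HW_ANT", "op": "in", "lo": 0.25, "hi": 0.30},
             {"character_id": "URS_ANT_VI", "op": "in", "lo": 0.25, "hi": 0.30},
             {"character_id": "HT_II_ANT_VI", "op": "in", "lo": 0.36, "hi": 0.39},
             {"character_id": "RHIN_ANT_III", "op": "in", "lo": 15, "hi": 24}],
            "taxon": "rosarum",
            "as_printed": "HW/ANT 0.25–0.30; URS/ANT VI 0.25–0.30; HT II/ANT VI 0.36–0.39; ANT III with 15–24 secondary rhinaria"},
      "b": {"predicates": [
             {"character_id": "HW_ANT", "op": "in", "lo": 0.31, "hi": 0.44},
             {"character_id": "URS_ANT_VI", "op": "in", "lo": 0.34, "hi": 0.47},
             {"character_id": "HT_II_ANT_VI", "op": "in", "lo": 0.44, "hi": 0.72},
             {"character_id": "RHIN_ANT_III", "op": "in", "lo": 6, "hi": 16}],
            "next": "4",
            "as_printed": "HW/ANT 0.31–0.44; URS/ANT VI 0.34–0.47; HT II/ANT VI 0.44–0.72; ANT III with 6–16 secondary rhinaria"}
    },
    "4": {
      "a": {"predicates": [
             {"character_id": "SIPH_CAUDA", "op": "in", "lo": 2.00, "hi": 2.27},
             {"character_id": "HW_ANT", "op": "in", "lo": 0.43, "hi": 0.44},
             {"character_id": "ANT_IV_ANT_III", "op": "in", "lo": 0.26, "hi": 0.31},
             {"character_id": "PT_BASE", "op": "in", "lo": 0.95, "hi": 1.00}],
            "taxon": "rezwanii",
            "as_printed": "SIPH/cauda 2.00–2.27; HW/ANT 0.43–0.44; ANT IV/ANT III 0.26–0.31; PT/BASE 0.95–1.00"},
      "b": {"predicates": [
             {"character_id": "SIPH_CAUDA", "op": "in", "lo": 1.21, "hi": 1.68},
             {"character_id": "HW_ANT", "op": "in", "lo": 0.31, "hi": 0.40},
             {"character_id": "ANT_IV_ANT_III", "op": "in", "lo": 0.33, "hi": 0.46},
             {"character_id": "PT_BASE", "op": "in", "lo": 1.05, "hi": 1.50}],
            "next": "5",
            "as_printed": "SIPH/cauda 1.21–1.68; HW/ANT 0.31–0.40; ANT IV/ANT III 0.33–0.46; PT/BASE 1.05–1.50"}
    },
    "5": {
      "a": {"predicates": [
             {"character_id": "ANT_IV_ANT_III", "op": "in", "lo": 1.00, "hi": 1.45,
              "curated": {"lo": 0.40, "hi": 0.46,
                          "justification": "printed 1.00–1.45 is unreachable after couplet 4 (0.33–0.46) and contradicts the bucktoni description (ANT IV/ANT III 0.40–0.46); description range used"}}],
            "taxon": "bucktoni",
            "as_printed": "ANT IV/ANT III 1.00–1.45"},
      "b": {"predicates": [
             {"character_id": "ANT_IV_ANT_III", "op": "in", "lo": 0.31, "hi": 0.41}],
            "taxon": "turanica",
            "as_printed": "ANT IV/ANT III 0.31–0.41"}
    }
  }
}
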