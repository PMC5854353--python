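{
  "id": "fundatrix",
  "name": "Key to known fundatrices",
  "morph": "fundatrix",
  "root": "1",
  "couplets": {
    "1": {
      "a": {"predicates": [
             {"character_id": "DORSAL_SETA_ABD", "op": "in", "lo": 0.02, "hi": 0.075},
             {"character_id": "DORSAL_SETA_FORM", "op": "eq", "state": "long-pointed"}],
            "taxon": "tianshanica",
            "as_printed": "Dorsal abdominal setae very long (0.02–0.075 mm), thick and pointed"},
      "b": {"predicates": [
             {"character_id": "DORSAL_SETA_ABD", "op": "in", "lo": 0.005, "hi": 0.02},
             {"character_id": "DORSAL_SETA_FORM", "op": "eq", "state": "short-blunt"}],
            "next": "2",
            "as_printed": "Dorsal abdominal setae very short (0.005–0.02 mm), inconspicuous and blunt"}
    },
    "2": {
      "a": {"predicates": [
             {"character_id": "SIPH_CAUDA", "op": "in", "lo": 2.5555, "hi": 2.8245},
             {"character_id": "PT_BASE", "op": "in", "lo": 0.627, "hi": 0.693},
             {"character_id": "URS_ANT_V", "op": "in", "lo": 0.646, "hi": 0.714}],
            "taxon": "rezwanii",
            "as_printed": "SIPH/cauda about 2.69; PT/BASE about 0.66; URS/ANT V about 0.68"},
      "b": {"predicates": [
             {"character_id": "SIPH_CAUDA", "op": "le", "hi": 1.96},
             {"character_id": "PT_BASE", "op": "ge", "lo": 0.88},
             {"character_id": "URS_ANT_V", "op": "le", "hi": 0.57}],
            "next": "3",
            "as_printed": "SIPH/cauda 1.96 or less; PT/BASE 0.88 or more; URS/ANT V 0.57 or less"}
    },
    "3": {
      "a": {"predicates": [
             {"character_id": "LS_III_BD_III", "op": "in", "lo": 0.25, "hi": 0.40},
             {"character_id": "SIPH_CAUDA", "op": "in", "lo": 1.65, "hi": 1.96},
             {"character_id": "URS_ANT_V", "op": "in", "lo": 0.44, "hi": 0.53}],
            "next": "4",
            "as_printed": "LS/BD III 0.25–0.40; SIPH/cauda 1.65–1.96; URS/ANT V 0.44–0.53"},
      "b": {"predicates": [
             {"character_id": "LS_III_BD_III", "op": "in", "lo": 0.57, "hi": 0.66},
             {"character_id": "SIPH_CAUDA", "op": "in", "lo": 1.43, "hi": 1.51},
             {"character_id": "URS_ANT_V", "op": "in", "lo": 0.54, "hi": 0.57}],
            "taxon": "bucktoni",
            "as_printed": "LS/BD III 0.57–0.66; SIPH/cauda 1.43–1.51; URS/ANT V 0.54–0.57"}
    },
    "4": {
      "a": {"predicates": [
             {"character_id": "FRONTAL_TUBERCLE", "op": "state_in", "states": ["rounded", "quadrate", "rectangular"]},
             {"character_id": "SIPH_CAUDA_PIGMENT", "op": "eq", "state": "dark"}],
            "taxon": "rosarum",
            "as_printed": "Median frontal tubercle well developed. SIPH and cauda dark"},
      "b": {"predicates": [
             {"character_id": "FRONTAL_TUBERCLE", "op": "eq", "state": "absent"},
             {"character_id": "SIPH_CAUDA_PIGMENT", "op": "eq", "state": "pale"}],
            "taxon": "tuatayae",
            "as_printed": "Median frontal tubercle absent. SIPH and cauda pale"}
    }
  }
}
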