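{
  "id": "apterae",
  "name": "Key to apterous viviparous females",
  "morph": "aptera",
  "root": "1",
  "couplets": {
    "1": {
      "a": {"predicates": [
             {"character_id": "FRONTAL_TUBERCLE", "op": "eq", "state": "absent"}],
            "next": "2",
            "as_printed": "Frons straight or broadly convex without median frontal tubercle"},
      "b": {"predicates": [
             {"character_id": "FRONTAL_TUBERCLE", "op": "state_in", "states": ["rounded", "quadrate", "rectangular"]}],
            "next": "3",
            "as_printed": "Frons with more or less developed median frontal tubercle that is quadrate or rounded"}
    },
    "2": {
      "a": {"predicates": [
             {"character_id": "DORSUM_PIGMENT", "op": "eq", "state": "dark"},
             {"character_id": "SIPH_FORM", "op": "eq", "state": "clavate"},
             {"character_id": "ANT_V_ANT_III", "op": "in", "lo": 0.57, "hi": 0.68},
             {"character_id": "HLS_BD_III", "op": "in", "lo": 1.25, "hi": 1.35}],
            "taxon": "juchnevitschae",
            "as_printed": "Dorsum dark; SIPH clavate; ANT V/ANT III 0.57–0.68; Longest head setae 1.25–1.35 x BD III"},
      "b": {"predicates": [
             {"character_id": "DORSUM_PIGMENT", "op": "eq", "state": "pale"},
             {"character_id": "SIPH_FORM", "op": "eq", "state": "tapering"},
             {"character_id": "ANT_V_ANT_III", "op": "in", "lo": 0.38, "hi": 0.45},
             {"character_id": "HLS_BD_III", "op": "in", "lo": 0.43, "hi": 0.54}],
            "taxon": "tuatayae",
            "as_printed": "Dorsum pale; SIPH not clavate, tapering towards apex; ANT V/ANT III 0.38–0.45; Longest head setae 0.43–0.54 x BD III"}
    },
    "3": {
      "a": {"predicates": [
             {"character_id": "DORSAL_SETA_ABD", "op": "in", "lo": 0.055, "hi": 0.090},
             {"character_id": "DORSAL_SETA_FORM", "op": "eq", "state": "long-pointed"}],
            "taxon": "tianshanica",
            "as_printed": "Dorsal body setae long (0.055–0.090 mm), thick and pointed"},
      "b": {"predicates": [
             {"character_id": "DORSAL_SETA_ABD", "op": "in", "lo": 0.001, "hi": 0.025},
             {"character_id": "DORSAL_SETA_FORM", "op": "eq", "state": "short-blunt"}],
            "next": "4",
            "as_printed": "Dorsal body setae very short (0.001–0.025 mm), inconspicuous and blunt"}
    },
    "4": {
      "a": {"predicates": [
             {"character_id": "FRONTAL_TUBERCLE", "op": "eq", "state": "rounded"}],
            "next": "5",
            "as_printed": "Median frontal tubercle with gentle and delicate edges; almost rounded"},
      "b": {"predicates": [
             {"character_id": "FRONTAL_TUBERCLE", "op": "state_in", "states": ["quadrate", "rectangular"]}],
            "next": "6",
            "as_printed": "Median frontal tubercle clearly quadrate with evident perpendicular edges"}
    },
    "5": {
      "a": {"predicates": [
             {"character_id": "DORSUM_PIGMENT", "op": "eq", "state": "pale"},
             {"character_id": "PLEURAL_STRIPES", "op": "eq", "state": "absent"}],
            "taxon": "rezwanii",
            "as_printed": "Dorsum pale, slightly wrinkled, without dark longitudinal pleural stripes"},
      "b": {"predicates": [
             {"character_id": "PLEURAL_STRIPES", "op": "eq", "state": "broad"}],
            "taxon": "bucktoni",
            "as_printed": "Dorsum strongly wrinkled with two broad dark longitudinal pleural stripes"}
    },
    "6": {
      "a": {"predicates": [
             {"character_id": "FRONTAL_TUBERCLE", "op": "eq", "state": "quadrate"},
             {"character_id": "HLS_BD_III", "op": "in", "lo": 0.30, "hi": 0.60},
             {"character_id": "GENITAL_PLATE_SETAE", "op": "in", "lo": 4, "hi": 7}],
            "taxon": "rosarum",
            "as_printed": "Median frontal tubercle as long as wide with 2 setae, their length 0.30–0.60 x BD III. Subgenital plate with total 4–7 setae"},
      "b": {"predicates": [
             {"character_id": "FRONTAL_TUBERCLE", "op": "eq", "state": "rectangular"},
             {"character_id": "HLS_BD_III", "op": "in", "lo": 0.80, "hi": 1.10},
             {"character_id": "GENITAL_PLATE_SETAE", "op": "ge", "lo": 9}],
            "next": "7",
            "as_printed": "Median frontal tubercle usually wider than long with 2–4 setae, their length 0.80–1.10 x BD III. Subgenital plate with more than 8 setae"}
    },
    "7": {
      "a": {"predicates": [
             {"character_id": "URS_ANT_III", "op": "in", "lo": 0.32, "hi": 0.51},
             {"character_id": "HT_II_ANT_III", "op": "in", "lo": 0.42, "hi": 0.67},
             {"character_id": "PLEURAL_STRIPES", "op": "eq", "state": "absent"}],
            "taxon": "turanica",
            "as_printed": "URS/ANT III 0.32–0.51; HT II/ANT III 0.42–0.67; Abdomen without two darker longitudinal pleural stripes"},
      "b": {"predicates": [
             {"character_id": "URS_ANT_III", "op": "in", "lo": 0.70, "hi": 0.87},
             {"character_id": "HT_II_ANT_III", "op": "in", "lo": 0.85, "hi": 1.00},
             {"character_id": "PLEURAL_STRIPES", "op": "eq", "state": "narrow"}],
            "taxon": "oezdemirae",
            "as_printed": "URS/ANT III 0.70–0.87; HT II/ANT III 0.85–1.00; Abdomen with two narrow darker longitudinal pleural stripes"}
    }
  }
}
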