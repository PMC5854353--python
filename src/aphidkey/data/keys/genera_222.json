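{
  "id": "genera_222",
  "name": "Key to Macrosiphini genera with 2-2-2 first tarsal chaetotaxy (apterous viviparous females)",
  "morph": "aptera",
  "root": "1",
  "terminals_are_genera": true,
  "couplets": {
    "1": {
      "a": {"predicates": [
             {"character_id": "RHIN_ANT_III", "op": "ge", "lo": 1}],
            "taxon": "Hydaphias",
            "as_printed": "ANT III with secondary rhinaria"},
      "b": {"predicates": [
             {"character_id": "RHIN_ANT_III", "op": "in", "lo": 0, "hi": 0}],
            "next": "2",
            "as_printed": "ANT III without secondary rhinaria"}
    },
    "2": {
      "a": {"predicates": [
             {"character_id": "SIPH_FORM", "op": "eq", "state": "pore-like"},
             {"character_id": "URS_SHAPE", "op": "eq", "state": "stiletto"}],
            "taxon": "Cryptosiphum",
            "as_printed": "SIPH pore-shaped and hardly visible; URS stiletto-shaped"},
      "b": {"predicates": [
             {"character_id": "SIPH_FORM", "op": "state_in", "states": ["cylindrical", "clavate", "truncate", "swollen-distal", "slightly-swollen", "tapering"]},
             {"character_id": "URS_SHAPE", "op": "eq", "state": "normal"}],
            "next": "3",
            "as_printed": "SIPH cylindrical, swollen or truncate, easily visible; URS not stiletto-shaped"}
    },
    "3": {
      "a": {"predicates": [
             {"character_id": "ANT_TUBERCLE_INNER", "op": "eq", "state": "spiculose"}],
            "taxon": "Myzus",
            "as_printed": "Inner faces of antennal tubercles spiculose or scabrous"},
      "b": {"predicates": [
             {"character_id": "ANT_TUBERCLE_INNER", "op": "eq", "state": "smooth"}],
            "next": "4",
            "as_printed": "Inner faces of antennal tubercles smooth"}
    },
    "4": {
      "a": {"predicates": [
             {"character_id": "CAUDA_FORM", "op": "eq", "state": "semicircular"},
             {"character_id": "SIPH_INCISION", "op": "eq", "state": "present"}],
            "taxon": "Brachycaudus",
            "as_printed": "Cauda short and semicircular; SIPH with a marked subapical annular incision"},
      "b": {"predicates": [
             {"character_id": "CAUDA_FORM", "op": "state_in", "states": ["triangular", "finger-shaped", "tongue-shaped"]},
             {"character_id": "SIPH_INCISION", "op": "eq", "state": "absent"}],
            "next": "5",
            "as_printed": "Cauda triangular or finger-shaped; SIPH without a marked subapical annular incision"}
    },
    "5": {
      "a": {"predicates": [
             {"character_id": "ANT_TUBERCLE_DEV", "op": "eq", "state": "well-developed"}],
            "taxon": "Micromyzella",
            "as_printed": "Antennal tubercles well developed"},
      "b": {"predicates": [
             {"character_id": "ANT_TUBERCLE_DEV", "op": "eq", "state": "low"}],
            "next": "6",
            "as_printed": "Antennal tubercles low or undeveloped"}
    },
    "6": {
      "a": {"predicates": [
             {"character_id": "SIPH_FORM", "op": "eq", "state": "truncate"}],
            "taxon": "Staegeriella",
            "as_printed": "SIPH short, truncate and squamous"},
      "b": {"predicates": [
             {"character_id": "SIPH_FORM", "op": "state_in", "states": ["cylindrical", "clavate", "swollen-distal", "slightly-swollen"]}],
            "next": "7",
            "as_printed": "SIPH long and cylindrical or swollen, not squamous"}
    },
    "7": {
      "a": {"predicates": [
             {"character_id": "DORSUM_PIGMENT", "op": "eq", "state": "dark"},
             {"character_id": "DORSUM_SCULPTURE", "op": "eq", "state": "smooth"},
             {"character_id": "SIPH_FORM", "op": "eq", "state": "cylindrical"}],
            "taxon": "Pseudacaudella",
            "as_printed": "Dorsum dark pigmented, mainly smooth; SIPH cylindrical"},
      "b": {"predicates": [
             {"character_id": "DORSUM_PIGMENT", "op": "eq", "state": "pale"},
             {"character_id": "SIPH_FORM", "op": "state_in", "states": ["clavate", "swollen-distal", "slightly-swollen"]}],
            "next": "8",
            "as_printed": "Dorsum pale, membranous and reticulated or wrinkled; SIPH clavate"}
    },
    "8": {
      "a": {"predicates": [
             {"character_id": "DORSUM_SCULPTURE", "op": "eq", "state": "reticulated"},
             {"character_id": "SIPH_FORM", "op": "eq", "state": "swollen-distal"}],
            "taxon": "Hyadaphis",
            "as_printed": "Dorsum membranous and reticulated; SIPH markedly swollen in the distal half"},
      "b": {"predicates": [
             {"character_id": "DORSUM_SCULPTURE", "op": "eq", "state": "wrinkled"},
             {"character_id": "SIPH_FORM", "op": "eq", "state": "slightly-swollen"}],
            "taxon": "Richardsaphis",
            "as_printed": "Dorsum wrinkled; SIPH slightly swollen apically"}
    }
  }
}
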