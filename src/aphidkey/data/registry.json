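{
  "characters": [
    {"id": "BL", "name": "body length", "kind": "linear", "unit": "mm"},
    {"id": "HW", "name": "head width across compound eyes", "kind": "linear", "unit": "mm"},
    {"id": "HLS", "name": "head longest seta", "kind": "linear", "unit": "mm"},
    {"id": "ANT", "name": "antenna length", "kind": "linear", "unit": "mm"},
    {"id": "ANT_I", "name": "antennal segment I length", "kind": "linear", "unit": "mm"},
    {"id": "ANT_II", "name": "antennal segment II length", "kind": "linear", "unit": "mm"},
    {"id": "ANT_III", "name": "antennal segment III length", "kind": "linear", "unit": "mm"},
    {"id": "ANT_IV", "name": "antennal segment IV length", "kind": "linear", "unit": "mm"},
    {"id": "ANT_V", "name": "antennal segment V length", "kind": "linear", "unit": "mm"},
    {"id": "ANT_VI", "name": "antennal segment VI length", "kind": "linear", "unit": "mm"},
    {"id": "BASE", "name": "basal part of last antennal segment", "kind": "linear", "unit": "mm"},
    {"id": "PT", "name": "terminal process of last antennal segment", "kind": "linear", "unit": "mm"},
    {"id": "LS_III", "name": "longest seta on ANT III", "kind": "linear", "unit": "mm"},
    {"id": "BD_III", "name": "basal articular diameter of ANT III", "kind": "linear", "unit": "mm"},
    {"id": "URS", "name": "ultimate rostral segment length", "kind": "linear", "unit": "mm"},
    {"id": "FEMUR_III", "name": "hind femur length", "kind": "linear", "unit": "mm"},
    {"id": "TIBIA_III", "name": "hind tibia length", "kind": "linear", "unit": "mm"},
    {"id": "HT_I", "name": "first hind tarsal segment length", "kind": "linear", "unit": "mm"},
    {"id": "HT_II", "name": "second hind tarsal segment length", "kind": "linear", "unit": "mm"},
    {"id": "SIPH", "name": "siphunculus length", "kind": "linear", "unit": "mm"},
    {"id": "CAUDA", "name": "cauda length", "kind": "linear", "unit": "mm"},
    {"id": "GPL", "name": "genital plate length", "kind": "linear", "unit": "mm"},
    {"id": "GPW", "name": "genital plate width", "kind": "linear", "unit": "mm"},
    {"id": "DORSAL_SETA_THORAX", "name": "dorsal thoracic seta length", "kind": "linear", "unit": "mm"},
    {"id": "DORSAL_SETA_ABD", "name": "dorsal abdominal seta length", "kind": "linear", "unit": "mm"},

    {"id": "SIPH_CAUDA", "name": "SIPH / cauda", "kind": "ratio", "numerator_id": "SIPH", "denominator_id": "CAUDA"},
    {"id": "PT_BASE", "name": "PT / BASE", "kind": "ratio", "numerator_id": "PT", "denominator_id": "BASE"},
    {"id": "URS_ANT_III", "name": "URS / ANT III", "kind": "ratio", "numerator_id": "URS", "denominator_id": "ANT_III"},
    {"id": "URS_ANT_V", "name": "URS / ANT V", "kind": "ratio", "numerator_id": "URS", "denominator_id": "ANT_V"},
    {"id": "URS_ANT_VI", "name": "URS / ANT VI", "kind": "ratio", "numerator_id": "URS", "denominator_id": "ANT_VI"},
    {"id": "URS_BASE", "name": "URS / BASE", "kind": "ratio", "numerator_id": "URS", "denominator_id": "BASE"},
    {"id": "URS_HT_II", "name": "URS / HT II", "kind": "ratio", "numerator_id": "URS", "denominator_id": "HT_II"},
    {"id": "HT_II_ANT_III", "name": "HT II / ANT III", "kind": "ratio", "numerator_id": "HT_II", "denominator_id": "ANT_III"},
    {"id": "HT_II_BASE", "name": "HT II / BASE", "kind": "ratio", "numerator_id": "HT_II", "denominator_id": "BASE"},
    {"id": "HT_II_ANT_V", "name": "HT II / ANT V", "kind": "ratio", "numerator_id": "HT_II", "denominator_id": "ANT_V"},
    {"id": "HT_II_ANT_VI", "name": "HT II / ANT VI", "kind": "ratio", "numerator_id": "HT_II", "denominator_id": "ANT_VI"},
    {"id": "ANT_BL", "name": "ANT / BL", "kind": "ratio", "numerator_id": "ANT", "denominator_id": "BL"},
    {"id": "HW_ANT", "name": "HW / ANT", "kind": "ratio", "numerator_id": "HW", "denominator_id": "ANT"},
    {"id": "ANT_HW", "name": "ANT / HW", "kind": "ratio", "numerator_id": "ANT", "denominator_id": "HW"},
    {"id": "ANT_V_ANT_III", "name": "ANT V / ANT III", "kind": "ratio", "numerator_id": "ANT_V", "denominator_id": "ANT_III"},
    {"id": "ANT_IV_ANT_III", "name": "ANT IV / ANT III", "kind": "ratio", "numerator_id": "ANT_IV", "denominator_id": "ANT_III"},
    {"id": "ANT_VI_ANT_III", "name": "ANT VI / ANT III", "kind": "ratio", "numerator_id": "ANT_VI", "denominator_id": "ANT_III"},
    {"id": "LS_III_BD_III", "name": "LS III / BD III", "kind": "ratio", "numerator_id": "LS_III", "denominator_id": "BD_III"},
    {"id": "HLS_BD_III", "name": "longest head seta / BD III", "kind": "ratio", "numerator_id": "HLS", "denominator_id": "BD_III"},

    {"id": "RHIN_ANT_III", "name": "secondary rhinaria on ANT III", "kind": "count"},
    {"id": "RHIN_ANT_IV", "name": "secondary rhinaria on ANT IV", "kind": "count"},
    {"id": "RHIN_ANT_V", "name": "secondary rhinaria on ANT V", "kind": "count"},
    {"id": "RHIN_ANT_VI", "name": "secondary rhinaria on ANT VI", "kind": "count"},
    {"id": "PSEUDOSENSORIA", "name": "pseudosensoria on hind tibiae", "kind": "count"},
    {"id": "CAUDA_SETAE", "name": "setae on cauda", "kind": "count"},
    {"id": "FIRST_TARSAL_SETAE", "name": "ventral setae on first tarsal segments", "kind": "count"},
    {"id": "URS_ACC_SETAE", "name": "accessory setae on URS", "kind": "count"},
    {"id": "GENITAL_PLATE_SETAE", "name": "setae on (sub)genital plate", "kind": "count"},
    {"id": "ANT_SEGMENTS", "name": "number of antennal segments", "kind": "count"},
    {"id": "SETAE_ANT_I", "name": "setae on ANT I", "kind": "count"},
    {"id": "SETAE_ANT_II", "name": "setae on ANT II", "kind": "count"},
    {"id": "SETAE_ANT_III", "name": "setae on ANT III", "kind": "count"},
    {"id": "SETAE_ANT_IV", "name": "setae on ANT IV", "kind": "count"},
    {"id": "SETAE_ANT_V", "name": "setae on ANT V", "kind": "count"},
    {"id": "SETAE_ANT_VI", "name": "basal setae on ANT VI", "kind": "count"},

    {"id": "FRONTAL_TUBERCLE", "name": "median frontal tubercle form", "kind": "categorical", "allowed_states": ["absent", "rounded", "quadrate", "rectangular"]},
    {"id": "DORSAL_SETA_FORM", "name": "dorsal body seta form", "kind": "categorical", "allowed_states": ["short-blunt", "long-pointed"]},
    {"id": "SIPH_FORM", "name": "siphunculus form", "kind": "categorical", "allowed_states": ["tapering", "cylindrical", "clavate", "pore-like", "truncate", "swollen-distal", "slightly-swollen"]},
    {"id": "SIPH_INCISION", "name": "subapical annular incision on SIPH", "kind": "categorical", "allowed_states": ["present", "absent"]},
    {"id": "SIPH_CAUDA_PIGMENT", "name": "SIPH and cauda pigmentation", "kind": "categorical", "allowed_states": ["pale", "dark"]},
    {"id": "DORSUM_PIGMENT", "name": "dorsum pigmentation", "kind": "categorical", "allowed_states": ["pale", "dark"]},
    {"id": "PLEURAL_STRIPES", "name": "dark longitudinal pleural stripes", "kind": "categorical", "allowed_states": ["absent", "narrow", "broad"]},
    {"id": "ANT_TUBERCLE_INNER", "name": "inner face of antennal tubercles", "kind": "categorical", "allowed_states": ["smooth", "spiculose"]},
    {"id": "ANT_TUBERCLE_DEV", "name": "antennal tubercle development", "kind": "categorical", "allowed_states": ["low", "well-developed"]},
    {"id": "DORSUM_SCULPTURE", "name": "dorsal cuticle sculpture", "kind": "categorical", "allowed_states": ["depressions", "wrinkled", "reticulated", "smooth"]},
    {"id": "CAUDA_FORM", "name": "cauda shape", "kind": "categorical", "allowed_states": ["tongue-shaped", "triangular", "finger-shaped", "semicircular"]},
    {"id": "TIBIA_III_SWELLING", "name": "hind tibia swelling (oviparae)", "kind": "categorical", "allowed_states": ["swollen", "not-swollen"]},
    {"id": "WINGS", "name": "wings", "kind": "categorical", "allowed_states": ["present", "absent"]},
    {"id": "URS_SHAPE", "name": "URS shape", "kind": "categorical", "allowed_states": ["normal", "stiletto"]}
  ]
}
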