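{
  "species": [
    {"genus": "Myzaphis", "species": "bucktoni", "authority": "Jacob, 1946", "status": "valid"},
    {"genus": "Myzaphis", "species": "juchnevitschae", "authority": "Kadyrbekov, 1993", "status": "valid"},
    {"genus": "Myzaphis", "species": "komatsubarae", "authority": "Shinji, 1922", "status": "nomen_dubium"},
    {"genus": "Myzaphis", "species": "oezdemirae", "authority": "Kanturski & Barjadze, 2018", "status": "valid"},
    {"genus": "Myzaphis", "species": "rezwanii", "authority": "Kanturski & Barjadze, 2018", "status": "valid"},
    {"genus": "Myzaphis", "species": "rosarum", "authority": "(Kaltenbach, 1843)", "status": "valid"},
    {"genus": "Myzaphis", "species": "tianshanica", "authority": "Kadyrbekov, 1993", "status": "valid"},
    {"genus": "Myzaphis", "species": "tuatayae", "authority": "Kanturski & Barjadze, 2018", "status": "valid"},
    {"genus": "Myzaphis", "species": "turanica", "authority": "Nevsky, 1929", "status": "valid"},
    {"genus": "Ericaphis", "species": "avariolosa", "authority": "(David, Rajasingh & Narayanan, 1970)", "status": "valid", "note": "transferred from Myzaphis"},
    {"genus": "Richardsaphis", "species": "canadensis", "authority": "(Richards, 1963)", "status": "valid"}
  ],
  "genus_level_traits": {
    "Myzaphis": {"FIRST_TARSAL_SETAE": [5, 5], "CAUDA_SETAE": [6, 7]},
    "Richardsaphis": {"FIRST_TARSAL_SETAE": [2, 2]},
    "Ericaphis": {"FIRST_TARSAL_SETAE": [5, 5]}
  },
  "genus_terminals": [
    "Hydaphias", "Cryptosiphum", "Myzus", "Brachycaudus", "Micromyzella",
    "Staegeriella", "Pseudacaudella", "Hyadaphis", "Richardsaphis"
  ],
  "examined_material": {
    "fundatrix": 36, "aptera": 316, "alata": 47, "ovipara": 50, "male": 25,
    "total_individuals": 474, "total_slides": 154
  }
}
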