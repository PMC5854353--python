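taxon,morph,character_id,action,lo,hi,new_character_id,justification
tuatayae,aptera,ANT_IV,replace,0.08,0.10,,printed 0.08–1.10 exceeds the whole antenna (0.66–0.81); decimal slip for 0.10 (congeners 0.04–0.14)
bucktoni,aptera,GPW,replace,0.13,0.20,,printed 0.3–0.20 is inverted; read as 0.13–0.20 (dropped digit; congeners 0.13–0.25 and bucktoni alata GPW 0.16–0.23)
tianshanica,aptera,ANT,drop,,,,printed 0.16–0.18 equals the ANT III range and is below ANT VI alone (0.19–0.22); no correction derivable so curated value left absent
rezwanii,alata,RHIN_ANT_III,replace,8,11,,printed 8–110; alatae key gives 6–16 for this group; read 110 as 11
rezwanii,male,DORSAL_SETA_THORAX,replace,0.007,0.010,,printed 0.07–0.010 is inverted; read as 0.007–0.010
tuatayae,aptera,HLS,replace,0.005,0.014,,printed 0.005–0.14; with HLS/BD III 0.43–0.54 and BD III near 0.025 mm the longest head seta is near 0.013 mm; read 0.14 as 0.014
turanica,aptera,DORSAL_SETA_ABD,replace,0.010,0.027,,printed 0.010–0.271; congeners 0.012–0.031 and the apterae key bounds short setae at 0.025; read 0.271 as 0.027
tianshanica,aptera,URS_ANT_VI,remap,,,URS_ANT_V,printed quotient 0.65–0.80 matches URS/ANT V (0.08 / 0.10–0.13); vs ANT VI (0.19–0.22) it would be 0.36–0.42; segment label slip
bucktoni,ovipara,ANT_V,replace,0.04,0.05,,printed 0.06–0.07 gives ANT V/ANT III 0.46–0.58 while description and oviparae key both print 0.33–0.40; 0.04–0.05 matches the printed ratio
canadensis,male,URS_ANT_VI,drop,,,,printed 0.45–0.50 is irreconcilable with the table (0.07 / 0.20–0.21 = 0.33–0.35) even allowing rounding; curated value left absent
canadensis,male,URS,replace,0.065,0.075,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/ANT III 0.23–0.24
canadensis,male,ANT_III,replace,0.285,0.295,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/ANT III and HT II/ANT III ratios
canadensis,male,HT_II,replace,0.085,0.095,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed HT II/ANT III 0.30–0.31
canadensis,ovipara,HT_II,replace,0.065,0.075,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed HT II/ANT VI 0.60–0.64
canadensis,ovipara,ANT_VI,replace,0.115,0.125,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed HT II/ANT VI 0.60–0.64
juchnevitschae,alata,ANT_III,replace,0.215,0.225,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed ANT VI/ANT III 0.72 and URS/ANT III 0.33–0.34
juchnevitschae,alata,ANT_VI,replace,0.155,0.175,,printed at 0.01 mm precision; half-unit rounding width restored to admit the printed ANT VI/ANT III 0.72
juchnevitschae,alata,URS,replace,0.065,0.075,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/ANT III 0.33–0.34
juchnevitschae,alata,BASE,replace,0.095,0.105,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/BASE about 0.75
oezdemirae,aptera,URS,replace,0.065,0.075,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/HT II 0.82–0.87
oezdemirae,aptera,HT_II,replace,0.075,0.085,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/HT II 0.82–0.87
oezdemirae,aptera,BASE,replace,0.055,0.065,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/BASE about 1.16
oezdemirae,ovipara,URS_BASE,drop,,,,the printed quotient (about 1.16) is jointly irreconcilable with URS/HT II 0.77–0.88 and HT II/BASE 1.06–1.20 under the printed table values even allowing rounding; curated value left absent
rezwanii,male,URS,replace,0.055,0.065,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/HT II about 1.08
rezwanii,male,HT_II,replace,0.055,0.065,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/HT II about 1.08
tianshanica,alata,URS,replace,0.065,0.075,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/ANT III about 0.22
tianshanica,alata,ANT_III,replace,0.335,0.345,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/ANT III about 0.22
tianshanica,alata,HT_II,replace,0.085,0.095,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/HT II about 0.83
tianshanica,aptera,URS,replace,0.075,0.085,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/HT II about 0.85
tianshanica,aptera,HT_II,replace,0.095,0.105,,single measurement printed at 0.01 mm precision; half-unit rounding width restored to admit the printed URS/HT II about 0.85
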