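taxon,morph,character_id,lo,hi,provenance,as_printed
bucktoni,ovipara,BL,1.42,1.52,T4,1.42–1.52
bucktoni,ovipara,HW,0.31,0.32,T4,0.31–0.32
bucktoni,ovipara,ANT,0.50,0.53,T4,0.50–0.53
bucktoni,ovipara,ANT_III,0.12,0.13,T4,0.12–0.13
bucktoni,ovipara,ANT_IV,0.04,0.05,T4,0.04–0.05
bucktoni,ovipara,ANT_V,0.06,0.07,T4,0.06–0.07
bucktoni,ovipara,ANT_VI,0.17,0.18,T4,0.17–0.18
bucktoni,ovipara,BASE,0.07,0.08,T4,0.07–0.08
bucktoni,ovipara,PT,0.10,0.10,T4,0.10
bucktoni,ovipara,URS,0.07,0.08,T4,0.07–0.08
bucktoni,ovipara,FEMUR_III,0.25,0.27,T4,0.25–0.27
bucktoni,ovipara,TIBIA_III,0.39,0.42,T4,0.39–0.42
bucktoni,ovipara,HT_I,0.03,0.03,T4,0.03
bucktoni,ovipara,HT_II,0.09,0.10,T4,0.09–0.10
bucktoni,ovipara,SIPH,0.23,0.25,T4,0.23–0.25
bucktoni,ovipara,CAUDA,0.14,0.15,T4,0.14–0.15
bucktoni,ovipara,GPL,0.07,0.08,T4,0.07–0.08
bucktoni,ovipara,GPW,0.18,0.22,T4,0.18–0.22
oezdemirae,ovipara,BL,1.14,1.25,T4,1.14–1.25
oezdemirae,ovipara,HW,0.26,0.27,T4,0.26–0.27
oezdemirae,ovipara,ANT,0.54,0.56,T4,0.54–0.56
oezdemirae,ovipara,ANT_III,0.13,0.15,T4,0.13–0.15
oezdemirae,ovipara,ANT_IV,0.06,0.07,T4,0.06–0.07
oezdemirae,ovipara,ANT_V,0.07,0.08,T4,0.07–0.08
oezdemirae,ovipara,ANT_VI,0.16,0.18,T4,0.16–0.18
oezdemirae,ovipara,BASE,0.07,0.08,T4,0.07–0.08
oezdemirae,ovipara,PT,0.08,0.10,T4,0.08–0.10
oezdemirae,ovipara,URS,0.07,0.07,T4,0.07
oezdemirae,ovipara,FEMUR_III,0.24,0.26,T4,0.24–0.26
oezdemirae,ovipara,TIBIA_III,0.39,0.43,T4,0.39–0.43
oezdemirae,ovipara,HT_I,0.02,0.02,T4,0.02
oezdemirae,ovipara,HT_II,0.08,0.09,T4,0.08–0.09
oezdemirae,ovipara,SIPH,0.23,0.27,T4,0.23–0.27
oezdemirae,ovipara,CAUDA,0.13,0.14,T4,0.13–0.14
oezdemirae,ovipara,GPL,0.07,0.08,T4,0.07–0.08
oezdemirae,ovipara,GPW,0.18,0.20,T4,0.18–0.20
rezwanii,ovipara,BL,0.94,0.98,T4,0.94–0.98
rezwanii,ovipara,HW,0.23,0.25,T4,0.23–0.25
rezwanii,ovipara,ANT,0.34,0.42,T4,0.34–0.42
rezwanii,ovipara,ANT_III,0.12,0.14,T4,0.12–0.14
rezwanii,ovipara,ANT_IV,0.05,0.07,T4,0.05–0.07
rezwanii,ovipara,ANT_V,0.09,0.12,T4,0.09–0.12
rezwanii,ovipara,BASE,0.04,0.07,T4,0.04–0.07
rezwanii,ovipara,PT,0.04,0.06,T4,0.04–0.06
rezwanii,ovipara,URS,0.07,0.08,T4,0.07–0.08
rezwanii,ovipara,FEMUR_III,0.20,0.23,T4,0.20–0.23
rezwanii,ovipara,TIBIA_III,0.33,0.39,T4,0.33–0.39
rezwanii,ovipara,HT_I,0.02,0.02,T4,0.02
rezwanii,ovipara,HT_II,0.06,0.07,T4,0.06–0.07
rezwanii,ovipara,SIPH,0.20,0.23,T4,0.20–0.23
rezwanii,ovipara,CAUDA,0.10,0.11,T4,0.10–0.11
rezwanii,ovipara,GPL,0.08,0.10,T4,0.08–0.10
rezwanii,ovipara,GPW,0.15,0.19,T4,0.15–0.19
rosarum,ovipara,BL,1.15,1.67,T4,1.15–1.67
rosarum,ovipara,HW,0.28,0.32,T4,0.28–0.32
rosarum,ovipara,ANT,0.59,0.67,T4,0.59–0.67
rosarum,ovipara,ANT_III,0.14,0.22,T4,0.14–0.22
rosarum,ovipara,ANT_IV,0.07,0.09,T4,0.07–0.09
rosarum,ovipara,ANT_V,0.08,0.09,T4,0.08–0.09
rosarum,ovipara,ANT_VI,0.19,0.21,T4,0.19–0.21
rosarum,ovipara,BASE,0.08,0.09,T4,0.08–0.09
rosarum,ovipara,PT,0.10,0.12,T4,0.10–0.12
rosarum,ovipara,URS,0.07,0.08,T4,0.07–0.08
rosarum,ovipara,FEMUR_III,0.24,0.29,T4,0.24–0.29
rosarum,ovipara,TIBIA_III,0.44,0.50,T4,0.44–0.50
rosarum,ovipara,HT_I,0.03,0.03,T4,0.03
rosarum,ovipara,HT_II,0.08,0.10,T4,0.08–0.10
rosarum,ovipara,SIPH,0.27,0.32,T4,0.27–0.32
rosarum,ovipara,CAUDA,0.13,0.17,T4,0.13–0.17
rosarum,ovipara,GPL,0.07,0.10,T4,0.07–0.10
rosarum,ovipara,GPW,0.20,0.25,T4,0.20–0.25
turanica,ovipara,BL,1.11,1.45,T4,1.11–1.45
turanica,ovipara,HW,0.27,0.29,T4,0.27–0.29
turanica,ovipara,ANT,0.49,0.59,T4,0.49–0.59
turanica,ovipara,ANT_III,0.16,0.21,T4,0.16–0.21
turanica,ovipara,ANT_IV,0.07,0.08,T4,0.07–0.08
turanica,ovipara,ANT_V,0.16,0.19,T4,0.16–0.19
turanica,ovipara,BASE,0.07,0.08,T4,0.07–0.08
turanica,ovipara,PT,0.09,0.11,T4,0.09–0.11
turanica,ovipara,URS,0.06,0.07,T4,0.06–0.07
turanica,ovipara,FEMUR_III,0.23,0.28,T4,0.23–0.28
turanica,ovipara,TIBIA_III,0.39,0.45,T4,0.39–0.45
turanica,ovipara,HT_I,0.02,0.02,T4,0.02
turanica,ovipara,HT_II,0.08,0.10,T4,0.08–0.10
turanica,ovipara,SIPH,0.21,0.25,T4,0.21–0.25
turanica,ovipara,CAUDA,0.10,0.14,T4,0.10–0.14
turanica,ovipara,GPL,0.06,0.09,T4,0.06–0.09
turanica,ovipara,GPW,0.18,0.21,T4,0.18–0.21
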