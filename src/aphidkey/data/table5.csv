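taxon,morph,character_id,lo,hi,provenance,as_printed
bucktoni,male,BL,0.95,1.13,T5,0.95–1.13
bucktoni,male,HW,0.27,0.28,T5,0.27–0.28
bucktoni,male,ANT,0.60,0.70,T5,0.60–0.70
bucktoni,male,ANT_III,0.19,0.21,T5,0.19–0.21
bucktoni,male,ANT_IV,0.07,0.09,T5,0.07–0.09
bucktoni,male,ANT_V,0.07,0.10,T5,0.07–0.10
bucktoni,male,ANT_VI,0.17,0.20,T5,0.17–0.20
bucktoni,male,BASE,0.07,0.08,T5,0.07–0.08
bucktoni,male,PT,0.10,0.12,T5,0.10–0.12
bucktoni,male,URS,0.07,0.07,T5,0.07
bucktoni,male,FEMUR_III,0.21,0.26,T5,0.21–0.26
bucktoni,male,TIBIA_III,0.36,0.46,T5,0.36–0.46
bucktoni,male,HT_I,0.02,0.03,T5,0.02–0.03
bucktoni,male,HT_II,0.07,0.09,T5,0.07–0.09
bucktoni,male,SIPH,0.15,0.17,T5,0.15–0.17
bucktoni,male,CAUDA,0.08,0.10,T5,0.08–0.10
oezdemirae,male,BL,0.90,1.25,T5,0.90–1.25
oezdemirae,male,HW,0.25,0.27,T5,0.25–0.27
oezdemirae,male,ANT,0.77,0.87,T5,0.77–0.87
oezdemirae,male,ANT_III,0.22,0.27,T5,0.22–0.27
oezdemirae,male,ANT_IV,0.13,0.14,T5,0.13–0.14
oezdemirae,male,ANT_V,0.12,0.13,T5,0.12–0.13
oezdemirae,male,ANT_VI,0.20,0.24,T5,0.20–0.24
oezdemirae,male,BASE,0.08,0.09,T5,0.08–0.09
oezdemirae,male,PT,0.12,0.15,T5,0.12–0.15
oezdemirae,male,URS,0.06,0.07,T5,0.06–0.07
oezdemirae,male,FEMUR_III,0.26,0.29,T5,0.26–0.29
oezdemirae,male,TIBIA_III,0.45,0.54,T5,0.45–0.54
oezdemirae,male,HT_I,0.02,0.03,T5,0.02–0.03
oezdemirae,male,HT_II,0.08,0.10,T5,0.08–0.10
oezdemirae,male,SIPH,0.13,0.15,T5,0.13–0.15
oezdemirae,male,CAUDA,0.08,0.09,T5,0.08–0.09
rezwanii,male,BL,0.77,0.80,T5,0.77–0.80
rezwanii,male,HW,0.22,0.23,T5,0.22–0.23
rezwanii,male,ANT,0.36,0.40,T5,0.36–0.40
rezwanii,male,ANT_III,0.15,0.16,T5,0.15–0.16
rezwanii,male,ANT_IV,0.05,0.06,T5,0.05–0.06
rezwanii,male,ANT_V,0.09,0.10,T5,0.09–0.10
rezwanii,male,BASE,0.05,0.06,T5,0.05–0.06
rezwanii,male,PT,0.03,0.04,T5,0.03–0.04
rezwanii,male,URS,0.06,0.06,T5,0.06
rezwanii,male,FEMUR_III,0.19,0.20,T5,0.19–0.20
rezwanii,male,TIBIA_III,0.35,0.38,T5,0.35–0.38
rezwanii,male,HT_I,0.02,0.02,T5,0.02
rezwanii,male,HT_II,0.06,0.06,T5,0.06
rezwanii,male,SIPH,0.14,0.14,T5,0.14
rezwanii,male,CAUDA,0.07,0.07,T5,0.07
rosarum,male,BL,1.02,1.17,T5,1.02–1.17
rosarum,male,HW,0.27,0.29,T5,0.27–0.29
rosarum,male,ANT,0.78,0.92,T5,0.78–0.92
rosarum,male,ANT_III,0.24,0.28,T5,0.24–0.28
rosarum,male,ANT_IV,0.09,0.13,T5,0.09–0.13
rosarum,male,ANT_V,0.11,0.13,T5,0.11–0.13
rosarum,male,ANT_VI,0.22,0.29,T5,0.22–0.29
rosarum,male,BASE,0.08,0.09,T5,0.08–0.09
rosarum,male,PT,0.13,0.19,T5,0.13–0.19
rosarum,male,URS,0.07,0.07,T5,0.07
rosarum,male,FEMUR_III,0.26,0.31,T5,0.26–0.31
rosarum,male,TIBIA_III,0.46,0.58,T5,0.46–0.58
rosarum,male,HT_I,0.02,0.03,T5,0.02–0.03
rosarum,male,HT_II,0.08,0.09,T5,0.08–0.09
rosarum,male,SIPH,0.20,0.22,T5,0.20–0.22
rosarum,male,CAUDA,0.10,0.10,T5,0.10
turanica,male,BL,0.82,0.95,T5,0.82–0.95
turanica,male,HW,0.28,0.28,T5,0.28
turanica,male,ANT,0.54,0.58,T5,0.54–0.58
turanica,male,ANT_III,0.21,0.22,T5,0.21–0.22
turanica,male,ANT_IV,0.08,0.08,T5,0.08
turanica,male,ANT_V,0.16,0.19,T5,0.16–0.19
turanica,male,BASE,0.07,0.08,T5,0.07–0.08
turanica,male,PT,0.09,0.11,T5,0.09–0.11
turanica,male,URS,0.05,0.05,T5,0.05
turanica,male,FEMUR_III,0.21,0.23,T5,0.21–0.23
turanica,male,TIBIA_III,0.39,0.40,T5,0.39–0.40
turanica,male,HT_I,0.02,0.02,T5,0.02
turanica,male,HT_II,0.07,0.08,T5,0.07–0.08
turanica,male,SIPH,0.17,0.17,T5,0.17
turanica,male,CAUDA,0.07,0.08,T5,0.07–0.08
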