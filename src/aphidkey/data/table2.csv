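taxon,morph,character_id,lo,hi,provenance,as_printed
bucktoni,aptera,BL,1.20,2.10,T2,1.20–2.10
bucktoni,aptera,HW,0.25,0.38,T2,0.25–0.38
bucktoni,aptera,ANT,0.40,0.73,T2,0.40–0.73
bucktoni,aptera,ANT_III,0.10,0.22,T2,0.10–0.22
bucktoni,aptera,ANT_IV,0.04,0.09,T2,0.04–0.09
bucktoni,aptera,ANT_V,0.05,0.10,T2,0.05–0.10
bucktoni,aptera,ANT_VI,0.12,0.19,T2,0.12–0.19
bucktoni,aptera,BASE,0.05,0.09,T2,0.05–0.09
bucktoni,aptera,PT,0.06,0.11,T2,0.06–0.11
bucktoni,aptera,URS,0.07,0.09,T2,0.07–0.09
bucktoni,aptera,FEMUR_III,0.22,0.41,T2,0.22–0.41
bucktoni,aptera,TIBIA_III,0.37,0.68,T2,0.37–0.68
bucktoni,aptera,HT_I,0.02,0.03,T2,0.02–0.03
bucktoni,aptera,HT_II,0.08,0.11,T2,0.08–0.11
bucktoni,aptera,SIPH,0.23,0.42,T2,0.23–0.42
bucktoni,aptera,CAUDA,0.13,0.23,T2,0.13–0.23
bucktoni,aptera,GPL,0.08,0.12,T2,0.08–0.12
bucktoni,aptera,GPW,0.3,0.20,T2,0.3–0.20
juchnevitschae,aptera,BL,1.52,1.82,T2,1.52–1.82
juchnevitschae,aptera,HW,0.34,0.37,T2,0.34–0.37
juchnevitschae,aptera,ANT,0.50,0.60,T2,0.50–0.60
juchnevitschae,aptera,ANT_III,0.12,0.16,T2,0.12–0.16
juchnevitschae,aptera,ANT_IV,0.07,0.08,T2,0.07–0.08
juchnevitschae,aptera,ANT_V,0.08,0.09,T2,0.08–0.09
juchnevitschae,aptera,ANT_VI,0.14,0.15,T2,0.14–0.15
juchnevitschae,aptera,BASE,0.08,0.08,T2,0.08
juchnevitschae,aptera,PT,0.05,0.07,T2,0.05–0.07
juchnevitschae,aptera,URS,0.07,0.07,T2,0.07
juchnevitschae,aptera,FEMUR_III,0.31,0.38,T2,0.31–0.38
juchnevitschae,aptera,TIBIA_III,0.50,0.60,T2,0.50–0.60
juchnevitschae,aptera,HT_I,0.02,0.03,T2,0.02–0.03
juchnevitschae,aptera,HT_II,0.09,0.10,T2,0.09–0.10
juchnevitschae,aptera,SIPH,0.27,0.33,T2,0.27–0.33
juchnevitschae,aptera,CAUDA,0.16,0.18,T2,0.16–0.18
juchnevitschae,aptera,GPL,0.10,0.12,T2,0.10–0.12
juchnevitschae,aptera,GPW,0.13,0.16,T2,0.13–0.16
oezdemirae,aptera,BL,1.09,1.13,T2,1.09–1.13
oezdemirae,aptera,HW,0.25,0.26,T2,0.25–0.26
oezdemirae,aptera,ANT,0.44,0.44,T2,0.44
oezdemirae,aptera,ANT_III,0.08,0.10,T2,0.08–0.10
oezdemirae,aptera,ANT_IV,0.05,0.07,T2,0.05–0.07
oezdemirae,aptera,ANT_V,0.07,0.07,T2,0.07
oezdemirae,aptera,ANT_VI,0.13,0.14,T2,0.13–0.14
oezdemirae,aptera,BASE,0.06,0.06,T2,0.06
oezdemirae,aptera,PT,0.07,0.08,T2,0.07–0.08
oezdemirae,aptera,URS,0.07,0.07,T2,0.07
oezdemirae,aptera,FEMUR_III,0.21,0.21,T2,0.21
oezdemirae,aptera,TIBIA_III,0.35,0.35,T2,0.35
oezdemirae,aptera,HT_I,0.02,0.02,T2,0.02
oezdemirae,aptera,HT_II,0.08,0.08,T2,0.08
oezdemirae,aptera,SIPH,0.23,0.25,T2,0.23–0.25
oezdemirae,aptera,CAUDA,0.12,0.14,T2,0.12–0.14
oezdemirae,aptera,GPL,0.09,0.09,T2,0.09
oezdemirae,aptera,GPW,0.14,0.14,T2,0.14
rezwanii,aptera,BL,1.10,1.60,T2,1.10–1.60
rezwanii,aptera,HW,0.25,0.32,T2,0.25–0.32
rezwanii,aptera,ANT,0.48,0.63,T2,0.48–0.63
rezwanii,aptera,ANT_III,0.12,0.18,T2,0.12–0.18
rezwanii,aptera,ANT_IV,0.05,0.08,T2,0.05–0.08
rezwanii,aptera,ANT_V,0.06,0.09,T2,0.06–0.09
rezwanii,aptera,ANT_VI,0.14,0.17,T2,0.14–0.17
rezwanii,aptera,BASE,0.06,0.07,T2,0.06–0.07
rezwanii,aptera,PT,0.08,0.10,T2,0.08–0.10
rezwanii,aptera,URS,0.07,0.08,T2,0.07–0.08
rezwanii,aptera,FEMUR_III,0.23,0.32,T2,0.23–0.32
rezwanii,aptera,TIBIA_III,0.38,0.53,T2,0.38–0.53
rezwanii,aptera,HT_I,0.02,0.03,T2,0.02–0.03
rezwanii,aptera,HT_II,0.08,0.10,T2,0.08–0.10
rezwanii,aptera,SIPH,0.22,0.31,T2,0.22–0.31
rezwanii,aptera,CAUDA,0.12,0.17,T2,0.12–0.17
rezwanii,aptera,GPL,0.08,0.12,T2,0.08–0.12
rezwanii,aptera,GPW,0.13,0.14,T2,0.13–0.14
rosarum,aptera,BL,1.04,2.20,T2,1.04–2.20
rosarum,aptera,HW,0.23,0.38,T2,0.23–0.38
rosarum,aptera,ANT,0.42,0.89,T2,0.42–0.89
rosarum,aptera,ANT_III,0.09,0.26,T2,0.09–0.26
rosarum,aptera,ANT_IV,0.04,0.14,T2,0.04–0.14
rosarum,aptera,ANT_V,0.06,0.13,T2,0.06–0.13
rosarum,aptera,ANT_VI,0.15,0.24,T2,0.15–0.24
rosarum,aptera,BASE,0.06,0.10,T2,0.06–0.10
rosarum,aptera,PT,0.08,0.15,T2,0.08–0.15
rosarum,aptera,URS,0.047,0.10,T2,0.047–0.10
rosarum,aptera,FEMUR_III,0.19,0.45,T2,0.19–0.45
rosarum,aptera,TIBIA_III,0.30,0.79,T2,0.30–0.79
rosarum,aptera,HT_I,0.02,0.03,T2,0.02–0.03
rosarum,aptera,HT_II,0.07,0.12,T2,0.07–0.12
rosarum,aptera,SIPH,0.21,0.46,T2,0.21–0.46
rosarum,aptera,CAUDA,0.13,0.25,T2,0.13–0.25
rosarum,aptera,GPL,0.08,0.15,T2,0.08–0.15
rosarum,aptera,GPW,0.17,0.22,T2,0.17–0.22
tianshanica,aptera,BL,1.95,2.00,T2,1.95–2.00
tianshanica,aptera,HW,0.34,0.36,T2,0.34–0.36
tianshanica,aptera,ANT,0.16,0.18,T2,0.16–0.18
tianshanica,aptera,ANT_III,0.16,0.18,T2,0.16–0.18
tianshanica,aptera,ANT_IV,0.11,0.13,T2,0.11–0.13
tianshanica,aptera,ANT_V,0.10,0.13,T2,0.10–0.13
tianshanica,aptera,ANT_VI,0.19,0.22,T2,0.19–0.22
tianshanica,aptera,BASE,0.09,0.10,T2,0.09–0.10
tianshanica,aptera,PT,0.10,0.12,T2,0.10–0.12
tianshanica,aptera,URS,0.08,0.08,T2,0.08
tianshanica,aptera,FEMUR_III,0.40,0.42,T2,0.40–0.42
tianshanica,aptera,TIBIA_III,0.67,0.68,T2,0.67–0.68
tianshanica,aptera,HT_I,0.03,0.03,T2,0.03
tianshanica,aptera,HT_II,0.10,0.10,T2,0.10
tianshanica,aptera,SIPH,0.41,0.42,T2,0.41–0.42
tianshanica,aptera,CAUDA,0.19,0.20,T2,0.19–0.20
tianshanica,aptera,GPL,0.09,0.10,T2,0.09–0.10
tianshanica,aptera,GPW,0.16,0.17,T2,0.16–0.17
tuatayae,aptera,BL,2.07,2.32,T2,2.07–2.32
tuatayae,aptera,HW,0.36,0.40,T2,0.36–0.40
tuatayae,aptera,ANT,0.66,0.81,T2,0.66–0.81
tuatayae,aptera,ANT_III,0.21,0.26,T2,0.21–0.26
tuatayae,aptera,ANT_IV,0.08,1.10,T2,0.08–1.10
tuatayae,aptera,ANT_V,0.08,0.12,T2,0.08–0.12
tuatayae,aptera,ANT_VI,0.16,0.19,T2,0.16–0.19
tuatayae,aptera,BASE,0.08,0.09,T2,0.08–0.09
tuatayae,aptera,PT,0.07,0.10,T2,0.07–0.10
tuatayae,aptera,URS,0.08,0.09,T2,0.08–0.09
tuatayae,aptera,FEMUR_III,0.39,0.45,T2,0.39–0.45
tuatayae,aptera,TIBIA_III,0.50,0.75,T2,0.50–0.75
tuatayae,aptera,HT_I,0.03,0.04,T2,0.03–0.04
tuatayae,aptera,HT_II,0.11,0.12,T2,0.11–0.12
tuatayae,aptera,SIPH,0.41,0.44,T2,0.41–0.44
tuatayae,aptera,CAUDA,0.20,0.25,T2,0.20–0.25
tuatayae,aptera,GPL,0.12,0.15,T2,0.12–0.15
tuatayae,aptera,GPW,0.17,0.20,T2,0.17–0.20
turanica,aptera,BL,1.65,2.45,T2,1.65–2.45
turanica,aptera,HW,0.29,0.39,T2,0.29–0.39
turanica,aptera,ANT,0.57,0.92,T2,0.57–0.92
turanica,aptera,ANT_III,0.15,0.28,T2,0.15–0.28
turanica,aptera,ANT_IV,0.06,0.14,T2,0.06–0.14
turanica,aptera,ANT_V,0.08,0.13,T2,0.08–0.13
turanica,aptera,ANT_VI,0.16,0.24,T2,0.16–0.24
turanica,aptera,BASE,0.07,0.11,T2,0.07–0.11
turanica,aptera,PT,0.09,0.14,T2,0.09–0.14
turanica,aptera,URS,0.07,0.10,T2,0.07–0.10
turanica,aptera,FEMUR_III,0.31,0.44,T2,0.31–0.44
turanica,aptera,TIBIA_III,0.50,0.74,T2,0.50–0.74
turanica,aptera,HT_I,0.02,0.04,T2,0.02–0.04
turanica,aptera,HT_II,0.09,0.12,T2,0.09–0.12
turanica,aptera,SIPH,0.30,0.44,T2,0.30–0.44
turanica,aptera,CAUDA,0.16,0.26,T2,0.16–0.26
turanica,aptera,GPL,0.08,0.14,T2,0.08–0.14
turanica,aptera,GPW,0.15,0.23,T2,0.15–0.23
avariolosa,aptera,BL,2.00,2.00,T2,2.00
avariolosa,aptera,HW,0.35,0.35,T2,0.35
avariolosa,aptera,ANT,1.22,1.26,T2,1.22–1.26
avariolosa,aptera,ANT_III,0.32,0.38,T2,0.32–0.38
avariolosa,aptera,ANT_IV,0.20,0.20,T2,0.20
avariolosa,aptera,ANT_V,0.17,0.18,T2,0.17–0.18
avariolosa,aptera,ANT_VI,0.30,0.35,T2,0.30–0.35
avariolosa,aptera,BASE,0.10,0.13,T2,0.10–0.13
avariolosa,aptera,PT,0.20,0.22,T2,0.20–0.22
avariolosa,aptera,URS,0.09,0.09,T2,0.09
avariolosa,aptera,FEMUR_III,0.57,0.58,T2,0.57–0.58
avariolosa,aptera,TIBIA_III,0.98,0.99,T2,0.98–0.99
avariolosa,aptera,HT_I,0.04,0.04,T2,0.04
avariolosa,aptera,HT_II,0.10,0.11,T2,0.10–0.11
avariolosa,aptera,SIPH,0.42,0.44,T2,0.42–0.44
avariolosa,aptera,CAUDA,0.17,0.19,T2,0.17–0.19
avariolosa,aptera,GPL,0.11,0.11,T2,0.11
avariolosa,aptera,GPW,0.23,0.23,T2,0.23
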