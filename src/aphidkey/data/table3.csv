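taxon,morph,character_id,lo,hi,provenance,as_printed
bucktoni,alata,BL,1.50,1.92,T3,1.50–1.92
bucktoni,alata,HW,0.28,0.34,T3,0.28–0.34
bucktoni,alata,ANT,0.76,1.02,T3,0.76–1.02
bucktoni,alata,ANT_III,0.27,0.38,T3,0.27–0.38
bucktoni,alata,ANT_IV,0.12,0.16,T3,0.12–0.16
bucktoni,alata,ANT_V,0.10,0.16,T3,0.10–0.16
bucktoni,alata,ANT_VI,0.17,0.25,T3,0.17–0.25
bucktoni,alata,BASE,0.08,0.10,T3,0.08–0.10
bucktoni,alata,PT,0.09,0.15,T3,0.09–0.15
bucktoni,alata,URS,0.07,0.09,T3,0.07–0.09
bucktoni,alata,FEMUR_III,0.36,0.47,T3,0.36–0.47
bucktoni,alata,TIBIA_III,0.63,0.86,T3,0.63–0.86
bucktoni,alata,HT_I,0.02,0.04,T3,0.02–0.04
bucktoni,alata,HT_II,0.10,0.12,T3,0.10–0.12
bucktoni,alata,SIPH,0.21,0.26,T3,0.21–0.26
bucktoni,alata,CAUDA,0.14,0.19,T3,0.14–0.19
bucktoni,alata,GPL,0.09,0.11,T3,0.09–0.11
bucktoni,alata,GPW,0.16,0.23,T3,0.16–0.23
juchnevitschae,alata,BL,1.62,1.62,T3,1.62
juchnevitschae,alata,HW,0.31,0.31,T3,0.31
juchnevitschae,alata,ANT,0.72,0.74,T3,0.72–0.74
juchnevitschae,alata,ANT_III,0.22,0.22,T3,0.22
juchnevitschae,alata,ANT_IV,0.13,0.13,T3,0.13
juchnevitschae,alata,ANT_V,0.11,0.12,T3,0.11–0.12
juchnevitschae,alata,ANT_VI,0.16,0.17,T3,0.16–0.17
juchnevitschae,alata,BASE,0.10,0.10,T3,0.10
juchnevitschae,alata,PT,0.06,0.07,T3,0.06–0.07
juchnevitschae,alata,URS,0.07,0.07,T3,0.07
juchnevitschae,alata,FEMUR_III,0.39,0.40,T3,0.39–0.40
juchnevitschae,alata,TIBIA_III,0.71,0.73,T3,0.71–0.73
juchnevitschae,alata,HT_I,0.02,0.03,T3,0.02–0.03
juchnevitschae,alata,HT_II,0.10,0.11,T3,0.10–0.11
juchnevitschae,alata,SIPH,0.23,0.25,T3,0.23–0.25
juchnevitschae,alata,CAUDA,0.14,0.14,T3,0.14
juchnevitschae,alata,GPL,0.10,0.10,T3,0.10
juchnevitschae,alata,GPW,0.16,0.16,T3,0.16
rezwanii,alata,BL,1.47,1.50,T3,1.47–1.50
rezwanii,alata,HW,0.30,0.32,T3,0.30–0.32
rezwanii,alata,ANT,0.67,0.73,T3,0.67–0.73
rezwanii,alata,ANT_III,0.24,0.25,T3,0.24–0.25
rezwanii,alata,ANT_IV,0.06,0.07,T3,0.06–0.07
rezwanii,alata,ANT_V,0.09,0.11,T3,0.09–0.11
rezwanii,alata,ANT_VI,0.17,0.20,T3,0.17–0.20
rezwanii,alata,BASE,0.08,0.10,T3,0.08–0.10
rezwanii,alata,PT,0.08,0.10,T3,0.08–0.10
rezwanii,alata,URS,0.07,0.07,T3,0.07
rezwanii,alata,FEMUR_III,0.35,0.37,T3,0.35–0.37
rezwanii,alata,TIBIA_III,0.66,0.70,T3,0.66–0.70
rezwanii,alata,HT_I,0.03,0.03,T3,0.03
rezwanii,alata,HT_II,0.09,0.09,T3,0.09
rezwanii,alata,SIPH,0.25,0.25,T3,0.25
rezwanii,alata,CAUDA,0.11,0.12,T3,0.11–0.12
rezwanii,alata,GPL,0.07,0.08,T3,0.07–0.08
rezwanii,alata,GPW,0.15,0.19,T3,0.15–0.19
rosarum,alata,BL,1.85,2.07,T3,1.85–2.07
rosarum,alata,HW,0.34,0.37,T3,0.34–0.37
rosarum,alata,ANT,1.11,1.35,T3,1.11–1.35
rosarum,alata,ANT_III,0.37,0.46,T3,0.37–0.46
rosarum,alata,ANT_IV,0.19,0.22,T3,0.19–0.22
rosarum,alata,ANT_V,0.17,0.22,T3,0.17–0.22
rosarum,alata,ANT_VI,0.26,0.36,T3,0.26–0.36
rosarum,alata,BASE,0.11,0.13,T3,0.11–0.13
rosarum,alata,PT,0.15,0.23,T3,0.15–0.23
rosarum,alata,URS,0.08,0.09,T3,0.08–0.09
rosarum,alata,FEMUR_III,0.45,0.54,T3,0.45–0.54
rosarum,alata,TIBIA_III,0.86,1.02,T3,0.86–1.02
rosarum,alata,HT_I,0.03,0.03,T3,0.03
rosarum,alata,HT_II,0.10,0.13,T3,0.10–0.13
rosarum,alata,SIPH,0.25,0.31,T3,0.25–0.31
rosarum,alata,CAUDA,0.15,0.18,T3,0.15–0.18
rosarum,alata,GPL,0.11,0.13,T3,0.11–0.13
rosarum,alata,GPW,0.18,0.23,T3,0.18–0.23
tianshanica,alata,BL,2.02,2.02,T3,2.02
tianshanica,alata,HW,0.34,0.34,T3,0.34
tianshanica,alata,ANT,1.16,1.21,T3,1.16–1.21
tianshanica,alata,ANT_III,0.34,0.34,T3,0.34
tianshanica,alata,ANT_IV,0.22,0.24,T3,0.22–0.24
tianshanica,alata,ANT_V,0.21,0.21,T3,0.21
tianshanica,alata,ANT_VI,0.27,0.29,T3,0.27–0.29
tianshanica,alata,BASE,0.11,0.13,T3,0.11–0.13
tianshanica,alata,PT,0.16,0.16,T3,0.16
tianshanica,alata,URS,0.07,0.07,T3,0.07
tianshanica,alata,FEMUR_III,0.48,0.48,T3,0.48
tianshanica,alata,TIBIA_III,0.81,0.83,T3,0.81–0.83
tianshanica,alata,HT_I,0.02,0.02,T3,0.02
tianshanica,alata,HT_II,0.09,0.09,T3,0.09
tianshanica,alata,SIPH,0.27,0.27,T3,0.27
tianshanica,alata,CAUDA,0.14,0.14,T3,0.14
tianshanica,alata,GPL,0.11,0.11,T3,0.11
tianshanica,alata,GPW,0.20,0.20,T3,0.20
turanica,alata,BL,1.87,1.95,T3,1.87–1.95
turanica,alata,HW,0.30,0.34,T3,0.30–0.34
turanica,alata,ANT,0.84,0.91,T3,0.84–0.91
turanica,alata,ANT_III,0.30,0.34,T3,0.30–0.34
turanica,alata,ANT_IV,0.10,0.14,T3,0.10–0.14
turanica,alata,ANT_V,0.10,0.13,T3,0.10–0.13
turanica,alata,ANT_VI,0.20,0.21,T3,0.20–0.21
turanica,alata,BASE,0.09,0.09,T3,0.09
turanica,alata,PT,0.10,0.12,T3,0.10–0.12
turanica,alata,URS,0.08,0.08,T3,0.08
turanica,alata,FEMUR_III,0.41,0.45,T3,0.41–0.45
turanica,alata,TIBIA_III,0.76,0.80,T3,0.76–0.80
turanica,alata,HT_I,0.02,0.03,T3,0.02–0.03
turanica,alata,HT_II,0.11,0.15,T3,0.11–0.15
turanica,alata,SIPH,0.25,0.29,T3,0.25–0.29
turanica,alata,CAUDA,0.17,0.19,T3,0.17–0.19
turanica,alata,GPL,0.08,0.12,T3,0.08–0.12
turanica,alata,GPW,0.17,0.18,T3,0.17–0.18
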