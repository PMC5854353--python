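taxon,morph,character_id,lo,hi,provenance,as_printed
bucktoni,fundatrix,BL,2.10,2.60,T1,2.10–2.60
bucktoni,fundatrix,HW,0.37,0.43,T1,0.37–0.43
bucktoni,fundatrix,ANT,0.60,0.70,T1,0.60–0.70
bucktoni,fundatrix,ANT_III,0.24,0.27,T1,0.24–0.27
bucktoni,fundatrix,ANT_IV,0.07,0.10,T1,0.07–0.10
bucktoni,fundatrix,ANT_V,0.16,0.18,T1,0.16–0.18
bucktoni,fundatrix,BASE,0.08,0.09,T1,0.08–0.09
bucktoni,fundatrix,PT,0.08,0.09,T1,0.08–0.09
bucktoni,fundatrix,URS,0.09,0.10,T1,0.09–0.10
bucktoni,fundatrix,FEMUR_III,0.35,0.42,T1,0.35–0.42
bucktoni,fundatrix,TIBIA_III,0.60,0.68,T1,0.60–0.68
bucktoni,fundatrix,HT_I,0.03,0.04,T1,0.03–0.04
bucktoni,fundatrix,HT_II,0.10,0.12,T1,0.10–0.12
bucktoni,fundatrix,SIPH,0.31,0.44,T1,0.31–0.44
bucktoni,fundatrix,CAUDA,0.22,0.29,T1,0.22–0.29
rezwanii,fundatrix,BL,1.45,1.62,T1,1.45–1.62
rezwanii,fundatrix,HW,0.34,0.35,T1,0.34–0.35
rezwanii,fundatrix,ANT,0.40,0.47,T1,0.40–0.47
rezwanii,fundatrix,ANT_III,0.13,0.16,T1,0.13–0.16
rezwanii,fundatrix,ANT_IV,0.06,0.08,T1,0.06–0.08
rezwanii,fundatrix,ANT_V,0.10,0.12,T1,0.10–0.12
rezwanii,fundatrix,BASE,0.06,0.07,T1,0.06–0.07
rezwanii,fundatrix,PT,0.04,0.05,T1,0.04–0.05
rezwanii,fundatrix,URS,0.07,0.08,T1,0.07–0.08
rezwanii,fundatrix,FEMUR_III,0.28,0.34,T1,0.28–0.34
rezwanii,fundatrix,TIBIA_III,0.50,0.57,T1,0.50–0.57
rezwanii,fundatrix,HT_I,0.02,0.03,T1,0.02–0.03
rezwanii,fundatrix,HT_II,0.07,0.08,T1,0.07–0.08
rezwanii,fundatrix,SIPH,0.30,0.35,T1,0.30–0.35
rezwanii,fundatrix,CAUDA,0.12,0.13,T1,0.12–0.13
rosarum,fundatrix,BL,1.10,2.17,T1,1.10–2.17
rosarum,fundatrix,HW,0.28,0.39,T1,0.28–0.39
rosarum,fundatrix,ANT,0.44,0.72,T1,0.44–0.72
rosarum,fundatrix,ANT_III,0.15,0.31,T1,0.15–0.31
rosarum,fundatrix,ANT_IV,0.06,0.10,T1,0.06–0.10
rosarum,fundatrix,ANT_V,0.14,0.19,T1,0.14–0.19
rosarum,fundatrix,BASE,0.06,0.10,T1,0.06–0.10
rosarum,fundatrix,PT,0.07,0.09,T1,0.07–0.09
rosarum,fundatrix,URS,0.07,0.08,T1,0.07–0.08
rosarum,fundatrix,FEMUR_III,0.20,0.36,T1,0.20–0.36
rosarum,fundatrix,TIBIA_III,0.37,0.64,T1,0.37–0.64
rosarum,fundatrix,HT_I,0.02,0.03,T1,0.02–0.03
rosarum,fundatrix,HT_II,0.08,0.10,T1,0.08–0.10
rosarum,fundatrix,SIPH,0.26,0.38,T1,0.26–0.38
rosarum,fundatrix,CAUDA,0.14,0.23,T1,0.14–0.23
tianshanica,fundatrix,BL,2.07,2.25,T1,2.07–2.25
tianshanica,fundatrix,HW,0.34,0.38,T1,0.34–0.38
tianshanica,fundatrix,ANT,0.58,0.66,T1,0.58–0.66
tianshanica,fundatrix,ANT_III,0.22,0.25,T1,0.22–0.25
tianshanica,fundatrix,ANT_IV,0.10,0.12,T1,0.10–0.12
tianshanica,fundatrix,ANT_V,0.16,0.18,T1,0.16–0.18
tianshanica,fundatrix,BASE,0.09,0.09,T1,0.09
tianshanica,fundatrix,PT,0.07,0.09,T1,0.07–0.09
tianshanica,fundatrix,URS,0.08,0.09,T1,0.08–0.09
tianshanica,fundatrix,FEMUR_III,0.37,0.41,T1,0.37–0.41
tianshanica,fundatrix,TIBIA_III,0.62,0.70,T1,0.62–0.70
tianshanica,fundatrix,HT_I,0.03,0.03,T1,0.03
tianshanica,fundatrix,HT_II,0.10,0.10,T1,0.10
tianshanica,fundatrix,SIPH,0.39,0.42,T1,0.39–0.42
tianshanica,fundatrix,CAUDA,0.19,0.22,T1,0.19–0.22
tuatayae,fundatrix,BL,1.94,2.25,T1,1.94–2.25
tuatayae,fundatrix,HW,0.39,0.41,T1,0.39–0.41
tuatayae,fundatrix,ANT,0.61,0.62,T1,0.61–0.62
tuatayae,fundatrix,ANT_III,0.19,0.27,T1,0.19–0.27
tuatayae,fundatrix,ANT_IV,0.08,0.10,T1,0.08–0.10
tuatayae,fundatrix,ANT_V,0.17,0.17,T1,0.17
tuatayae,fundatrix,BASE,0.08,0.09,T1,0.08–0.09
tuatayae,fundatrix,PT,0.07,0.08,T1,0.07–0.08
tuatayae,fundatrix,URS,0.09,0.10,T1,0.09–0.10
tuatayae,fundatrix,FEMUR_III,0.40,0.41,T1,0.40–0.41
tuatayae,fundatrix,TIBIA_III,0.65,0.71,T1,0.65–0.71
tuatayae,fundatrix,HT_I,0.03,0.04,T1,0.03–0.04
tuatayae,fundatrix,HT_II,0.11,0.11,T1,0.11
tuatayae,fundatrix,SIPH,0.43,0.46,T1,0.43–0.46
tuatayae,fundatrix,CAUDA,0.23,0.25,T1,0.23–0.25
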