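taxon,morph,character_id,lo,hi,provenance,as_printed
canadensis,aptera,BL,1.35,1.40,T6,1.35–1.40
canadensis,aptera,HW,0.25,0.31,T6,0.25–0.31
canadensis,aptera,ANT,0.36,0.40,T6,0.36–0.40
canadensis,aptera,ANT_III,0.06,0.07,T6,0.06–0.07
canadensis,aptera,ANT_IV,0.05,0.05,T6,0.05
canadensis,aptera,ANT_V,0.05,0.06,T6,0.05–0.06
canadensis,aptera,ANT_VI,0.13,0.14,T6,0.13–0.14
canadensis,aptera,BASE,0.07,0.08,T6,0.07–0.08
canadensis,aptera,PT,0.05,0.06,T6,0.05–0.06
canadensis,aptera,URS,0.07,0.07,T6,0.07
canadensis,aptera,FEMUR_III,0.19,0.20,T6,0.19–0.20
canadensis,aptera,TIBIA_III,0.32,0.33,T6,0.32–0.33
canadensis,aptera,HT_I,0.01,0.03,T6,0.01–0.03
canadensis,aptera,HT_II,0.08,0.09,T6,0.08–0.09
canadensis,aptera,SIPH,0.28,0.29,T6,0.28–0.29
canadensis,aptera,CAUDA,0.15,0.17,T6,0.15–0.17
canadensis,alata,BL,1.04,1.13,T6,1.04–1.13
canadensis,alata,HW,0.24,0.27,T6,0.24–0.27
canadensis,alata,ANT,0.66,0.80,T6,0.66–0.80
canadensis,alata,ANT_III,0.20,0.26,T6,0.20–0.26
canadensis,alata,ANT_IV,0.10,0.13,T6,0.10–0.13
canadensis,alata,ANT_V,0.10,0.10,T6,0.10
canadensis,alata,ANT_VI,0.19,0.24,T6,0.19–0.24
canadensis,alata,BASE,0.08,0.10,T6,0.08–0.10
canadensis,alata,PT,0.11,0.14,T6,0.11–0.14
canadensis,alata,URS,0.06,0.07,T6,0.06–0.07
canadensis,alata,FEMUR_III,0.23,0.25,T6,0.23–0.25
canadensis,alata,TIBIA_III,0.44,0.47,T6,0.44–0.47
canadensis,alata,HT_I,0.02,0.02,T6,0.02
canadensis,alata,HT_II,0.08,0.10,T6,0.08–0.10
canadensis,alata,SIPH,0.15,0.18,T6,0.15–0.18
canadensis,alata,CAUDA,0.09,0.10,T6,0.09–0.10
canadensis,ovipara,BL,1.15,1.22,T6,1.15–1.22
canadensis,ovipara,HW,0.24,0.25,T6,0.24–0.25
canadensis,ovipara,ANT,0.36,0.43,T6,0.36–0.43
canadensis,ovipara,ANT_III,0.06,0.08,T6,0.06–0.08
canadensis,ovipara,ANT_IV,0.05,0.08,T6,0.05–0.08
canadensis,ovipara,ANT_V,0.05,0.06,T6,0.05–0.06
canadensis,ovipara,ANT_VI,0.12,0.12,T6,0.12
canadensis,ovipara,BASE,0.06,0.07,T6,0.06–0.07
canadensis,ovipara,PT,0.04,0.06,T6,0.04–0.06
canadensis,ovipara,URS,0.06,0.06,T6,0.06
canadensis,ovipara,FEMUR_III,0.18,0.18,T6,0.18
canadensis,ovipara,TIBIA_III,0.27,0.27,T6,0.27
canadensis,ovipara,HT_I,0.02,0.02,T6,0.02
canadensis,ovipara,HT_II,0.07,0.07,T6,0.07
canadensis,ovipara,SIPH,0.10,0.11,T6,0.10–0.11
canadensis,ovipara,CAUDA,0.10,0.12,T6,0.10–0.12
canadensis,male,BL,1.00,1.00,T6,1.00
canadensis,male,HW,0.22,0.22,T6,0.22
canadensis,male,ANT,0.89,0.92,T6,0.89–0.92
canadensis,male,ANT_III,0.29,0.29,T6,0.29
canadensis,male,ANT_IV,0.15,0.16,T6,0.15–0.16
canadensis,male,ANT_V,0.14,0.15,T6,0.14–0.15
canadensis,male,ANT_VI,0.20,0.21,T6,0.20–0.21
canadensis,male,BASE,0.10,0.11,T6,0.10–0.11
canadensis,male,PT,0.09,0.11,T6,0.09–0.11
canadensis,male,URS,0.07,0.07,T6,0.07
canadensis,male,FEMUR_III,0.25,0.25,T6,0.25
canadensis,male,TIBIA_III,0.44,0.45,T6,0.44–0.45
canadensis,male,HT_I,0.02,0.02,T6,0.02
canadensis,male,HT_II,0.09,0.09,T6,0.09
canadensis,male,SIPH,0.09,0.10,T6,0.09–0.10
canadensis,male,CAUDA,0.07,0.07,T6,0.07
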