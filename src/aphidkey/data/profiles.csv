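taxon,morph,n_examined,source
bucktoni,fundatrix,3,T1
rezwanii,fundatrix,21,T1
rosarum,fundatrix,10,T1
tianshanica,fundatrix,3,T1
tuatayae,fundatrix,3,T1
bucktoni,aptera,94,T2
juchnevitschae,aptera,4,T2
oezdemirae,aptera,2,T2
rezwanii,aptera,35,T2
rosarum,aptera,120,T2
tianshanica,aptera,2,T2
tuatayae,aptera,12,T2
turanica,aptera,41,T2
avariolosa,aptera,1,T2
bucktoni,alata,13,T3
juchnevitschae,alata,1,T3
rezwanii,alata,2,T3
rosarum,alata,21,T3
tianshanica,alata,2,T3
turanica,alata,6,T3
bucktoni,ovipara,13,T4
oezdemirae,ovipara,4,T4
rezwanii,ovipara,4,T4
rosarum,ovipara,19,T4
turanica,ovipara,8,T4
bucktoni,male,7,T5
oezdemirae,male,3,T5
rezwanii,male,2,T5
rosarum,male,10,T5
turanica,male,2,T5
canadensis,aptera,5,T6
canadensis,alata,2,T6
canadensis,ovipara,3,T6
canadensis,male,1,T6
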