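site,transect,species_code,count
HX,T1,LC,20
HX,T1,NAA,4
HX,T1,NAC,4
HX,T2,LC,20
HX,T2,NAA,4
HX,T2,NAB,4
HX,T3,LC,20
HX,T3,NAB,4
HX,T3,NAC,4
HX,T4,PJ,5
HX,T4,NBA,4
HX,T4,NBC,4
HX,T5,PJ,5
HX,T5,NBA,4
HX,T5,NBB,4
HX,T6,PJ,5
HX,T6,NBB,4
HX,T6,NBC,4
HY,T1,LC,4
HY,T1,NAA,3
HY,T1,NAC,3
HY,T2,LC,4
HY,T2,NAA,3
HY,T2,NAB,3
HY,T3,LC,4
HY,T3,NAB,3
HY,T3,NAC,3
HY,T4,PJ,18
HY,T4,NBA,3
HY,T4,NBC,3
HY,T5,PJ,18
HY,T5,NBA,3
HY,T5,NBB,3
HY,T6,PJ,18
HY,T6,NBB,3
HY,T6,NBC,3
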