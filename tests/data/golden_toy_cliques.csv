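site,clique_rank,species_code,is_hub,status
HX,1,LC,True,invasive
HX,1,NAA,False,native
HX,1,NAB,False,native
HX,1,NAC,False,native
HX,2,NBA,False,native
HX,2,NBB,False,native
HX,2,NBC,False,native
HX,2,PJ,True,invasive
HY,1,LC,True,invasive
HY,1,NAA,False,native
HY,1,NAB,False,native
HY,1,NAC,False,native
HY,2,NBA,False,native
HY,2,NBB,False,native
HY,2,NBC,False,native
HY,2,PJ,True,invasive
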