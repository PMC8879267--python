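site,clique_rank,species_code,is_hub
SV,1,LL,True
SV,1,CF,False
SV,1,PP,False
SV,1,AE,False
SV,1,CAR,False
SV,2,AI,True
SV,2,LC,False
SV,2,GRE,False
SV,2,HI,False
SV,2,DS,False
SV,3,AV,True
SV,3,CS,False
SV,3,BR,False
SV,4,CD,True
SV,4,PJ,False
SV,4,DC,False
SV,4,MS,False
SV,5,TG,True
SV,5,AS,False
SV,5,ZM,False
SV,5,PC,False
TUQ,1,BR,True
TUQ,1,PJ,False
TUQ,1,CS,False
TUQ,2,AN,True
TUQ,2,CF,False
TUQ,2,AL,False
TUQ,2,PC,False
TUQ,3,GRE,True
TUQ,3,HI,False
TUQ,3,PP,False
TUQ,3,ZN,False
TUQ,3,DC,False
TUQ,4,AI,True
TUQ,4,CD,False
TUQ,4,AV,False
TUQ,5,LC,True
TUQ,5,BS,False
HK,1,SS,True
HK,1,PP,False
HK,1,CS,False
HK,1,EL,False
HK,2,LL,True
HK,2,MOA,False
HK,2,AV,False
HK,2,AN,False
HK,2,DS,False
HK,3,LC,True
HK,3,DC,False
HK,3,ZN,False
HK,3,AI,False
HK,4,PC,True
HK,4,CF,False
HK,4,GRE,False
HK,4,CD,False
HK,4,MK,False
HK,4,DR,False
HK,5,PJ,True
HK,5,BM,False
HK,5,MP,False
HK,5,AE,False
HK,5,TA,False
JCF,1,PJ,True
JCF,1,CS,False
JCF,1,CAR,False
JCF,1,AI,False
JCF,2,HI,True
JCF,2,PP,False
JCF,2,AA,False
JCF,2,CF,False
JCF,2,SS,False
JCF,2,TG,False
JCF,2,PC,False
JCF,3,LC,True
JCF,3,ZN,False
JCF,3,BM,False
MEH,1,LC,True
MEH,1,AV,False
MEH,1,AN,False
MEH,1,HI,False
MEH,1,PP,False
MEH,1,CF,False
MEH,2,CT,True
MEH,2,ZN,False
MEH,2,AL,False
MEH,2,GRE,False
MEH,3,ABU,True
MEH,3,CS,False
MEH,3,CD,False
MEH,4,AI,True
MEH,4,PJ,False
JNU,1,BR,True
JNU,1,LC,False
JNU,1,ZN,False
JNU,1,ZM,False
JNU,2,CD,True
JNU,2,AV,False
JNU,2,AI,False
JNU,2,AL,False
JNU,3,PJ,True
JNU,3,CS,False
JNU,3,DC,False
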