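code,scientific_name,status
LC,Lantana camara (toy),invasive
NAA,Nativa toyensis a,native
NAB,Nativa toyensis b,native
NAC,Nativa toyensis c,native
NBA,Nativa toyensis d,native
NBB,Nativa toyensis e,native
NBC,Nativa toyensis f,native
PJ,Prosopis juliflora (toy),invasive
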