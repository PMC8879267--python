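code,scientific_name,status
AA,Albizia amara,native
ABU,Abutilon indicum,native
AE,Ailanthus excelsa,native
AI,Azadirachta indica,introduced
AL,Acacia leucophloea,native
AN,Acacia nilotica,native
AS,Acacia senegal,native
AV,Adhatoda vasica,native
BM,Bombax malabarica,native
BR,Balanites roxburghii,native
BS,Bougainvillea spectabilis,native
CAR,Carissa spinarum,native
CD,Capparis decidua,native
CF,Cassia fistula,native
CS,Capparis sepiaria,native
CT,Cassia tora,introduced
DC,Diospyros cordifolia,native
DR,Drypetes roxburghii,native
DS,Dalbergia sissoo,native
EL,Ehretia laevis,native
GRE,Grewia tenax,native
HI,Holoptelea integrifolia,native
LC,Lantana camara,invasive
LL,Leucaena leucocephala,invasive
MK,Murraya koenigii,native
MOA,Morus alba,introduced
MP,Milletia peguensis,native
MS,Maytenus senegalensis,native
PC,Prosopis cineraria,native
PJ,Prosopis juliflora,invasive
PP,Pongamia pinnata,native
SS,Senna siamea,native
TA,Terminalia arjuna,native
TG,Tectona grandis,native
ZM,Ziziphus mauritiana,native
ZN,Ziziphus nummularia,native
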