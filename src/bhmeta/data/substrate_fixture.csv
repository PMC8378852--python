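name,smiles,kind,label
bromobenzene,Brc1ccccc1,electrophile,Br_ARY
2-bromo-m-xylene,Cc1cccc(C)c1Br,electrophile,Br_ARY
3-bromopyridine,Brc1cccnc1,electrophile,Br_HAR
6-bromoquinoline,Brc1ccc2ncccc2c1,electrophile,Br_HAR
chlorobenzene,Clc1ccccc1,electrophile,Cl_ARY
2-chloropyridine,Clc1ccccn1,electrophile,Cl_HAR
2-chloroquinoline,Clc1ccc2ccccc2n1,electrophile,Cl_HAR
iodobenzene,Ic1ccccc1,electrophile,I_ARY
phenyl triflate,O=S(=O)(Oc1ccccc1)C(F)(F)F,electrophile,OTf_ARY
naphthalen-2-yl triflate,O=S(=O)(Oc1ccc2ccccc2c1)C(F)(F)F,electrophile,OTf_ARY
phenyl tosylate,Cc1ccc(S(=O)(=O)Oc2ccccc2)cc1,electrophile,OTs_ARY
fluorobenzene,Fc1ccccc1,electrophile,F_ARY
aniline,Nc1ccccc1,nucleophile,Aryl
3-aminopyridine,Nc1cccnc1,nucleophile,Aryl
diphenylamine,c1ccc(Nc2ccccc2)cc1,nucleophile,DiAryl
benzylamine,NCc1ccccc1,nucleophile,Alkyl
cyclohexylamine,NC1CCCCC1,nucleophile,Alkyl
morpholine,C1COCCN1,nucleophile,DiAlkyl
N-methylpiperazine,CN1CCNCC1,nucleophile,DiAlkyl
N-methylaniline,CNc1ccccc1,nucleophile,AlkylAryl
carbazole,c1ccc2c(c1)[nH]c1ccccc12,nucleophile,aromN
pyrrole,c1cc[nH]c1,nucleophile,aromN
2-hydroxypyridine,Oc1ccccn1,nucleophile,aromN
benzophenone imine,N=C(c1ccccc1)c1ccccc1,nucleophile,Ketimine
benzamide,NC(=O)c1ccccc1,nucleophile,Amide
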