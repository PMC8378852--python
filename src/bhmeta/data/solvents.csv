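name,smiles
toluene,Cc1ccccc1
1.4-dioxane,C1COCCO1
THF,C1CCOC1
DMF,CN(C)C=O
DMSO,CS(C)=O
water,O
tert-butanol,CC(C)(C)O
DME,COCCOC
NMP,CN1CCCC1=O
xylene,Cc1ccccc1C
benzene,c1ccccc1
ethanol,CCO
2-methyl-2-butanol,CCC(C)(C)O
acetonitrile,CC#N
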