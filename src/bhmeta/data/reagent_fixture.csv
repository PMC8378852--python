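name,smiles,role,ligand_kind
toluene,Cc1ccccc1,solvent,
1.4-dioxane,C1COCCO1,solvent,
THF,C1CCOC1,solvent,
DMF,CN(C)C=O,solvent,
water,O,solvent,
tert-butanol,CC(C)(C)O,solvent,
NMP,CN1CCCC1=O,solvent,
NaOtBu,CC(C)(C)[O-].[Na+],base,
KOtBu,CC(C)(C)[O-].[K+],base,
Cs2CO3,[Cs+].[Cs+].[O-]C([O-])=O,base,
K2CO3,[K+].[K+].[O-]C([O-])=O,base,
K3PO4,[K+].[K+].[K+].[O-]P(=O)([O-])[O-],base,
KOH,[K+].[OH-],base,
LiHMDS,C[Si](C)(C)[N-][Si](C)(C)C.[Li+],base,
P1-tBu phosphazene,CC(C)(C)N=P(N(C)C)(N(C)C)N(C)C,base,
PPh3,c1ccc(P(c2ccccc2)c2ccccc2)cc1,ligand,phosphine
P(tBu)3,CC(C)(C)P(C(C)(C)C)C(C)(C)C,ligand,phosphine
PCy3,C1CCC(P(C2CCCCC2)C2CCCCC2)CC1,ligand,phosphine
XPhos,CC(C)c1cc(C(C)C)c(-c2ccccc2P(C2CCCCC2)C2CCCCC2)c(C(C)C)c1,ligand,phosphine
SPhos,COc1cccc(OC)c1-c1ccccc1P(C1CCCCC1)C1CCCCC1,ligand,phosphine
RuPhos,CC(C)Oc1cccc(OC(C)C)c1-c1ccccc1P(C1CCCCC1)C1CCCCC1,ligand,phosphine
JohnPhos,CC(C)(C)P(c1ccccc1-c1ccccc1)C(C)(C)C,ligand,phosphine
P(o-tol)3,Cc1ccccc1P(c1ccccc1C)c1ccccc1C,ligand,phosphine
BINAP,c1ccc(P(c2ccccc2)c2ccc3ccccc3c2-c2c(P(c3ccccc3)c3ccccc3)ccc3ccccc23)cc1,ligand,phosphine
Xantphos,CC1(C)c2cccc(P(c3ccccc3)c3ccccc3)c2Oc2c(P(c3ccccc3)c3ccccc3)cccc21,ligand,phosphine
triisobutylphosphatrane,CC(C)CN1CCN2CCN(CC(C)C)P1N(CC(C)C)CC2,ligand,phosphine
dppf,[Fe+2].c1ccc(P(c2ccccc2)[c-]2cccc2)cc1.c1ccc(P(c2ccccc2)[c-]2cccc2)cc1,ligand,phosphine
triphenyl phosphite,c1ccc(OP(Oc2ccccc2)Oc2ccccc2)cc1,ligand,phosphine
PCl3,ClP(Cl)Cl,generic,
IPr-HCl,[Cl-].CC(C)c1cccc(C(C)C)c1[n+]1ccn(-c2c(C(C)C)cccc2C(C)C)c1,ligand,NHC
SIPr-HCl,[Cl-].CC(C)c1cccc(C(C)C)c1[N+]1=CN(c2c(C(C)C)cccc2C(C)C)CC1,ligand,NHC
IPr carbene,CC(C)c1cccc(C(C)C)c1N1C=CN(c2c(C(C)C)cccc2C(C)C)[C]1,ligand,NHC
Pd(OAc)2,CC(=O)O[Pd]OC(C)=O,metal_source,
Pd2(dba)3,O=C(/C=C/c1ccccc1)/C=C/c1ccccc1.O=C(/C=C/c1ccccc1)/C=C/c1ccccc1.O=C(/C=C/c1ccccc1)/C=C/c1ccccc1.[Pd].[Pd],metal_source,
PdCl2,Cl[Pd]Cl,metal_source,
Pd(PPh3)4,c1ccc(P(c2ccccc2)(c2ccccc2)->[Pd](<-P(c2ccccc2)(c2ccccc2)c2ccccc2)(<-P(c2ccccc2)(c2ccccc2)c2ccccc2)<-P(c2ccccc2)(c2ccccc2)c2ccccc2)cc1,metal_source,
ethyl acetate,CCOC(C)=O,generic,
18-crown-6,C1COCCOCCOCCOCCOCCO1,generic,
TBAB,CCCC[N+](CCCC)(CCCC)CCCC.[Br-],generic,
phenylboronic acid,OB(O)c1ccccc1,generic,
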