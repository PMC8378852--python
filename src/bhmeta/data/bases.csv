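name,smiles,strength_rank
LiHMDS,C[Si](C)(C)[N-][Si](C)(C)C.[Li+],1
KOtBu,CC(C)(C)[O-].[K+],2
NaOtBu,CC(C)(C)[O-].[Na+],3
P1-tBu phosphazene,CC(C)(C)N=P(N(C)C)(N(C)C)N(C)C,4
KOH,[K+].[OH-],5
NaOH,[Na+].[OH-],6
K3PO4,[K+].[K+].[K+].[O-]P(=O)([O-])[O-],7
Cs2CO3,[Cs+].[Cs+].[O-]C([O-])=O,8
K2CO3,[K+].[K+].[O-]C([O-])=O,9
DBU,C1CCC2=NCCCN2CC1,10
triethylamine,CCN(CC)CC,11
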