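# Leaving-group patterns anchored to an aromatic carbon, in priority order.
# Sulfonates come first so their fluorines / ring carbons are never counted
# as separate halide leaving groups.
OTf c-[OX2]-[SX4](=[OX1])(=[OX1])[CX4](F)(F)F
OTs c-[OX2]-[SX4](=[OX1])(=[OX1])-c1ccc([CH3])cc1
Br  c-[Br]
Cl  c-[Cl]
I   c-[I]
F   c-[F]
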