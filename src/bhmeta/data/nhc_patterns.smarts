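# N-heterocyclic carbene ligand patterns: free carbenes and azolium salt precursors.
[#6;X2;+0]1[#7][#6]~[#6][#7]1      # imidazol-2-ylidene / imidazolin-2-ylidene (free carbene)
[cH1]1[n+][c][c][n]1               # imidazolium salt precursor (aromatic form)
[#6;H1]1=[#7+][#6][#6][#7]1        # imidazolinium salt precursor (saturated form)
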