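# Residue side-chain SMILES fragments, attached at the alpha carbon.
# "[H]" marks glycine (no side chain).
Phe: Cc1ccccc1
Ala: C
Gly: "[H]"
Leu: CC(C)C
Val: C(C)C
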