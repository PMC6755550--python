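# Synthetic example probe scaffolds (hand-constructed macrolactones for
# demonstration and smoke tests; NOT transcriptions of any published
# bioactive macrolide structures).
CCC1OC(=O)C(C)C(O)C(C)C(O)C(C)(O)CC(C)C(=O)C(C)C(O)C1C probe_a_synthetic
CC1CC(C)C(=O)C(C=CC(O)CC(O)CCC(=O)O1)O probe_b_synthetic
O=C1CCCC(O)C(C)CCCC(OC)CCO1 probe_c_synthetic
CC1CCC(N)C(O)C(C)CCCCC(=O)OC1C probe_d_synthetic
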