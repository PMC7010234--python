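name	sequence
HLA-A_fwd	cgcagtcagtgctctagagctagcgGATTCTCCCCAGACSCCGAGG
HLA-A_rev	gtaatccagaggttgattgtcgacgcACAAGGCAGCTGTCTCACA
HLA-B_fwd	cgcagtcagtgctctagagctagcgCACCCGGACTCARARTCTCCT
HLA-B_rev	gtaatccagaggttgattgtcgacgcCCTTTTCAAGCTGTGAGAG
HLA-C_fwd	cgcagtcagtgctctagagctagcgTTCTCCCCAGASGCCGAGATG
HLA-C_rev	gtaatccagaggttgattgtcgacgcGTCTCAGGCTTTACAAGYGA
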