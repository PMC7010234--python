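UCN	TRAV	TRAJ	cdr3a_nt	cdr3a_aa	TRBV	TRBD	TRBJ	cdr3b_nt	cdr3b_aa
CMV1	TRAV3*01	TRAJ26*01	TGCGCTGTATACTATGGTCAGAATTTTGTCTTT	CAVYYGQNFVF	TRBV28*01	TRBD1*01	TRBJ1-1*01	TGCGCCAGCAGTAACCAGGGGTACACTGAAGCTTTCTTT	CASSNQGYTEAFF
CMV2	TRAV*3*01	TRAJ26*01	TGCGCTGACTACTATGGTCAGAATTTTGTCTTT	CADYYGQNFVF	TRBV28*01	TRBD1*01	TRBJ1-1*01	TGCGCCAGCAGTTACCAGGGTTACACTGAAGCTTTCTTT	CASSYQGYTEAFF
CMV3	TRAV25*01	TRAJ39*01	TGCGCCACTAATGCAGGCAACATGCTCACCTTT	CATNAGNMLTF	TRBV28*01	TRBD1*01	TRBJ2-3*01	TGCGCCAGCAGTTTCTTGACAGGGGTGGGGGATACGCAGTATTTT	CASSFLTGVGDTQYF
CMV4	TRAV3*01	TRAJ31*01	TGCGCTGTGAGAGACATAAATGCCAGACTCATGTTT	CAVRDINARLMF	TRBV12-3*01		TRBJ1-1*01	TGCGCCAGCAGTTCAGTGAACGAAGCTTTCTTT	CASSSVNEAFF
CMV5	TRAV3*01	TRAJ31*01	TGCGCTGTGAGAGACGTGAATGCCAGACTCATGTTT	CAVRDVNARLMF	TRBV12-3*01		TRBJ1-1*01	TGCGCCAGCAGTTCGGTCAATGAAGCTTTCTTT	CASSSVNEAFF
CMV6	TRAV35*01	TRAJ50*01	TGCGCTGGCCCAACGAAAACCTCCTACGACAAGGTGATATTT	CAGPTKTSYDKVIF	TRBV12-3*01		TRBJ1-2*01	TGCGCCAGCAGTTCGGCCTACTATGGCTACACCTTC	CASSSAYYGYTF
CMV7	TRAV26-2*01	TRAJ49*01	TGCATCCTGAGTGGCTCAGAGGGCCAGTTCTATTTT	CILSGSEGQFYF	TRBV29-1*01		TRBJ2-2*01	TGCAGCGTCCACTCTTATGGGGACACCGGGGAGCTGTTTTTT	CSVHSYGDTGELFF
CMV8	TRAV26-2*01	TRAJ47*01	TGCATCCTGAGACAGGAATATGGAAACAAACTGGTCTTT	CILRQEYGNKLVF	TRBV16*01		TRBJ2-7*01	TGCGCCAGCAGCCAAGGGGAGCTAGGGACTAGCGGGAGCCACGAGCAGTACTTC	CASSQGELGTSGSHEQYF
CMV9	TRAV3*01	TRAJ47*01	TGCGCTGTGGAATATGGAAACAAACTGGTCTTT	CAVEYGNKLVF	TRBV27*01		TRBJ2-7*01	TGCGCCAGCAGCCCCGTAGCGGGAGCCCCCCACGAGCAGTACTTC	CASSPVAGAPHEQYF
CMV10	TRAV24*01	TRAJ43*01	TGCGCCTTCCCGTACAATAACAATGACATGCGCTTT	CAFPYNNNDMRF	TRBV27*01	TRBD2*02	TRBJ1-1*01	TGCGCCAGCAGTTTAGAGGGTTACACTGAAGCTTTCTTT	CASSLEGYTEAFF
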