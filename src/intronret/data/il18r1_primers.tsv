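name	role	sequence	template	binding_start	binding_end	expected_product_bp	pair
human_ref_F	forward	ACGCCGAGTTTGAAGATCAGGGGT	NM_003855.2	545	568	687	human_ref
human_ref_R	reverse	CCCTGGGCAAAATCTCCACAGCA	NM_003855.2	1209	1231	687	human_ref
human_typeII_F	forward	ACGCCGAGTTTGAAGATCAGGGGT	NM_003855.2	545	568	874	human_typeII
human_typeII_R	reverse	ATACAGTTCCTGGGCCCGAGCA	chr2:hg19	103006939	103006960	874	human_typeII
rat_typeII_F	forward	CCAACGAAGAAGCCACAGACA	NM_001106905.2	1269	1289	463	rat_typeII
rat_typeII_R	reverse	AGCACGGGACATGTGAGGAGA	chr9:RGSC3.4	39652714	39652734	463	rat_typeII
rat_actb_F	forward	TACAACCTTCTTGCAGCTCCTCCG	NM_031144.2	28	51	649	rat_actb
rat_actb_R	reverse	TGTAGCCACGCTCGGTCAGG	NM_031144.2	657	676	649	rat_actb
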