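mirna_id	transcript_id	site_start	region	binding_type
hsa-miR-192-5p|0	ENST0000001	120	3UTR	8mer
hsa-miR-192-5p|0	ENST0000001	45	CDS	other
hsa-miR-192-5p|+1	ENST0000002	10	5UTR	6mer
hsa-miR-192-5p|+1	ENST0000003	210	3UTR	7mer-m8
hsa-miR-10a-5p|0	ENST0000002	88	CDS	7mer-A1
hsa-miR-10a-5p|0	ENST0000004	301	3UTR	other
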