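mirna_id	transcript_id	site_position	seed_match
hsa-miR-192-5p|0	ENST0000001	121	8mer
hsa-miR-192-5p|+1	ENST0000002	74	6mer
hsa-miR-192-5p|+1	ENST0000003	211	7mer-m8
hsa-miR-10a-5p|0	ENST0000005	33	7mer-A1
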