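mirna	five_prime_shift	edited_position	adj5	adj3
hsa-let-7d-3p	0	4	U	C
hsa-miR-151a-3p	-2	2	U	G
hsa-miR-200b-3p	0	4	U	C
hsa-miR-376c-3p	0	5	U	G
hsa-miR-379-5p	0	4	U	G
hsa-miR-381-3p	-1	3	U	C
hsa-miR-381-3p	0	3	U	C
hsa-miR-411-5p	-1	4	U	G
hsa-miR-411-5p	0	4	U	G
hsa-miR-455-5p	0	16	U	C
hsa-miR-4662a-5p	0	2	U	G
hsa-miR-497-5p	0	1	C	G
hsa-miR-589-3p	0	5	A	C
hsa-miR-9903	0	2	U	U
hsa-miR-99a-5p	-1	0	A	A
hsa-miR-99a-5p	0	0	A	A
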