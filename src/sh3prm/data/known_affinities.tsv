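sh3_id	peptide_id	kd_uM	note
ARHGAP12	P7	0.2	high-affinity wild-type pair
NCK1-3	P9	0.9	high-affinity wild-type pair
NCK1-2	RP2	1.0	high-affinity wild-type pair
ARHGAP12_Set1	P7	23	interface-swap mutant, 115-fold weaker than wild type
NCK1_Set1	P9	14	interface-swap mutant, 15.6-fold weaker than wild type
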