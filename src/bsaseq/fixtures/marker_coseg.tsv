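genotype_id	band_1500_present	transcript_detected
S01	1	1
S02	1	1
S03	1	1
S04	1	1
S05	1	1
S06	1	1
S07	0	0
S08	0	0
S09	0	0
S10	0	0
S11	0	0
S12	0	0
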