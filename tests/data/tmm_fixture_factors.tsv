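sample	lib_size	tmm_factor
S1	2130	1.282016439828
S2	7441	0.962904275845
S3	1483	1.063667316235
S4	3679	0.877261500581
S5	2289	0.908628887643
S6	8112	0.955436581296
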