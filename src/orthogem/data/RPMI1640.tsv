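exchange_id	lb	ub	always_open
EX_glc_e	-1000	1000	0
EX_o2_e	-1000	1000	0
EX_pi_e	-1000	1000	0
EX_nh4_e	-1000	1000	0
EX_aa1_e	-1000	1000	0
EX_aa3_e	-1000	1000	0
EX_h2o_e	-1000	1000	1
EX_h_e	-1000	1000	1
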