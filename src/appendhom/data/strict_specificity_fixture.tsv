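gene_id	horn_bud_2mo	horn_bud_4mo	pedicle	antler_tip	mineralized_cartilage	cartilage_zone	transition_zone	pre_cartilage	reserve_mesenchyme
NCAM2	1	0	0	0	0	0	0	0	1
SCG2	1	0	0	0	0	0	0	0	1
DMP1	1	0	0	0	0	0	0	0	1
RXFP2	1	0	0	0	0	0	0	0	1
SFRP2	1	0	0	0	0	0	0	0	1
GAD2	0	1	1	0	0	0	0	0	0
TMEM211	0	1	1	0	0	0	0	0	0
TMIE	0	1	1	0	0	0	0	0	0
TYR	0	1	1	0	0	0	0	0	0
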