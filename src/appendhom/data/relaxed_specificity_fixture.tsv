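gene_id	horn_bud_2mo	horn_bud_4mo	pedicle	antler_tip	mineralized_cartilage	cartilage_zone	transition_zone	pre_cartilage	reserve_mesenchyme
ASXL3	1	0	1	1	0	1	1	1	1
C1QTNF3	1	0	1	1	1	1	0	0	0
EPHA5	1	0	0	0	0	0	1	1	1
ESR2	1	0	1	1	0	0	0	0	0
GABRA3	1	0	0	0	0	0	0	0	1
IGF2	1	0	1	1	0	0	1	1	1
KAZALD1	1	0	0	0	1	1	0	0	0
LGALS1	1	0	1	0	0	0	1	1	1
NALCN	1	0	1	1	1	1	0	0	0
PDZD2	1	0	0	0	0	0	1	1	0
SERPINF1	1	0	1	1	0	1	1	1	1
BNIP3	0	1	0	0	1	0	1	0	0
DOLPP1	0	1	0	0	0	0	0	0	1
EFCAB1	0	1	0	0	0	1	1	0	0
EXOC3L2	0	1	0	0	0	1	1	1	0
FAM167B	0	1	0	0	1	1	1	1	0
FOSL1	0	1	0	0	0	0	1	1	1
FRAS1	0	1	1	0	0	0	0	0	0
GPI	0	1	0	0	0	0	0	1	1
GPR1	0	1	1	1	0	0	1	0	0
HSD17B2	0	1	0	1	0	0	0	0	0
KCNA2	0	1	0	0	1	0	0	0	0
LDHA	0	1	0	0	0	1	0	0	0
LINGO1	0	1	0	0	0	0	1	0	0
NSDHL	0	1	0	1	0	1	1	1	0
PCSK6	0	1	1	1	0	0	0	0	0
PDLIM1	0	1	0	0	1	1	1	0	0
PKM	0	1	0	0	1	1	1	1	0
SFXN2	0	1	0	0	0	0	1	1	1
SH3BP5	0	1	0	0	0	0	0	1	0
SMPD5	0	1	0	0	1	1	0	0	0
SMPDL3B	0	1	0	0	0	0	0	0	1
WNT9B	0	1	0	0	0	0	1	1	0
YWHAH	0	1	1	1	0	0	1	0	0
CA12	1	1	0	1	0	0	0	1	1
CHEK1	1	1	1	1	1	1	0	1	1
GARNL3	1	1	1	1	1	0	0	0	0
LIPG	1	1	0	0	0	0	0	1	1
ST18	1	1	0	1	0	1	1	0	0
STMN4	1	1	1	1	0	1	1	0	1
TTK	1	1	1	1	1	0	1	1	1
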