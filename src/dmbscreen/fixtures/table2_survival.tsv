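# Per-probeset univariate proportional-hazards results for DMB genes in the
# two DLBCL treatment arms (CHOP and R-CHOP): hazard ratio per one-unit
# expression increase with 95% Wald CI, plus the CHOP-vs-R-CHOP difference p.
# direction is the microarray deregulation direction of the gene (+1 up, -1 down).
gene_symbol	probeset	direction	hr_chop	ci_low_chop	ci_high_chop	hr_rchop	ci_low_rchop	ci_high_rchop	p_arm_diff
CCT3	200910_at	1	1.686	1.057	2.689	1.682	0.999	2.832	0.9944
CLCF1	219500_at	-1	0.846	0.685	1.045	0.736	0.61	0.889	0.3366
COBLL1	203641_s_at	-1	0.86	0.767	0.963	0.976	0.872	1.092	0.1204
COBLL1	229598_at	-1	0.855	0.76	0.961	0.849	0.738	0.976	0.9388
CTPS	202613_at	1	1.451	1.007	2.091	1.476	1.034	2.106	0.9475
FABP5	202345_s_at	1	1.144	0.836	1.566	1.468	1.081	1.995	0.2645
HSPD1	200806_s_at	1	1.267	0.739	2.174	1.886	1.115	3.19	0.3012
HSPD1	200807_s_at	1	1.12	0.88	1.425	1.614	1.059	2.459	0.1401
MRPS17	218982_s_at	1	1.264	0.879	1.818	1.787	1.18	2.707	0.2186
NDC80	204162_at	1	1.153	0.848	1.568	1.54	1.052	2.255	0.2464
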