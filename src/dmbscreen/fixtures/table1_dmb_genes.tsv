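# 60 concordantly deregulated human-DLBCL / mouse-lymphoma (DMB) genes.
# One row per human probeset; the mouse columns are filled on the first row
# of each gene (each gene has exactly one mouse probeset) and empty on
# additional human-probeset rows.
gene_symbol	human_probeset	human_p	human_fold	mouse_probeset	mouse_p	mouse_fold
AURKB	209464_at	1.00E-03	8.94	1451246_s_at	2.80E-03	4.54
BCAT1	226517_at	9.30E-04	33.8	1450871_a_at	2.40E-03	10.24
BCAT1	225285_at	1.70E-03	22.7
BIRC5	202095_s_at	1.30E-04	12.63	1424278_a_at	1.60E-03	3.69
BIRC5	202094_at	6.00E-03	3.34
BOLA3	227291_s_at	9.40E-04	3.17	1433970_at	5.30E-03	2.13
BUB1B	203755_at	1.30E-04	20.2	1447363_s_at	1.10E-03	7.06
CCDC99	221685_s_at	1.40E-03	2.9	1424971_at	6.90E-03	2.44
CCNA2	203418_at	1.10E-05	12.82	1417911_at	1.30E-03	3.62
CCNA2	213226_at	2.10E-05	6.71
CCNB2	202705_at	1.70E-05	22.67	1450920_at	7.40E-03	2.98
CCT3	200910_at	1.30E-03	2.36	1459987_s_at	5.70E-03	2.38
CDK1	203213_at	1.00E-05	42.72	1448314_at	3.00E-04	5.39
CDK1	210559_s_at	7.50E-06	25.98
CDK1	203214_x_at	1.40E-05	19.09
CENPA	204962_s_at	5.40E-04	10.2	1450842_a_at	2.00E-03	2.9
CKS1B	201897_s_at	6.20E-03	2.96	1448441_at	1.00E-03	5.14
CKS2	204170_s_at	1.10E-04	15.51	1417458_s_at	2.30E-03	3.22
CLCF1	219500_at	2.90E-04	-2.14	1450262_at	4.50E-04	-2.08
COBLL1	203641_s_at	8.70E-03	-8.74	1458097_at	1.80E-04	-3.1
COBLL1	229598_at	1.70E-03	-2.17
CTPS	202613_at	9.30E-04	5.71	1416563_at	1.10E-04	3.98
DOCK11	238356_at	1.80E-04	-2.39	1443467_at	6.50E-04	2.34
ESPL1	38158_at	1.00E-03	4.42	1433862_at	6.00E-04	4.79
ESPL1	204817_at	4.60E-03	3.23
FABP5	202345_s_at	3.50E-04	12.47	1416022_at	5.60E-03	20.82
FAM65B	206707_x_at	2.20E-04	-7.34	1460555_at	1.30E-03	-8.93
FKBP1A	200709_at	4.70E-04	2.61	1456196_x_at	1.70E-03	2.56
FKBP1A	214119_s_at	7.90E-04	2.27
FKBP1A	210186_s_at	8.20E-03	2.03
FOSB	202768_at	3.40E-05	-11.83	1422134_at	5.70E-04	-5.19
GMNN	218350_s_at	6.30E-04	10.78	1417506_at	3.00E-04	2.89
HECA	230529_at	8.70E-05	-13.57	1434478_at	3.20E-03	-2.61
HMGA1	206074_s_at	6.70E-03	3.87	1416184_s_at	3.20E-03	3.75
HMGB3	203744_at	2.40E-03	5.25	1416155_at	6.90E-03	3.52
HSPD1	200807_s_at	3.50E-04	2.69	1426351_at	2.20E-03	2.58
HSPD1	200806_s_at	5.10E-03	2.41
JMJD1C	228793_at	1.70E-03	-2.88	1448049_at	3.80E-04	-3.14
JMJD1C	221763_at	2.80E-03	-2.3
KIF18B	222039_at	1.30E-04	12.7	1453226_at	1.10E-03	3.13
KIF20A	218755_at	3.80E-04	6.51	1449207_a_at	4.70E-03	4.68
LDHA	200650_s_at	5.10E-04	3.65	1419737_a_at	1.90E-03	2.74
LGALS3	208949_s_at	2.00E-03	-29.33	1426808_at	8.60E-03	-3.48
MAP3K1	214786_at	1.00E-04	-11.89	1443540_at	2.90E-03	-4.19
MAP3K1	225927_at	4.80E-03	-5.03
MARCH1	1562338_at	1.30E-05	-2.33	1440209_at	4.40E-04	-11.5
MRPS17	218982_s_at	1.70E-03	3.42	1453728_a_at	4.10E-03	2.16
NDC80	204162_at	5.10E-05	10.97	1417445_at	8.60E-03	2.5
NDUFB6	203613_s_at	9.90E-03	2.09	1434057_at	2.10E-03	2.36
NEK2	204641_at	1.40E-04	11.97	1437580_s_at	4.40E-03	3.01
ORC6L	219105_x_at	4.50E-03	3.5	1417037_at	1.40E-03	2.49
PBK	219148_at	1.40E-03	19.23	1448627_s_at	1.30E-03	6.99
PBXIP1	207838_x_at	6.80E-03	-2.02	1451132_at	1.70E-03	-3.15
PDE7A	224046_s_at	8.20E-03	-2.54	1458218_s_at	6.40E-03	-3.91
PFDN6	222029_x_at	1.70E-03	2.7	1415744_at	5.00E-03	2.16
PFDN6	233588_x_at	9.30E-03	2.28
PHC3	215521_at	6.60E-03	-2.56	1455312_at	6.50E-03	-3.08
PHC3	226508_at	2.30E-03	-2.23
RABEP2	74694_s_at	5.70E-03	-2.89	1440795_x_at	4.10E-03	-4.74
RABEP2	219057_at	1.70E-03	-2.09
RACGAP1	222077_s_at	1.50E-05	12.79	1451358_a_at	2.10E-03	5.11
RIN3	60471_at	1.00E-03	-4.6	1434684_at	7.60E-03	-4.58
RIN3	219456_s_at	8.30E-04	-2.06
RIN3	219457_s_at	1.30E-03	-3.46
SAP30	204900_x_at	7.90E-03	4.65	1417719_at	4.10E-03	3.92
SFXN1	230069_at	7.90E-04	3.75	1417560_at	4.50E-03	2.04
SFXN1	218392_x_at	1.40E-03	2.11
SPAG5	203145_at	2.30E-04	6.81	1433893_s_at	6.00E-03	4.73
TMEM55B	225287_s_at	8.30E-03	-2.03	1454797_at	9.10E-03	-2.94
TOP2A	201292_at	1.70E-06	29.72	1454694_a_at	2.40E-03	2.33
TOP2A	201291_s_at	1.10E-04	11.93
TTK	204822_at	8.80E-04	8.18	1449171_at	1.60E-05	6.61
VAMP2	201557_at	4.80E-05	-2.99	1420834_at	4.30E-03	-2.01
VAMP2	201556_s_at	1.40E-03	-2.14
VDAC1	212038_s_at	5.10E-04	3.12	1437947_x_at	4.90E-05	2.61
VDAC1	217140_s_at	6.50E-03	2.58
WDFY2	1560112_at	1.70E-05	-5.49	1434517_at	1.30E-04	-3.8
WDFY2	227490_at	2.90E-03	-2.09
YPEL3	232077_s_at	1.70E-03	-4.15	1426624_a_at	4.90E-04	-4.13
YPEL3	223179_at	3.70E-03	-2.98
ZMYM5	215948_x_at	2.70E-04	-2.75	1445543_at	6.80E-05	-4.04
ZMYM5	206652_at	7.30E-04	-2.29
ZMYM6	227594_at	2.30E-03	-2.74	1438685_at	7.00E-05	-3.11
ZMYM6	219925_at	1.10E-03	-2.24
ZWILCH	218349_s_at	5.40E-03	3.79	1416757_at	9.00E-04	3.34
ZWILCH	222606_at	7.60E-04	3.51
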