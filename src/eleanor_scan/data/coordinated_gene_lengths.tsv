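gene	group	length_bp
SDK1	coordinated	967552
LRBA	coordinated	750839
RERE	coordinated	465236
ESR1	coordinated	412778
USP34	coordinated	283260
SYNPO2	coordinated	210560
KDMA2A	coordinated	138811
KYNU	coordinated	111912
AVL9	coordinated	88604
CCDC50	coordinated	68586
SYTL2	coordinated	63780
AHNAK	coordinated	41104
ATIC	coordinated	37818
ERBB2	non_coordinated	40523
BRD8	non_coordinated	38900
SLC12A5	non_coordinated	38461
CLN3	non_coordinated	25430
SIDT2	non_coordinated	18223
DBNDD1	non_coordinated	14659
CASP14	non_coordinated	8813
ESRP2	non_coordinated	7687
TUBG2	non_coordinated	7759
CYP1A1	non_coordinated	5995
VPS28	non_coordinated	4963
APH1A	non_coordinated	3811
MFSD10	non_coordinated	3677
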