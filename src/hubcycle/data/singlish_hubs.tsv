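hub	n_interfaces	domains	functional_group	reported_class
BOI2	2	SH3_1,SAM_2,PH	Bud Formation	Static
CDC42	2	Ras	Bud Formation	Static
CLA4	2	PH,PDB(CRIB),Pkinase	Bud Formation	Dynamic
CDC28	2	Pkinase	Cyclin Proteins	Static
CLB1	2	Cyclin_N,Cyclin_C	Cyclin Proteins	Dynamic
CLB2	2	Cyclin_N,Cyclin_C	Cyclin Proteins	Dynamic
CLB3	2	Cyclin_N,Cyclin_C	Cyclin Proteins	Dynamic
CLB4	2	Cyclin_N,Cyclin_C	Cyclin Proteins	Dynamic
CLB5	2	Cyclin_N,Cyclin_C	Cyclin Proteins	Dynamic
CLB6	2	Cyclin_N,Cyclin_C	Cyclin Proteins	Dynamic
CLN1	2	Cyclin_N	Cyclin Proteins	Dynamic
CLN2	2	Cyclin_N	Cyclin Proteins	Dynamic
CLN3	2	Cyclin_N	Cyclin Proteins	Dynamic
PHO85	2	Pkinase	Cyclin Proteins	Static
YTA7	1	AAA,bromodomain	Cyclin Proteins	Static
ACT1	2	Actin	Structural	Static
MLC1	2		Structural	Static
GDI1	1	GDI	Protein Sorting/Transport	Static
MRS6	2	GDI	Protein Sorting/Transport	Static
VPS21	2	Ras	Protein Sorting/Transport	Static
YKT6	2	Longin,Synaptobrevin	Protein Sorting/Transport	-
YPT52	2	Ras	Protein Sorting/Transport	Static
GSP1	2	Ras	Others	-
HSC82	2	HATPase_c,HSP90	Others	-
HSP82	2	HATPase_c,HSP90	Others	-
MTR3	1	RNase_PH	Others	-
RAS2	2	Ras	Others	-
SGN1	1	RRM_1	Others	-
SLT2	2	Pkinase	Others	-
SNF1	2	Pkinase,UBA_2	Others	-
DBP8	1	DEAD,Helicase_c	Ribosomal RNA Processing	-
DBP9	1	DEAD,Helicase_c	Ribosomal RNA Processing	-
DRS1	2	DEAD,Helicase_c	Ribosomal RNA Processing	-
HAS1	1	DEAD,Helicase_c,DUF4217	Ribosomal RNA Processing	-
HCA4	1	DEAD,Helicase_c,DUF4217	Ribosomal RNA Processing	-
SPB4	1	DEAD,Helicase_c,DUF4217	Ribosomal RNA Processing	-
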