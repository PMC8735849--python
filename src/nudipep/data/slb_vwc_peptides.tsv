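# Published single-neuron MALDI-TOF peptide identifications for the three
# nudipleuran species (SLB cells / ventral white cell).  mean_mh is the
# observed mean [M+H]+; printed_mh is the theoretical [M+H]+ as printed in
# the original report (kept verbatim, including its known inconsistencies).
# P. californica rows without masses are peptides previously characterized
# in that neuron; they carry no observed mean.
species	family	name	sequence	modifications	mean_mh	printed_mh
H. crassicornis	FCAP	FCAP_3	GLDSLGGFNVHGGW		1415.684	1415.668
H. crassicornis	FCAP	FCAP_1	GLDSLGGFQVHGGW		1429.71	1429.684
H. crassicornis	FCAP	FCAP_2	GLDSLGGFHVHGGGW		1495.7	1495.706
H. crassicornis	FMRFa	FMRFa	FMRF	amidation	599.279	599.312
H. crassicornis	LFRFa	TLFRFa	TLFRF	amidation	682.393	682.403
H. crassicornis	LFRFa	GSIFRFa	GSIFRF	amidation	725.404	725.409
H. crassicornis	LFRFa	ASLFRFa	ASLFRF	amidation	739.423	739.425
H. crassicornis	LFRFa	GGSLFRFa	GGSLFRF	amidation	782.464	782.431
H. crassicornis	LFRFa	ARGSLFRFa	ARGSLFRF	amidation	952.594	952.547
H. crassicornis	SCP	SCP_A	SGYLAFPRM	amidation	1041.588	1041.535
H. crassicornis	SCP	SCP_B	VNYLAFPRM	amidation	1109.638	1109.592
M. leonina	FMRFa	FVRFa	FVRF	amidation	567.313	567.34
M. leonina	FMRFa	FLRFa	FLRF	amidation	581.338	581.356
M. leonina	FMRFa	YLRFa	YLRF	amidation	597.335	597.35
M. leonina	FMRFa	FMRFa	FMRF	amidation	599.303	599.312
M. leonina	FMRFa	FMRFa peptides-2	RSVDDDDMSTRSGDVID		1882.809	1882.806
M. leonina	FMRFa	FMRFa peptides-1	SQQPNVDDIYNKALLQLEEPYS		2564.237	2564.249
M. leonina	LFRFa	SSLFRFa	SSLFRF	amidation	755.442	755.42
M. leonina	LFRFa	GGTLFRFa	GGTLFRF	amidation	796.477	796.446
M. leonina	LFRFa	SSLFRFa (acetylated)	SSLFRF	acetylation;amidation	797.432	797.43
M. leonina	LFRFa	LFRF peptides-2	SGPQSNEGM	acetylation	948.51	948.371
M. leonina	MIP-related	GPPRFVa	GPPRFV	amidation	671.414	671.398
M. leonina	MIP-related	QAPRFVa (pyroglutamated)	QAPRFV	amidation;pyroglutamation-from-Gln	699.411	699.393
M. leonina	MIP-related	QAPRFVa	QAPRFV	amidation	716.442	716.42
M. leonina	MIP-related	YVPRFVa	YVPRFV	amidation	779.493	779.456
M. leonina	MIP-related	YIPRFVa	YIPRFV	amidation	793.511	793.472
M. leonina	MIP-related	AIQPRFVa	AIQPRFV	amidation	829.546	829.504
M. leonina	MIP-related	YDPPRFVa	YDPPRFV	amidation	892.514	892.4673
M. leonina	MIP-related	ARSPPRFVa	ARSPPRFV	amidation	928.594	928.54726
M. leonina	MIP-related	MIP-related peptides 1	GPSLQASEE	acetylation	959.519	959.43
M. leonina	MIP-related	YGRPIIPGQIa	YGRPIIPGQI	amidation	1112.707	1112.6572
M. leonina	MIP-related	MIP-related peptides 2	DYDTIFDLLHNSA		1523.721	1523.699
M. leonina	SCP	SCP peptides-1	SEFSVSED	acetylation;amidation	940.5413	940.389
M. leonina	SCP	SCP_C	SGYAGFPRMS		1072.541	1072.486
M. leonina	SCP	SCP_A	SNYLAFPRM	amidation	1097.605	1097.556
M. leonina	SCP	SCP_B	MNYLAFPRM	amidation	1141.616	1141.564
P. californica	SCP	SCP_A	SGYLAFPRM	amidation	1041.6403	1041.535
P. californica	SCP	SCP_B	MNYLAFPRM	amidation	1141.7383	1141.564
P. californica	FMRFa	AEEPLY	ASAGGQRSEESLLREALMQAEEPLY
P. californica	FMRFa	AEEPLY'	SEESLLREALMQAEEPLY
P. californica	FMRFa	FLRFa	FLRF	amidation
P. californica	FMRFa	FMRFa	FMRF	amidation
P. californica	FMRFa	FMRFa peptide 3	DVGGGSAAGDAEEEDIISRQILGLGGGQVGESGDVIDGF
P. californica	FMRFa	FMRFa peptide 5	PSNAALEGLEGE
P. californica	QNFLa	QNFLa-peptide 5	QLDSIGAGMVSGLHQNFL	amidation;pyroglutamation-from-Gln
P. californica	QNFLa	QNFLa-peptide 6	FDSISSGRLNGFNANFL	amidation
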