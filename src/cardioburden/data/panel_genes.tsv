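symbol	category	disease_codes
AKAP9	channelopathy	1
ANK2	channelopathy	1,2,3
CACNA1C	channelopathy	2
CACNA2D1	channelopathy	2,4
CACNB2	channelopathy	2
CASQ2	channelopathy	3
GPD1L	channelopathy	2,5,6
HCN4	channelopathy	2,7
KCNE1	channelopathy	1,8
KCNE2	channelopathy	1,10
KCNE3	channelopathy	2
KCNH2	channelopathy	1,4
KCNJ2	channelopathy	1,8,4
KCNJ5	channelopathy	1
KCNJ8	channelopathy	2,6
KCNQ1	channelopathy	1,4,8
RYR2	channelopathy	3,1,9
SCN1B	channelopathy	2,8
SCN3B	channelopathy	2,8
SCN4B	channelopathy	2,8
SCN5A	channelopathy	1,2,6,7,8,10,11,12
SNTA1	channelopathy	1,6,13
TRPM4	channelopathy	2,10
ABCC9	cardiomyopathy	12
ACTC1	cardiomyopathy	12,13,14,15
ACTN2	cardiomyopathy	12,14
ANKRD1	cardiomyopathy	12
BAG3	cardiomyopathy	12
BRAF	cardiomyopathy	14,15
CALR3	cardiomyopathy	14
CAV3	cardiomyopathy	1,6,14
CSRP3	cardiomyopathy	12,13,14
DES	cardiomyopathy	12
DMD	cardiomyopathy	12
DNAJC19	cardiomyopathy	12
DSC2	cardiomyopathy	9
DSG2	cardiomyopathy	9,12
DSP	cardiomyopathy	9,12
DTNA	cardiomyopathy	13,15
FHL2	cardiomyopathy	12
GLA	cardiomyopathy	14
JPH2	cardiomyopathy	14
JUP	cardiomyopathy	9
LAMP2	cardiomyopathy	14
LDB3	cardiomyopathy	9,12,13
LMNA	cardiomyopathy	9,12
MIB1	cardiomyopathy	12
MYBPC3	cardiomyopathy	12,13,14
MYH7	cardiomyopathy	12,13,14
MYL2	cardiomyopathy	14
MYL3	cardiomyopathy	14
MYLK2	cardiomyopathy	14
MYOZ2	cardiomyopathy	12,14
NEBL	cardiomyopathy	12
NEXN	cardiomyopathy	12,14
PLN	cardiomyopathy	9,12,14
PRKAG2	cardiomyopathy	14
PKP2	cardiomyopathy	9,2
RBM20	cardiomyopathy	12
TAZ	cardiomyopathy	12,13
TCAP	cardiomyopathy	12,14
TGFB3	cardiomyopathy	9
TMEM43	cardiomyopathy	9
TMPO	cardiomyopathy	12
TNNC1	cardiomyopathy	12,14
TNNI3	cardiomyopathy	12,14
TNNT2	cardiomyopathy	12,13,14
TPM1	cardiomyopathy	12,13,14
TTN	cardiomyopathy	12,14
VCL	cardiomyopathy	12,14
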