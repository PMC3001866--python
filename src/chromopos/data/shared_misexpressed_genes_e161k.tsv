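gene_symbol	chromosome	heart_fold_change	fibroblast_fold_change
ATP1B1	1	-7.4	2.4
BRP44	1	2.6	2.8
LEPROT	1	-10.8	-2
PPAP2B	1	-8.9	3.3
PRELP	1	4.4	-4.3
TXNIP	1	-4.5	-2.3
ZNF281	1	-2.4	-1.54
CYP1B1	2	23.9	1.9
ID2	2	-2	2
PCOLCE2	3	2.6	11.1
ZBTB38	3	-6.5	-1.7
C5orf23	5	3.3	2.4
DUSP1	5	2.5	1.8
EDIL3	5	4	-38.3
PDCD6	5	3.4	-28.7
RHOBTB3	5	-8.5	-1.9
COL12A1	6	8.3	-3.5
RUNX1T1	8	-2.1	-1.9
KLF4	9	7.7	2.1
UGCG	9	-3.8	-1.9
C11orf54	11	-2.2	-1.9
LOC387758/FIBIN	11	10.1	-10.8
C1S	12	2.4	-1.8
DCN	12	9.7	-2.4/+2.5
MFAP5	12	6.1	4.1
NTN4	12	2.6	-2
SLC38A1	12	-6.6	-2.3
KPNA3	13	-6.6	2.5
LMO7	13	4.8	2.8
POSTN	13	37.9	-4.6
CHURC1	14	3.9	3.4
EIF2S1	14	4	11.7
IGF1R	15	-12.5	-2.7
FLJ37644	17	4.5	19
ID1	20	2.6	13.3
BEX1	X	4.8	-2.4
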