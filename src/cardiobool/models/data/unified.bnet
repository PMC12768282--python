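# Unified heart-field + cardiomyocyte-subtype network (21 nodes).
# GATA4/6 is shared between the two halves; NKX2-5 feeds IRX4 and GATA4/6
# gates NR2F2, coupling heart-field output to subtype commitment.
# FGF8 and its exogenous driver are carried from the adapted heart-field
# network; they have no outgoing edges and do not alter any attractor.
targets, factors
ex_WNT, ex_WNT
ex_BMP2, ex_BMP2
ex_FGF8, ex_FGF8
WNT, ex_WNT
BMP2, ex_BMP2 & !WNT
FGF8, ex_FGF8
FOXC1_2, WNT
MESP1, WNT & !FOXC1_2
ISL1, FOXC1_2
GATA4_6, GATA4_6 | MESP1 | ISL1
NKX2_5, GATA4_6
TBX1, FOXC1_2
TBX5, NKX2_5 & !ISL1
NOTCH, NOTCH
RA, RA
NR2F2, RA & GATA4_6
HEY2, NOTCH & GATA4_6 & !NR2F2
MYL7, NR2F2 & !HEY2
HAND2, IRX4 | GATA4_6
IRX4, HAND2 & NKX2_5 & !NR2F2
MYL2, IRX4 & !NR2F2
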