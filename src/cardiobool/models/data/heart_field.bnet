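# Heart-field specification gene regulatory network (11 nodes).
# ex_BMP2 is clamped to 1 in all standard analyses; ex_WNT selects the field.
targets, factors
ex_WNT, ex_WNT
ex_BMP2, ex_BMP2
WNT, ex_WNT
BMP2, ex_BMP2 & !WNT
FOXC1_2, WNT
MESP1, WNT & !FOXC1_2
ISL1, FOXC1_2
GATA4_6, GATA4_6 | MESP1 | ISL1
NKX2_5, GATA4_6
TBX1, FOXC1_2
TBX5, NKX2_5 & !ISL1
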