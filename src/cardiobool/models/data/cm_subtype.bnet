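# Cardiomyocyte-subtype gene regulatory network (9 nodes).
# Inputs NOTCH, RA and GATA4/6 are self-sustaining and clamped per condition.
targets, factors
NOTCH, NOTCH
RA, RA
GATA4_6, GATA4_6
NR2F2, RA
HEY2, NOTCH & GATA4_6 & !NR2F2
MYL7, NR2F2 & !HEY2
HAND2, IRX4 | GATA4_6
IRX4, HAND2 & !NR2F2
MYL2, IRX4 & !NR2F2
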