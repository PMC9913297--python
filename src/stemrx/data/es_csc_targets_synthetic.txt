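# Synthetic stand-in for the 21-gene stemness/chemoresistance target panel.
# Symbols recoverable from the published panel appear by name; entries with
# the TGTX prefix are placeholders for members that could not be recovered
# and exist only so the panel has its documented size.
POU5F1
KIT
CAV1
ITGB1
CD44
ABCB1
ABCC1
ABCG1
LIN28A
LEFTY2
DNMT3B
GABRB3
MTOR
TGTX14
TGTX15
TGTX16
TGTX17
TGTX18
TGTX19
TGTX20
TGTX21
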