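# {"name": "esc", "mode": "mean_z"}
ZIC1
TCF7L1
KLF5
MYBL2
NFE2L3
TEAD4
ILF3
HMGA1
HMGB3
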