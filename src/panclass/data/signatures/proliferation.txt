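# {"name": "proliferation", "mode": "mean_z", "placeholder": true}
# 110-gene in-vitro proliferation signature; the published list is not
# redistributed here. Replace this file with one gene id per line.
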