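# {"name": "ca20", "mode": "ca20", "placeholder": true}
# 20-gene centrosome-amplification signature; the published list is not
# redistributed here. Replace this file with one gene id per line.
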