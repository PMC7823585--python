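# {"name": "rb", "mode": "mean_z", "placeholder": true}
# 182-gene retinoblastoma-pathway signature; the published list is not
# redistributed here. Replace this file with one gene id per line.
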