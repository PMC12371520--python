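# Scaled-down system preserving the TF:TU ratio of the full model:
# 200-bead fibre, 8 TUs, 8 active + 8 repressive TFs (4 of each ON).
feedback = "positive"
seed = 0

[fibre]
n_beads = 200
n_tu = 8
tu_seed = 2025
box_length = 35.0

[tfs]
n_active = 8
n_repressive = 8
n_on_each = 4
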