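# Full-scale system: 1000-bead fibre, 39 TUs, 40 active + 40 repressive TFs
# (20 of each species initially ON), dilute periodic box.
feedback = "positive"
seed = 0

[fibre]
n_beads = 1000
n_tu = 39
tu_seed = 2025
box_length = 60.0

[tfs]
n_active = 40
n_repressive = 40
n_on_each = 20
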