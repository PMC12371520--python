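# Minimal end-to-end system for smoke tests: 20-bead fibre, 2 TUs, 2+2 TFs.
feedback = "positive"
seed = 0

[fibre]
n_beads = 20
n_tu = 2
tu_ids = [5, 15]
box_length = 14.0

[tfs]
n_active = 2
n_repressive = 2
n_on_each = 1

[kinetics]
p_s = 0.01
tau_r = 2000

[integrator]
steps = 20000

[sampling]
stride = 100
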