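# Methods

## Model

Chromatin is a coarse-grained bead-spring polymer: `n` beads of diameter
σ (the length unit; one bead is roughly 1–3 kbp, σ ≈ 20–30 nm), connected
by FENE springs and given excluded volume by a WCA potential
(Kremer–Grest), with a Kratky–Porod bending term `k_b (1 − cos θ)` on
consecutive bond triplets.  A subset of beads are transcription units
(TUs); a TU is permanently a TU but toggles between an *active* and a
*repressed* chromatin state.  Transcription factors (TFs) are free spheres
of the same diameter, of two species — active and repressive — each
stochastically switching between an interacting ON state and a purely
steric OFF state (modelling complex assembly/disassembly).

Attractive TF–chromatin contacts are truncated-and-shifted Lennard-Jones
wells, cut at `attraction_cutoff` and classed *weak* or *strong*; every
other pair (bead–bead, TF–TF, any pair involving an OFF TF) is WCA.
Active ON TFs bind active TUs strongly and everything else weakly, in all
model variants.  The three silencing feedbacks differ only in the
repressive-ON row of the affinity table:

| repressive ON TF vs. | unmarked | active TU | repressed TU |
|----------------------|----------|-----------|--------------|
| positive ("colour and stick")  | weak   | strong | strong |
| negative ("colour and flee")   | steric | strong | steric |
| neutral  ("colour and linger") | weak   | weak   | weak   |

Regulation: every `silencing_interval` steps, each active TU with at least
one repressive ON TF within `r_bind` is silenced with probability `p_s`
(at most one change per TU per attempt; a `compound_occupancy` flag makes
the probability compound over the number of bound repressors instead).  A
repressed TU reverts deterministically after `tau_r` steps.  Every
`switch_interval` steps each TF flips ON↔OFF with probability `p_switch`,
i.e. symmetric rates α_on = α_off = p_switch / switch_interval.

## Dynamics

Particles follow underdamped Langevin dynamics with unit mass, integrated
with the BAOAB splitting (half kick, half drift, Ornstein–Uhlenbeck
velocity refresh, half drift, recompute forces, half kick).  Units:
energies in k_BT, lengths in σ, time in τ = σ²γ/k_BT with γ = 1 and
k_BT = 1, so the long-time diffusion constant of a free particle is
D = k_BT/γ = 1.  BAOAB was chosen over first-order overdamped
Euler–Maruyama because the stiff FENE + WCA core makes the overdamped
scheme unstable at any step size large enough to reach the time scales on
which TFs find and exchange between TUs; BAOAB is stable at dt = 0.01 τ
(the default) with small configurational sampling bias, and is the
standard choice for this polymer family.  The integrator aborts with a
diagnostic on FENE over-extension or non-finite coordinates.

Neighbour search uses a Verlet pair list built from linked cells
(all-pairs fallback for boxes under three cells per side), rebuilt when any
particle has moved more than half the skin (default 0.8 σ); positions are
wrapped into the primary periodic box at rebuild time and the integer
image offset of every listed pair and chain bond is cached, so force loops
use plain coordinate differences.  Cell-list and all-pairs paths must (and
are tested to) agree.

Initial conditions: the chain is grown as a self-avoiding random walk with
bonds at the combined bond + WCA minimum (≈ 0.965 σ); TFs are inserted
uniformly without overlap; a short capped steepest descent removes
residual overlaps before dynamics.  Velocities start at zero and
thermalise within ~1/γ.

## Default parameters

| parameter | default | notes |
|-----------|---------|-------|
| FENE `bond_k`, `fene_r0` | 30 k_BT/σ², 1.6 σ | Kremer–Grest standard |
| bending `k_b` | 3 k_BT | persistence ≈ 3 beads |
| `eps_weak`, `eps_strong` | 3, 8 k_BT | this model family's usual range |
| `attraction_cutoff`, `r_bind` | 1.8 σ | binding = energetic range |
| `dt`, γ, k_BT | 0.01 τ, 1, 1 | BAOAB |
| `switch_interval`, `p_switch` | 100 steps, 0.002 | ON dwell 5·10⁴ steps = 500 τ |
| `silencing_interval` | 100 steps | shared cadence with switching |
| `tau_r` | 5·10⁴ steps (500 τ) | 500 switch intervals |
| run length / stride / equilibration | 2·10⁵ steps / 100 / first 10% | reduced system |

Two shipped presets define the study conditions: `paper1000` (1000 beads,
39 randomly placed TUs, 40 + 40 TFs with 20 of each species initially ON,
periodic box 60 σ) and `reduced200` (200 beads, 8 TUs, 8 + 8 TFs with 4
ON each, box 35 σ), which preserves the full system's TF:TU ratio of ≈ 1
and its TU concentration (≈ 1.8·10⁻⁴ σ⁻³) so that competition for TFs and
the diffusive search time carry over.

### Calibration of the kinetic constants

The absolute values of `p_switch`, `tau_r` and the well depths are not
fixed by the model definition; they were calibrated once, against the
physical requirements below, and then frozen:

* **Transition decade.**  A renewal argument fixes where silencing takes
  over: with occupancy `occ` (probability that an active TU has a
  repressive ON TF within `r_bind` at an attempt), the repressed fraction
  is `tau_r / (tau_r + Δ/(p_s·occ))`, so the activity curve falls around
  `p_s* ~ Δ/(tau_r·occ)` (the midpoint crossing sits somewhat below p_s*
  for feedbacks with a high post-transition plateau).  Measured
  occupancies on the reduced system (≈ 0.53 / 0.27 / 0.12 for positive /
  negative / neutral) put the midpoint crossings of all three feedbacks
  inside the decade [10⁻³, 10⁻²] for `tau_r` = 5·10⁴ steps.
* **Binding vs. search.**  A TF needs ~200 τ of diffusive search to find
  a TU at this dilution; `p_switch` = 0.002 gives an ON dwell of 500 τ so
  that switching models complex turnover rather than truncating every
  binding event.  Faster switching was examined and rejected: it starves
  the occupancy of weakly bound repressors (pushing the neutral-feedback
  transition out of the decade) without reducing the *relative*
  replica-to-replica activity heterogeneity, which stays at
  σ_a,TU/〈a_TU〉 ≈ 0.6–0.8 across the accessible range.

## Observables

* **Activity** `a_TU`: fraction of post-equilibration frames in which the
  TU is in the active state *and* has ≥ 1 active ON TF within `r_bind`.
  Averaging is two-stage, first over replicas per TU (〈a_TU〉), then over
  TUs (〈a〉), and the ensemble mean equals the unweighted mean of the
  per-TU means exactly.
* **Kymograph**: per TU and frame, OFF (repressed), ON-idle (active, no
  active ON TF in range) or ON-transcribing; the ON-transcribing row
  fraction reproduces `a_TU` identically.
* **Clusters**: single-linkage connected components of the TF proximity
  graph at `r_clust` = 2 σ (just beyond the first coordination shell).
  The reported "active cluster size" is the per-frame mean size of
  active-TF components with ≥ 2 members (ON-only by default), 0 when no
  such component exists, then time-averaged.  Compositions and radial
  profiles (member distance from the cluster centroid) support core/shell
  analyses.
* **Noise** σ_a,TU: sample standard deviation of a TU's time-averaged
  activity across replicas (a cell-to-cell variability proxy); a
  `noise_metric` flag switches to variance.
* **Correlation networks**: Pearson correlations of per-replica
  time-averaged activities across replicas, one edge per TU pair with
  |r| > 0.25 carrying the sign.  Zero-variance TUs yield no edges and a
  warning.  A time-windowed within-replica mode is intentionally not the
  default: correlating replica averages matches how the ensembles are
  generated and read.

## Ensembles and the transition locator

Replica seeds derive from a base seed through `SeedSequence`, so ensembles
are reproducible, order-independent and identical under serial or
parallel execution.  One RNG stream drives each replica with a fixed draw
order (thermal noise block; switching, one uniform per TF; silencing, one
uniform per eligible TU in ascending bead order), version-stamped in the
run manifest.

`scan_ps` shares the replica seed list across grid points (common random
numbers): replica k experiences the same thermal and regulatory noise
stream at every p_s, so the shape of the activity curve — and any paired
contrast between two grid points — is estimated with substantially less
variance than with independent ensembles, while replicas within one
ensemble stay mutually independent.

`locate_transition` takes the mean activities over the lowest and highest
scanned decades as plateaus and log-interpolates the first crossing of
their midpoint; a flat or non-decreasing curve returns a no-transition
result rather than raising.  The estimate is invariant under affine
rescaling of the activity axis.  A bootstrap over replicas provides a
confidence interval.

## What the scaled-down runs do and do not show

The acceptance-scale computations use the `reduced200` preset with
150k-step runs and 8–10 replicas per grid point, sized so a full
three-feedback scan completes in tens of minutes on one CPU.  They
preserve the TF:TU ratio, the dilution and all kinetic time scales of the
full system.  What they resolve, and what they do not:

* **Transition.**  All three feedbacks show a clear silencing transition.
  Its midpoint crossing lands inside [10⁻³, 10⁻²] for the positive and
  neutral feedbacks (≈ 4·10⁻³ and 3·10⁻³ under the default seed); the
  negative feedback's crossing sits at the decade's lower edge (≈ 9·10⁻⁴)
  because its activity curve is shallow — its post-transition plateau
  stays high, so the plateau midpoint is crossed early on the shoulder.
* **Cluster-size trends.**  With at most 8 active TFs the mean
  size of active-TF clusters carries replica-to-replica scatter of the
  same order as the high-vs-low-p_s contrast; the 10-replica bootstrap
  CIs on the contrast include zero for both the positive-feedback
  decrease and the negative-feedback increase.  Exploratory full-scale
  runs indicate that cluster coarsening needs windows well beyond 10³ τ,
  so this observable is reported but not statistically resolved at this
  scale.
* **Noise.**  Per-TU activities on the reduced system are dominated by
  quasi-static spatial heterogeneity (whether a TU sits inside a TF
  cluster is a long-lived random variable), giving σ_a,TU/〈a_TU〉 ≈ 0.6–0.8
  at low p_s.  A variance decomposition — activity ≈ a₀·(1−f) with a₀ the
  heterogeneous baseline and f the per-replica repressed fraction — shows
  the silencing-induced bump `a₀²·var(f)` then at best matches the
  baseline term it suppresses, so the measured σ(p_s) curve decreases
  monotonically instead of peaking at the transition.  Resolving an
  interior noise maximum requires either many more TFs per TU (full
  scale) or windows long enough to average the baseline heterogeneity
  away.

None of this bears on real chromatin beyond what the model family itself
can claim: there is no sequence, no polymerase kinetics, and no
physical-time calibration.

## Numerical choices and degenerate inputs

* Pair energies are exactly zero at and beyond their cutoffs (the shift is
  computed analytically, not sampled).
* `bound_tfs` uses a closed boundary (distance ≤ `r_bind` is bound).
* Recovery deadlines are integer step counts compared with ≤, so a TU
  whose deadline equals the current step reactivates (and may be
  re-silenced in the same attempt round: recovery runs first, then
  switching, then silencing).
* Silenced TUs do not displace bound TFs; only the affinity table entry
  they see changes from the next force evaluation.
* A single-replica ensemble reports NaN standard errors rather than
  raising; correlation networks need ≥ 3 replicas.
* `langevin_step` on a particle at a potential minimum with k_BT = 0 is
  a fixed point (no noise, no net force).

## Known limitations

* No hydrodynamics, no explicit polymerase elongation, no
  nucleosome-scale structure, no epigenetic spreading between neighbour
  beads, and exactly two TF species.
* The BAOAB configurational bias at dt = 0.01 τ is small but nonzero for
  the stiff FENE core; the harmonic-dimer Boltzmann test bounds it only
  for soft potentials.
* `ps_critical` from a midpoint crossing on a 7-point grid carries
  half-grid (~quarter-decade) resolution plus replica noise; the
  bootstrap CI is the honest uncertainty statement.
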