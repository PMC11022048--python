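# Methods

This note records the model as implemented, the parameter choices that
matter, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want to know.

## Cell geometry

The cell is a cube of `n = 2·ceil(r_cm/voxel) + 1` voxels per side (odd, so
a central voxel exists). Voxel `(i, j, k)`'s physical position is its
center, with the origin at the central voxel's center — the center voxel is
at distance exactly 0. Region assignment:

* **CO** (central organelle, nucleus + surrounding ER/mitochondria as one
  decision-making compartment): every voxel with center distance ≤ r_co.
* **PC / CM shells**: a voxel belongs to the r-shell iff
  `round(‖c‖/voxel) = round(r/voxel)`. This gives one-voxel-thick shells
  that are *closed*: the ordered voxel path of any outward ray changes one
  axis at a time, and its integer norm therefore passes through every
  rounded radius (the test suite checks this with an exact voxel
  traversal; naive fixed-step ray sampling can skip the crossing window).
* **CYTO**: everything strictly between the CO ball and the PC shell. The
  thin gap between the PC and CM shells is deliberately unlabeled (EMPTY):
  cytoskeleton is sandwiched between PC and CO, and fill fractions are
  quoted relative to that sandwiched cytoplasm only.

Cytoskeleton generation relabels exactly `round(f·|CYTO ∪ CS|)` cytoplasm
voxels as CS, drawn without replacement from one seeded permutation.
Exact-count sampling (rather than Bernoulli fill) keeps the fill fraction
exact per trial and reduces trial-to-trial variance in the percolation
sweep; the prefix-of-a-permutation construction makes CS sets nested in
the fraction for a fixed seed. The fill is unstructured (no filament
persistence) — matching the percolation study's "uniform random" design —
so filament-shaped generators are out of scope.

## Reservoir tensor

Vertices sit at even index triples of a `(2n−1)³` tensor; the edge between
voxels `x` and `x+d` stores its conductance at cell `2x+d`. All cells with
at least one odd coordinate are edge storage: `(2n−1)³ − n³ =
7n³ − 12n² + 6n − 1` cells for a full grid (19 for n = 2 — the test suite
pins this against brute-force enumeration). Two crossing face diagonals
share a face-midpoint cell and the four body diagonals of a cell cube
share its center, so crossing edges share one conductance value; this is a
property of the storage scheme, kept deliberately because the ≈7n³ edge
count presumes it.

Conductances are log-normal with *distribution* mean 0.1 and sd 0.5
(unitless); the underlying normal parameters come from moment matching
(σ² = ln(1 + (sd/mean)²), μ = ln mean − σ²/2). Conduction is restricted to
{PC, CS, CO} by default — signals enter at the peripheral cytoplasm,
travel via cytoskeleton, terminate at the organelle; membrane conduction
is a config switch. Boundary vertices simply have fewer neighbors.

## Dynamics

* **Potential**: `V_i = Σ_s δq_s e^{−r_is/λ}/r_is`, Euclidean distances in
  μm, Debye length λ = 1 μm (typical for cytosolic ionic strength). The
  1/r singularity at a source vertex is regularized with r = voxel/2, so
  the source holds the field maximum. Potentials are evaluated on
  conducting voxels only.
* **Front**: every informed voxel informs all occupied 26-neighbors at the
  next step, one voxel per step, unconditionally (pure Huygens front). The
  saturated informed set therefore equals BFS reachability from the
  sources — percolation is decided by connectivity alone and is identical
  for point and spherical sources, since the PC shell itself conducts. A
  strict-downhill gating mode exists as a config flag for exploration.
* **Current**: an informed vertex receives
  `I_i = Σ_{n uphill, informed} G_in (V_n − V_i)` — flow runs strictly from
  higher to lower potential and aggregates by Kirchhoff's current law.
  (The outflow-sum reading of the same expression would zero the signal at
  every receiver; the received-current form is the one consistent with
  information arriving at the organelle.)
* **Memory**: `S_t = β S_{t−1} + (1−β) tanh(I_t)`, `S_0 = 0`, β strictly
  inside (0, 1). No early-time bias correction is applied; the warm-up
  transient is part of the model's behavior.
* **Driven sequences**: per input sample the source charges are set to
  δq_t, the potential recomputed (adiabatic: the field permeates
  instantly relative to the perturbation timescale), the front advanced
  one step, currents and memory updated, and the organelle-surface memory
  snapshot recorded. Because potentials and currents are linear in the
  charge and the informed set is fixed after saturation, the engine caches
  the two unit current patterns (positive and negative drive; the uphill
  relation flips with the sign) and scales them by |δq_t| — numerically
  identical to stepwise recomputation (asserted to 1e-12 in the tests) and
  ~20× faster on long sequences.
* **Delay alignment**: the readout delay δt is the front's first
  organelle-surface arrival, measured once per (reservoir, source) by a
  charge-independent probe run and held fixed. Feature row `t` is the
  organelle state at step `t+δt`. So that this state exists for every
  sample even when the sequence is shorter than δt (the immune workflow
  drives only 4 samples), the input is extended by holding its last value
  for δt extra steps.
* **Units**: the simulation is unitless; the physical mapping is one step
  = voxel/speed (0.5 μm voxels at ion speeds of 1–10 m/s give 0.05–0.5 μs
  per step), and filament-bundle conductance G = σA/l spans 1e-8–1e-5 S
  for σ = 0.1–100 S/m over a 10 μm × 1 μm² bundle.

## Memory retention and the waveform tasks

The memory retention rate β has no canonical published value; it is the
one genuinely free dynamical parameter. The package default is **β = 0.5**
(decay timescale ≈ 2 steps), chosen from the following analysis rather
than convention.

In steady state every organelle-surface signal is an instantaneous (even)
transform of the scalar drive passed through the *same* exponential moving
average, so the fundamental Fourier component of every feature carries one
common phase lag φ(ω) = arctan(β sin ω / (1 − β cos ω)). A linear readout
can therefore reproduce a target sinusoid only up to an RMSE floor of
`|cos ψ|/√2`, where ψ is the residual phase mismatch after the δt feature
alignment. With a long memory (β ≈ 0.9, lag ≈ δt) this floor is 0.3–0.7
for any fixed task period — the linear-family readouts simply cannot track
a delayed sine. With a short memory the organelle state mirrors the
instantaneous drive, and if the demanded response delay equals the cell's
own signal-travel time the alignment cancels the phase almost exactly.

Accordingly the **delayed-response task** is defined physically: the input
is a cosine of amplitude 1 and period 4·δt (so the sine target *is* the
input delayed by the organelle-arrival time), length ten periods, trained
on the first quarter and tested on the rest. Under these conditions all
four readouts learn the sine response (test RMSE 0.09–0.14 on the
reference reservoir) while only the nonlinear ANN also learns the square
(threshold) response (0.22 vs 0.30 for linear) — the linear floor for a
square target is set by the per-harmonic phase locking above. The square
target is `sign(sin ωt)` with 50% duty cycle and amplitude 1.

Noise robustness adds N(0, σ²) to the *input* wave (σ ∈
{0.05, 0.1, 0.25, 0.5, 1.0}); errors are always reported against the
clean target. Test RMSE grows monotonically with σ for ridge and ANN;
the linear layer is the least robust and its blow-ups (observed on the
spherical source at σ = 1) are recorded in the result table as values —
with a `diverged` flag for non-finite cases — never raised.

## Readout layers

Linear, lasso and ridge are scikit-learn estimators over features
standardized on the training partition only (columns that are constant up
to float rounding are left unscaled — amplifying them by 1/sd ≈ 1e18
destroys conditioning). The split is temporal (first fraction trains), as
the rows are a time series.

The ANN is a single-hidden-layer tanh network (width 64) with a linear
output, written in numpy, trained by full-batch Adam (lr 0.01, 3000
epochs) with a **cosine-annealed step size** — at a fixed rate full-batch
Adam orbits the optimum instead of settling — and elastic-net
regularization: the L2 term enters the gradient, the L1 term is applied as
a **proximal soft-threshold** after each step (the subgradient form
oscillates under adaptive step sizes). The target is standardized
internally and the prediction unscaled. Defaults l1 = l2 = 1e-4. Width 64
at 3000 epochs was the smallest scanned configuration that learns the
square threshold; larger widths underfit within the same epoch budget.

Ensembles train `n_trials` (default 20) independently seeded readouts on
identical data; the per-point mean and sd of their predictions quantify
initialization uncertainty (zero for the deterministic linear family).

## The studies and their sizes

* **Percolation**: fill fractions 1–15% in 1% steps, 50 trials per
  fraction (a scale at which the 50% crossing reproduces stably to ±0.5
  points while the sweep stays interactive on one CPU; the CLI default is
  100), each trial a fresh seeded fill tested for PC→CO connectivity by
  26-connected component labeling. The stepping engine gives bitwise the
  same percolation verdicts (asserted against the BFS oracle); the
  labeling route is simply faster. The 50% crossing is linearly
  interpolated between bracketing sweep points. Representative results:
  crossing ≈ 7.5% of cytoplasm, guaranteed percolation from 10%,
  essentially none at ≤ 5%.
* **Front timing**: 20 geometry seeds at 20% fill; first organelle
  arrival ≈ 9–10 steps (spherical) and ≈ 13 steps (point), saturation
  ≈ 14 vs ≈ 39 steps — the point source must first spread along the
  peripheral shell. On the 41³ grid the minimum Chebyshev path from the
  PC shell (18 voxel radii) to the CO ball (5) is ≈ 8 steps along body
  diagonals, so ~10-step arrivals are geometrically tight.
* **Immune workflow**: the four extracellular-K⁺ conditions are an
  ascending length-4 input sequence with δq_t = ([K⁺]in − [K⁺]ex)/150
  ([K⁺]in = 150 mM; the 1/150 scale maps the maximal perturbation to unit
  charge). Each row's organelle state is concatenated with the
  organelle-surface-width replication of the ligand concentration and fit
  by the elastic-net ANN on all rows; replicate rows are averaged first.

## Synthetic immune tables

`synth_immune_table` emulates the *shape* of a flow-cytometry activation
summary: response frequency (% of parent cells) rises with ligand
concentration as a Hill curve (Emax 60%, EC50 1.5 mM, Hill 2) and falls
linearly with extracellular K⁺ (fractional suppression 0.6 at 40 mM),
plus optional Gaussian noise, clipped to [0, 100]. Default grids: ligand
{0.5, 1, 2, 3.5, 5} mM, K⁺ {0, 10, 20, 40} mM. It does **not** emulate
donor-to-donor variability, gating uncertainty, saturation kinetics or
ligand–K⁺ interaction terms, so passing the workflow on synthetic tables
demonstrates the pipeline's mechanics and fitting capacity — a zero-noise
table is fit to ≪ 0.5 percentage points — not biological validity on real
cytometry data, which must be supplied as a CSV with the documented
columns.

## Degenerate inputs and guards

Radii must satisfy 0 < r_co < r_pc < r_cm and the organelle must span at
least one voxel; the PC and CM shells must not coincide at the chosen
voxel size. β outside (0, 1) is rejected (0 = no memory, 1 = no
learning). Empty input sequences yield empty trajectories; zero charge
yields zero fields. Non-percolating geometries raise an explicit
"no signal reached organelle" error where features are required, and are
recorded (not raised) in sweep statistics. A max-steps guard (4× grid
side) bounds front propagation on pathological occupancy patterns.

## Known limitations

* Stable cytoskeletons only: no self-assembly or remodeling in response
  to fields; spherical cells only; a single central organelle.
* The potential field is a superposition ansatz, not a solution of the
  screened Poisson equation with boundary conditions; edges are pure
  resistors (no capacitive/inductive transients).
* Front propagation is connectivity-driven; the potential shapes current
  magnitudes but not the front, so arrival times are independent of
  charge.
* The phase-locking analysis above means linear readouts generalize to
  periodic targets only near the delay-matched regime; the ANN does not
  share this restriction.
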