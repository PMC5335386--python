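# Methods

This note documents the models implemented in `gluclear`, their
assumptions, the parameters that matter, and the design choices made
where the problem was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Simplified synapse scenes

A scene lives in a cubic world (edge 1 μm, reflective for glutamate)
centered on the middle of the synaptic cleft, with the synapse axis along
+z from the presynaptic to the postsynaptic terminal.

**Terminals.**  Each terminal is a sphere truncated by its cleft plane
(z = ∓10 nm for the default 20 nm cleft).  The flat apposition faces of
both terminals share the PSD-disc radius r = √(A_PSD/π) (≈178 nm for a
0.10 μm² PSD), and the sphere radius is solved numerically (Brent's
method on the closed-form truncated-sphere volume) so the enclosed volume
matches the specified value exactly.  For the control values this
reproduces the nominal 0.27 μm radius to within ~1%; the builder treats
the volume as the binding constraint because the printed TFLLR radius
(0.24 μm) is arithmetically inconsistent with its printed volume
(0.065 μm³ > (4/3)π·0.24³ ≈ 0.058 μm³).  The presynaptic solid is the
sphere minus its cleft-side cap; the postsynaptic solid is a
hemisphere-like cap.

**Astrocytic processes.**  Processes are flat rectangular slabs, 50 nm
thick and 0.5 μm tall, arranged with equal angular spacing around the
cleft axis.  The inner face sits at radial distance r_PSD + d, which
makes the nearest distance between the PSD disc and the process face
exactly the specified d (116 nm control, 190 nm TFLLR).  The slab width
is solved in closed form so the total surface area of the box (both
faces plus edges) equals the specified per-process area.  Flat slabs
were chosen over curved sheets because they give exact area control and
exact specular reflection against axis-aligned local frames; every
scalar constraint of the scene description (process count, per-process
area, PSD distance, world size) is still honored.  The builder raises a
feasibility error when the slabs cannot be packed (outside the world
box, overlapping each other, or intersecting a terminal).

**Meshes vs. solids.**  Each compartment is meshed (20 nm target edge)
for measurement and OBJ interchange; the build fails if a mesh area or
volume deviates more than 1% from its specification.  The particle
engine, however, collides against the *exact parametric solids*
(truncated spheres, slabs, world box), not the meshes — reflections are
analytic and no mesh-resolution error enters the dynamics.  Mesh
measurement uses `trimesh`; OBJ I/O is a minimal triangles-only
reader/writer whose write-then-read round trip is bit-identical.

**Surface molecules.**  Placement draws triangles with area-proportional
probability and uniform barycentric coordinates; the count is the
deterministic round(density × measured area) rather than a Poisson draw,
so counts are exactly reproducible and testable.  The default transporter
density is 10,800 μm⁻²; PSD receptor pools (GluA 200, GluN 300 μm⁻²) are
placed but participate in the dynamics only when enabled.

## Particle engine

Each of the 2,000 released molecules takes per-axis Gaussian steps with
σ = √(2·D·Δt) at Δt = 10 μs over 5,000 iterations (50 ms).  D is chosen
by the particle's pre-step region: the free-solution value
3.3×10⁻⁶ cm²/s inside the cleft cylinder (the cylinder between the
terminal faces with the PSD-disc radius) and the apparent value
1.41×10⁻⁶ cm²/s elsewhere, representing neuropil tortuosity.  The
λ-decomposition (λ_g, λ_v, λ_x with λ = 1.6) is carried as provenance
metadata only; the engine takes both diffusion coefficients literally and
never recombines the factors, since the two printed values and λ = 1.6
are not mutually consistent under D* = D/λ².

**Reflections.**  A displacement segment is tested against every surface
(world planes, sphere portions, flat cleft faces, slab boxes); the
earliest intersection reflects the residual displacement specularly.  Up
to 10 reflections are resolved per step; in the rare case the budget is
exhausted (a long step rattling inside the 20 nm cleft) the particle is
clamped at its last valid position and the event is counted in
`SimResult.clamped_steps` (~10⁻⁵ of particle-steps in the default
scenes).  Release is on the cleft axis, 1 nm from the presynaptic face.

**Bimolecular binding.**  A collision with a transporter-covered surface
binds with probability p = k_on′·σ·√(π·Δt/D), where k_on′ is the
per-pair rate in μm³/s and σ the free-transporter surface density.  This
is the probability that makes the discrete-time wall-collision flux of
Brownian particles (c·√(D/(π·Δt)) per unit area) reproduce the
mass-action rate k_on·[T]·[G] in the well-mixed limit; the binding
contract is therefore not the formula but the calibration test, which
compares a sealed transporter-covered box with no translocation against
the mass-action ODE (time-binned agreement within 5% of the saturating
bound count, 10 seeds).  The probability is scaled by the instantaneous
free fraction of the process's transporters, and a configuration with
p > 1 is rejected.

**Transporter states.**  Bound glutamate unbinds (k_off) or is
translocated (k_trans) with per-step probability 1 − exp(−k_tot·Δt) and
rate-proportional branching; translocated glutamate leaves the diffusing
pool permanently and the carrier becomes inward-facing, returning with
k_reorient (binomial thinning per step).  Unbound glutamate re-enters
1 nm off the surface along the stored face normal.  All rates are Q₁₀ = 3
scaled from 25 °C to 35 °C by default (one factor of 3), including the
bimolecular k_on; `scale_bimolecular=False` restricts scaling to the
unimolecular rates.  Receptors, when enabled, act as reversible surface
buffers on the PSD disc; their full gating schemes belong to the
deterministic EPSC module, and the shipped receptor rate set is
synthetic (see below).

**Determinism and conservation.**  One explicitly seeded RNG stream per
seed makes every run bit-reproducible; free + transporter-bound +
receptor-bound + translocated is asserted equal to the release count at
every recorded step, and a particle found outside the world box aborts
the run.

## Transporter kinetics

The cyclic carrier uses the printed rates k_on = 6×10⁶ M⁻¹s⁻¹,
k_off = 601 s⁻¹, k_trans = 2,000 s⁻¹, k_reorient = 50 s⁻¹.  The apparent
steady-state affinity implemented is the cyclic-carrier value
K_m = (k_off + k_trans)·k_reorient / (k_on·(k_reorient + k_trans)),
the unique concentration at which the steady-state translocation flux of
this scheme is half-saturating (verified numerically across a
30-fold concentration range).  With the printed rates this gives
10.6 μM, whereas the nominal affinity is quoted as 13 μM; no standard
steady-state expression reconciles the printed (K_m, k_off) pair, so
both are kept as independent configuration entries and the printed
k_off wins for simulation.

Well-mixed propagation offers a per-step matrix-exponential path
(unconditionally stable, exact for piecewise-constant ligand) and
classical RK4 with an explicit step-size guard; occupancies are checked
to remain a probability vector at every step.

## Transporter-current analysis

The facilitated STC is the paired-pulse record minus the single-pulse
record, time-shifted to its own stimulus (100 ms inter-pulse interval).
Kinetics are fitted with
A·(1−exp(−(t−t₀)/τ_rise))·(f·exp(−(t−t₀)/τ_fast)+(1−f)·exp(−(t−t₀)/τ_slow)),
multi-started over decay and rise initializations.  τ_rise is capped at
four times the time-to-peak: without the cap the rise term is degenerate
with the amplitude (A(1−e^{−t/τ}) → A·t/τ), and the fitted decay
decomposition becomes meaningless.  The centroid is
⟨t⟩ = Σt·|I|/Σ|I| from the stimulus over a 0–100 ms window with a 50 ms
pre-stimulus baseline.

**Filter derivation.**  In sub-saturating antagonist (10 μM TBOA) the
fSTC decay approaches the clearance time course, so the antagonist-
condition clearance is modeled as an instantaneous rise followed by the
fSTC's own biexponential decay, fitted on the decay phase only (the
full product model is not used here because only the decay matters and
the rise/decay trade-off would leak into the filter).  The filter is the
Wiener deconvolution of the TBOA fSTC by that clearance, rectified,
truncated to a 30 ms support, and normalized to unit area.  The
truncation reflects the physics — the distortion kernel is fast — and
removes the rectified noise tail that would otherwise bias the
subsequent clearance estimate toward faster centroids.

**Clearance estimation.**  The control-condition clearance is the Wiener
deconvolution of the control fSTC by the filter, with the regularization
λ set from the measured pre-stimulus noise power (Ĝ = H*/(|H|²+λ·max|H|²)).
The reported waveform is rectified at zero and peak-normalized; the
*centroid*, however, is computed on the raw (unrectified) estimate, so
that zero-mean deconvolution noise cancels in both moments instead of
being rectified into spurious late mass.  Convolving the raw estimate
back with the filter must reproduce the input; the relative RMS of that
reconstruction is reported with every estimate.

## Line-scan diffusion analysis

Profiles are sampled every 150 ms after the puff (every ~94 lines at
625 Hz), with the averaged pre-puff profile subtracted.  Each profile is
fitted with A·exp(−(x−x₀)²/γ²)+c; in this convention γ² = 4·D·t for an
instantaneous point source, so D is the slope of the unweighted linear
regression of γ²/4 on time within the 2 s linearity window (minimum
three surviving fits; failed fits are dropped; the intercept absorbs the
finite initial source width).  Tortuosity is λ = √(D_free/D*) and the
hydrodynamic diameter d_H = kT/(3πηD) with T = 295 K and
η = 9.68×10⁻⁴ Pa·s.  d_H is computed from whichever coefficient is
passed; applying it to an in-tissue apparent coefficient mixes hindrance
into an equivalent free-medium size and is reproduced here deliberately,
as the analysis convention this package follows.  Per-experiment values
(one D per kymograph, λ and d_H per experiment) are the primary outputs;
pooling across experiments is left to the caller's statistics.

## Kinetic EPSC simulations

Receptor schemes are ligand-driven Markov chains integrated with
classical RK4 at a 5 μs step (occupancy leak > 10⁻⁶ aborts; halving the
step changes peaks by < 0.1%).  The glutamate transient is an
instantaneous rise with monoexponential decay; the antagonist is held at
its bath concentration and the initial state is the resting equilibrium
*with antagonist bound* — omitting that pre-equilibration inverts the
block's dependence on transient duration.  Block ratio is
peak(B)/peak(0); the contour module integrates the whole (peak, τ) grid,
with and without antagonist, as one vectorized batch.  Trains default to
5 pulses at the experimental 100 ms paired-pulse interval and report
per-pulse peaks and the last/first summation index.

The shipped receptor file `glua_synthetic.yaml` is a generic
two-binding-site, desensitizing, ligand-gated scheme with a competitive
antagonist site (K_B = 100 μM) and plausible but *synthetic* rate
constants; published AMPA/NMDA rate sets drop in by editing the YAML.
Property-level behavior (monotone block contours, Schild-type
equilibrium limit, desensitization-dependent train summation) does not
depend on the specific numbers.

## Synthetic data

The generators are pure functions of (spec, seed) and always emit their
ground truth.

- **Transporter currents** — clearance (instantaneous rise,
  biexponential decay: f = 0.3, τ_fast = 5 ms, τ_slow = 18 ms, windowed
  centroid ≈ 16.5 ms) convolved with a gamma-kernel filter (shape 2,
  2 ms peak), scaled to a 27.7 pA response with paired-pulse
  facilitation 1.7 and Gaussian noise (default 0.3 pA ≈ 1%).  The TBOA
  condition scales the amplitude by 0.36 and the slow decay by 2.2.
  These defaults were calibrated once so the fitted fSTC decay lands
  near the control values (τ_fast ≈ 5, τ_slow ≈ 18 ms).
- **Kymographs** — the analytic instantaneous-point-source solution
  observed along a scan line offset 5 μm from the source, 625 Hz line
  rate, with Poisson photon noise and the recorded trace modeled as the
  average of 10 consecutive applications, as in the acquisition
  protocol.  The scan line is 384 μm (384 × 1 μm pixels) so that even
  the widest profile in the 2 s window (γ ≈ 63 μm at D = 0.5 μm²/ms)
  leaves flat wings and the Gaussian width and offset stay jointly
  identifiable.
- **Scene statistics** — truncated-normal draws around the
  reconstruction means ± SDs for the control and PAR1-activated groups,
  with physical floors (distance ≥ 0, positive volumes/areas, integer
  process counts).

What the generators deliberately do **not** emulate: stimulus artifacts,
series-resistance errors, baseline drift, photobleaching, a
finite-duration or finite-size source, or rise-time structure in the
clearance itself (the instantaneous rise is the same assumption the
deconvolution method makes).  Passing round-trip tests therefore shows
the analysis chain is consistent and correctly implemented under its own
model assumptions — not that those assumptions hold in any particular
recording.

## Problem sizes and numerical checks

The packaged scientific checks run the engine at its native conditions —
2,000 molecules, 5,000 × 10 μs steps — with 30 seeds per condition for
the control/TFLLR/half-density comparisons (one-sided rank tests,
α = 0.05), 10⁴ particles × 10³ steps for the Einstein-relation
calibration (2% tolerance), 10 seeds for the well-mixed binding
calibration (5%), 100 seeded repeats for the deconvolution round trip
(5% on the clearance centroid), and three decades-spanning coefficients
for the line-scan recovery (5%).

## Known limitations

- Simplified scenes only: the reconstructed-tomogram geometry pathway
  accepts meshes for measurement but the engine's collision geometry is
  parametric, so arbitrary triangle soups are not simulated.
- No electrodiffusion, voltage dependence of transport, or extracellular
  K⁺ dynamics (the sustained K⁺ current is measured, not modeled).
- The astrocytic slab volume implied by area × 50 nm thickness is
  smaller than the mean reconstructed process volume; the scenes match
  the stated surface areas, counts and distances, not process volume.
- Receptor buffering in the particle engine ignores gating and
  desensitization; those belong to the deterministic EPSC module.
- The engine's binding calibration holds for surface densities and time
  steps with p ≪ 1; pathological configurations are rejected rather than
  corrected.
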