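# gluclear

Modelling and analysis of synaptic glutamate clearance by astrocytes.

Fine astrocytic processes wrap excitatory synapses and terminate
glutamatergic transmission by taking up glutamate through high-density
membrane transporters (~10,800 μm⁻² in hippocampal *stratum radiatum*).
When the astrocytic protease-activated receptor PAR1 is stimulated (e.g.
by the peptide agonist TFLLR), the processes around a synapse multiply,
shrink, and retreat — and glutamate is cleared *faster*.  `gluclear`
packages the computational machinery needed to study this regime:

- **`gluclear.geometry`** — builds simplified 3D synapse scenes (two
  terminals separated by a 20 nm cleft inside a 1 μm³ world, surrounded by
  transporter-covered astrocytic slabs), measures triangulated meshes
  (surface area, divergence-theorem volume, nearest surface distances),
  and computes neuropil descriptors such as the local uptake capacity
  `d · N_astro · SA_1astro`.
- **`gluclear.mcsim`** — a particle-based Monte Carlo reaction–diffusion
  engine: 2,000 glutamate molecules released in the cleft take Gaussian
  Brownian steps (σ = √(2·D·Δt), Δt = 10 μs, D = 3.3×10⁻⁶ cm²/s in the
  cleft and 1.41×10⁻⁶ cm²/s in the tortuous neuropil), reflect specularly
  off every surface, and react stochastically with transporters.
- **`gluclear.kinetics`** — the cyclic transporter carrier
  T ⇌ TG → T_in → T (k_on = 6×10⁶ M⁻¹s⁻¹, k_off = 601 s⁻¹,
  k_trans = 2,000 s⁻¹, k_reorient = 50 s⁻¹, Q₁₀ = 3 scaling to 35 °C),
  general ligand-driven Markov schemes in editable YAML, and well-mixed
  deterministic propagation used as the engine's calibration oracle.
- **`gluclear.stc`** — astrocyte transporter-current analysis: fSTC
  isolation from paired-pulse protocols, multi-exponential kinetic fits,
  centroid ⟨t⟩ = Σt·|I|/Σ|I|, and Wiener deconvolution of the distortion
  filter (derived in sub-saturating TBOA) to recover the glutamate
  clearance waveform.
- **`gluclear.linescan`** — two-photon line-scan diffusion analysis:
  Gaussian profile fits with pre-puff subtraction, D from the regression
  of γ²/4 on time, tortuosity λ = √(D_free/D*), and Stokes–Einstein
  hydrodynamic diameter d_H = kT/(3πηD).
- **`gluclear.epsc`** — deterministic Q-matrix receptor simulations (RK4,
  5 μs step): EPSC block by competitive antagonists over grids of
  glutamate-transient amplitude and decay, iso-block contours, and train
  summation.
- **`gluclear.synth`** — seeded generators for every input class
  (transporter-current sweeps, kymographs, geometry statistics), each
  returning its ground truth so every analysis is testable end to end
  without any recordings.

## Worked example 1 — uptake simulations

```bash
gluclear run --config examples/fig4_quick.yaml --out runs/fig4_quick
gluclear report --manifest runs/fig4_quick/manifest.json
```

With the example configuration trimmed to 5 seeds this prints:

```
Glutamate lifetime centroids (cleft / neuropil counts):
           condition  density (um^-2)  cleft <t> (ms)  cleft SEM  neuropil <t> (ms)  neuropil SEM
             control          10800.0           0.107      0.010              3.213         0.063
               tfllr          10800.0           0.049      0.007              2.019         0.042
control_half_density           5400.0           0.412      0.038              6.037         0.098
  tfllr_half_density           5400.0           0.143      0.005              3.759         0.065
```

The centroid of the free-glutamate count time course is the summary
statistic for clearance speed: the PAR1-activated (TFLLR) geometry —
four smaller processes, farther from the synapse but with ~40% more
total transporter-bearing surface — clears both the cleft and the
neuropil faster than control, and halving the transporter surface
density slows clearance in both geometries.

## Worked example 2 — clearance from transporter currents

```python
from gluclear.synth import SynthSpec, synth_fstc
from gluclear.stc import TransporterCurrentModel

spec = SynthSpec(seed=0)
single, paired, truth = synth_fstc(spec)
tboa_single, tboa_paired, _ = synth_fstc(spec, tboa=True)
res = TransporterCurrentModel(single, paired, tboa_single, tboa_paired).fit()
print(res.summary())
```

```
                                      value
fSTC peak (pA)                   -46.233896
fSTC 20-80% rise (ms)              2.367872
fSTC tau_fast (ms)                 5.623695
fSTC tau_slow (ms)                16.586945
fSTC fast fraction                 0.837953
fSTC centroid <t> (ms)            20.090160
fit R^2                            0.997443
clearance centroid <t> (ms)       15.672917
deconvolution reconstruction RMS   0.034075
```

The fSTC is the convolution of glutamate clearance with a distortion
filter; deconvolving the filter (derived from the slowed fSTC in 10 μM
TBOA) recovers a clearance centroid of 15.7 ms against a generator
ground truth of 16.2 ms (−3%), and convolving the estimate back with the
filter reproduces the recorded trace to 3.4% RMS.  The clearance
centroid is faster than the fSTC centroid, as it must be.

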