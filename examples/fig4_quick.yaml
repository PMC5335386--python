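# Quick in-silico uptake comparison: control vs PAR1-activated (TFLLR)
# simplified scenes at full and reduced transporter density, 30 seeds.
# Run with:  gluclear run --config examples/fig4_quick.yaml --out runs/fig4_quick
experiment: fig4_quick
conditions:
  - name: control
    scene: control
  - name: tfllr
    scene: tfllr
  - name: control_half_density
    scene: control
    transporter_density: 5400.0
  - name: tfllr_half_density
    scene: tfllr
    transporter_density: 5400.0
simulation:
  dt_us: 10.0
  n_iterations: 5000
  n_molecules: 2000
  record_stride: 10
  seeds: "0:30"
kinetics:
  q10: 3.0
  t_ref: 25.0
  t_sim: 35.0
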