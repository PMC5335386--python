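# Synthetic AMPA-receptor-like scheme with competitive antagonist binding.
#
# This is a generic two-binding-site, desensitizing, ligand-gated scheme
# with plausible (not literature-fitted) rate constants, provided so the
# EPSC machinery runs out of the box.  Swap in a published rate set by
# editing this file or pointing the loader at another scheme document.
#
# States: C0 (unbound), C1 (one glutamate), C2 (two glutamate), O (open),
# D (desensitized), B (antagonist-bound, competitive at the resting state;
# K_B = 100 uM).
name: glua_synthetic
states: [C0, C1, C2, O, D, B]
transitions:
  - {from: C0, to: C1, rate: 2.0e7, ligand: glutamate}
  - {from: C1, to: C0, rate: 5000.0}
  - {from: C1, to: C2, rate: 1.0e7, ligand: glutamate}
  - {from: C2, to: C1, rate: 10000.0}
  - {from: C2, to: O, rate: 20000.0}
  - {from: O, to: C2, rate: 3000.0}
  - {from: C2, to: D, rate: 800.0}
  - {from: D, to: C2, rate: 20.0}
  - {from: C0, to: B, rate: 1.0e7, ligand: antagonist}
  - {from: B, to: C0, rate: 1000.0}
conducting: [O]
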