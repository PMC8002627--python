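# End-to-end toy pipeline: sample ligand and confined complex, assemble
# CREs, and report the three binding free-energy flavors.
#   crebind run examples/pipeline_demo.yaml
seed: 11
temperature: 298.15
windows: [15, 10, 6]
output_dir: crebind_out
simulate:
  n_torsions: 2
  steps: 1500
  barrier: 2.0
  binding_offset: -8.0
  host_semiaxes: [4.0, 4.0, 4.0]
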