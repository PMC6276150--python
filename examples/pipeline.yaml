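# Example end-to-end run: simulate -> fit -> project -> validate -> dca.
# `erisk run --config examples/pipeline.yaml`
seed: 1
n: 20000
outdir: erisk_out
stages:
  simulate: true
  impute: false
  fit: true
  project: true
  validate: true
  dca: true
horizon: 5.0
dca_cause: er_pos
dca_grid_step: 0.0005
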