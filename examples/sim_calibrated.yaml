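# Generate the default calibrated synthetic dataset:
#   hetenrich simulate --config examples/sim_calibrated.yaml --outdir simout
# then analyse it:
#   hetenrich run --config simout/run_config.yaml --outdir runout
seed: 0
sim:
  calibrated: true
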