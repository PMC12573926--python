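# End-to-end synthetic step-size study for `ssxdamage run-all`.
# Two simulated beamtimes share the same toy active site; the second one
# plants a step-size-dependent Fe-Wat elongation below 25 µm.
seed: 1

structure:
  fe_wat: 2.45        # Å
  fe_his: 2.1         # Å
  feoop: 0.3          # Å, signed toward the distal water

recipe:
  n_images: 30
  reflections_per_image: 0.4
  noise_sd: 0.1
  scale_sd: 0.15
  resolution_limit: 2.0

bootstrap:
  n_replicas: 30
  scramble_sd: 0.3

beamtimes:
  - name: clean
    step_sizes: [100, 75, 50, 25]
  - name: damaged
    step_sizes: [100, 50, 25, 15, 10]
    damage:
      threshold: 25     # µm: elongation ramps in below this step size
      elongation: 0.2   # Å at step -> 0

cells:
  k: 2
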