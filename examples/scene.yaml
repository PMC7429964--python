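# Example scene for `dffoct simulate --scene scene.yaml --out cube.tif`
# A fast disk inside a slow background, with exposure drift and shot noise.
width: 64
height: 64
n_frames: 512
frame_rate: 100.0
background_level: 20000.0
reference_level: 8000.0
shot_noise: true
exposure_drift: {kind: sinusoidal, amplitude: 0.02, period: 100}
regions:
  - shape: {type: disk, center: [32, 32], radius: 12}
    model: {kind: relaxation_phase, amplitude: 0.5, rate: 20.0, seed: 1}
  - shape: {type: rect, top: 0, left: 0, height: 64, width: 16}
    model: {kind: relaxation_phase, amplitude: 0.5, rate: 2.0, seed: 2}
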