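# End-to-end example: generate fixtures, draw a lesion, compose a mosaic,
# render a 3D view, and build a lesion incidence map.  Deterministic for a
# fixed seed: rerunning reproduces byte-identical PNG/CSV/NIfTI outputs.
#
# Run from anywhere:  voxview script examples/pipeline.yaml
# (relative paths resolve against this file's directory)
seed: 7

tasks:
  - command: fixtures
    output: out/fixtures
    options:
      lesions: 10

  - command: draw
    inputs: [out/fixtures/phantom.nii.gz]
    output: out/drawn.voi
    options:
      ops:
        - {op: ellipse, slice: 12, box: [[6, 6], [16, 18]], filled: false}
        - {op: bucket, slice: 12, seed_point: [11, 12]}
        - {op: pen, slice: 13, points: [[8, 8], [8, 16], [14, 16]], thickness: 3}
        - {op: paste, from: 13, to: 14}
        - {op: morph, operation: close, radius: 1}

  - command: mosaic
    inputs: [out/fixtures/phantom.nii.gz]
    output: out/mosaic.png
    options:
      axis: axial
      slices: [4, 8, 11, 12, 14, 20]   # arbitrary, not equidistant
      columns: 3
      overlap_fraction: 0.25
      scale: 2
      overlays: [out/drawn.voi]
      overlay_lut: red
      overlay_min: 0.5
      overlay_max: 1.0
      overlay_opacity: 0.6

  - command: render
    inputs: [out/fixtures/phantom.nii.gz]
    output: out/render.png
    options:
      azimuth: 35
      elevation: 15
      mode: composite
      step_mm: 1.0
      opacity_gain: 0.12
      image_size: [128, 128]
      cutout: [[16, 32], [0, 16], [12, 24]]
      hybrid: true

  - command: incidence
    inputs:
      - out/fixtures/lesion000.voi
      - out/fixtures/lesion001.voi
      - out/fixtures/lesion002.voi
      - out/fixtures/lesion003.voi
      - out/fixtures/lesion004.voi
      - out/fixtures/lesion005.voi
      - out/fixtures/lesion006.voi
      - out/fixtures/lesion007.voi
      - out/fixtures/lesion008.voi
      - out/fixtures/lesion009.voi
    output: out/incidence.nii.gz
    options:
      csv: out/lesions.csv
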