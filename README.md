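# optomask

Analysis pipeline for trial-based widefield calcium-imaging experiments in
which a visual detection target is combined with direct optogenetic
stimulation ("optostim") acting as a mask. The package covers:

- **synthetic sessions** (`optomask.synth`): a forward model producing image
  stacks, behavioral trial tables and a ground-truth sidecar — two Gaussian
  expression sites, Naka-Rushton visual responses, optostim responses at one
  site, a configurable sublinear visual×optostim interaction (visual
  component scaled by `1 − rho`), heart-rate-dependent periodic artifacts,
  translational micro-motion, linear drift, sensor noise, and choices drawn
  from a d′ psychometric model — so every downstream stage is testable by
  parameter recovery;
- **preprocessing**: motion-regression image stabilization
  (`optomask.stabilization`), ΔF/F with a pre-stimulus baseline, heart-rate
  polynomial artifact removal (`optomask.heartbeat`), ROI selection, linear
  detrending, response-window averaging, and blank-trial z-scoring
  (`optomask.extraction`);
- **neural analysis** (`optomask.neural`): weighted Naka-Rushton
  contrast-response fits, optostim-baseline subtraction, the closed-form
  proportional-reduction statistic ρ, and within-condition bootstrap
  inference;
- **behavior analysis** (`optomask.behavior`): joint maximum-likelihood
  signal-detection psychometric fits (per-block threshold α and criterion δ,
  shared steepness β), bias-corrected percent correct, normalized threshold
  ratios, and stratified bootstrap inference;
- **IO and orchestration** (`optomask.session_io`, `optomask.pipeline`,
  `optomask.cli`): HDF5/TIFF stack formats, CSV trial tables, YAML configs,
  and an end-to-end runner with a traceable JSON report.

## CLI

```bash
# generate a synthetic session (stacks.h5 + trials.csv + ground_truth.json)
optomask simulate --config cfg.yaml --seed 7 --out session/

# preprocess a session into a per-trial z-score table
optomask preprocess --in session/ --out pre/

# analyses
optomask analyze-neural   --in pre/samples.csv   --out results/ --n-boot 1000
optomask analyze-behavior --in session/trials.csv --out results/ --n-boot 1000

# end-to-end with a JSON run report
optomask run --config cfg.yaml --seed 7 --out run/
optomask report --in run/report.json
```

`cfg.yaml` accepts any `SessionConfig` field (see `optomask/config.py`);
omitted fields default to the reference protocol: 20 Hz acquisition with 24
frames, target onset 250 ms and optostim onset 290 ms after the cue, 5 ms
pulses every 22.5 ms for 210 ms, three baseline frames before onset, a
50–200 ms response window, a 1×1 mm ROI, proportions rescaled to
[0.005, 0.995], and 1000 bootstrap resamples.

## Conventions

Arrays are indexed `[t, y, x]`, 0-based; pixel coordinates are (x right,
y down); times are in ms relative to the cue unless a name says otherwise;
1-based frame labels like "F5" map to 0-based index 4. Motion vectors are
stored `(dy, dx)`.
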