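# vogkit

A modular video-oculography (video-based eye-tracking) toolkit in Python:
interchangeable frame sources, tracking pipelines and calibration methods,
glued together by a buffered multi-worker session runner with strictly
in-order output — plus a synthetic infrared eye-video generator with
analytic ground truth, so every pipeline is testable without recorded data.

## Features

- **Dark-pupil tracking** by three interchangeable methods: centroid,
  convex hull and direct least-squares ellipse fitting, with brightness
  thresholds and blob size limits (`vogkit.pupil`).
- **Corneal-reflection (glint) detection** and the pupil–CR vector that
  cancels camera/head translation (`vogkit.glints`).
- **Ocular torsion** via polar unwrapping of an iris annulus and normalized
  circular cross-correlation against a reference profile, with sub-sample
  parabolic refinement (`vogkit.torsion`).
- **Digital dual-Purkinje tracking**: P1/P4 spot detection and the P1−P4
  differential signal (`vogkit.dpi`).
- **Calibration**: geometric eye-model mapping (`asin` of normalized pupil
  displacement) or per-axis polynomial regression against fixation targets,
  with target-schedule files and calibration-file round-trip
  (`vogkit.calibration`).
- **Sessions**: plugin registry, typed settings with `section.key = value`
  text-file round-trip, bounded FIFO frame buffer (incoming frames are
  dropped — and flagged — when full in realtime mode), multi-worker
  processing with deterministic, frame-ordered output (`vogkit.core`).
- **Recording**: versioned tab-separated data files (one row per frame per
  eye, NaN for missing values, `#EVENT` markers), velocity/RMS trace
  metrics, batch reprocessing (`vogkit.recording`).
- **Lossless I/O**: uncompressed 8-bit grayscale AVI (hand-written RIFF,
  bit-exact round-trip) and PNG sequences, timestamp side-cars, and
  split/crop/rotate/flip pre-processing (`vogkit.video_io`).
- **Synthetic eye renderer**: pupil pose from a spherical projection model,
  harmonic iris texture, glints, P4 spot, eyelid occlusion and seeded
  noise, with per-frame analytic truth rows (`vogkit.synthetic`).
- **Remote control**: JSON-lines-over-TCP command protocol
  (status / startRecording / stopRecording / setSetting / getLastSample /
  recordEvent) (`vogkit.remote`).

## CLI

```sh
# generate a synthetic fixture (lossless AVI + ground-truth TSV)
vogkit synth --out fixtures/ --trajectory fixation --frames 100 --seed 1

# process one video into a data file
vogkit process --video fixtures/video.avi --out data.tsv

# reprocess a batch (TSV job list: video <TAB> settings <TAB> out ...)
vogkit batch --jobs jobs.tsv

# fit a regression calibration from tracked data + a target schedule
vogkit calibrate --data data.tsv --targets targets.txt --out cal.txt

# JSON-lines TCP remote-control server
vogkit serve --port 9000
```

Settings files are flat text (`pipeline.pupil_threshold = 80`, `#`
comments) with sections `system`, `pipeline` and `calibration`; every
setting has a typed default and unknown keys are rejected.

## Conventions

Images are 8-bit grayscale, origin top-left, x rightward, y downward;
pixel (i, j) has coordinates exactly (x=j, y=i).  Horizontal gaze is
positive rightward, vertical positive upward (image y negated); torsion is
positive for rotation from +x toward +y.  Ellipse axes are full lengths
(major ≥ minor) with the major-axis angle in [0°, 180°).  These are
recorded in every data-file header.
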