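# pifr

Pose-angle fall detection from COCO-17 keypoint streams.

`pifr` turns per-frame human skeletons (17 keypoints per person, as
produced by any pose-estimation backend) into confirmed fall events:

1. **Geometric features** — nine per frame: normalized center-of-mass
   x/y plus seven angles (shoulder–nose, torso vs. vertical, hip and
   shoulder lines vs. horizontal, both knee angles, nose-to-mid-ankle
   vs. vertical). All angles are in degrees, clamped to [0, 180], and
   invariant under translation and uniform scaling of the skeleton.
2. **Preprocessing** — moving-average smoothing (causal or centered),
   angle normalization (degrees/180 or z-score), missing-feature
   resolution (drop or short forward-fill), and keypoint-space training
   augmentation (rotation ±15°, scaling 0.75–1.25, horizontal flip with
   left/right keypoint swap, Gaussian jitter).
3. **Posture classification** — a per-frame standing (1) / lying (0)
   classifier. Default: RBF-kernel SVM with C = 1.0, gamma = 0.1;
   decision-tree, random-forest, and gradient-boosting families are
   available behind the same interface.
4. **Temporal fall criteria** — a per-track state machine with three
   configurable rules (lying duration in seconds, in frames, and
   standing→lying transition speed with a confirmation run), any/all
   combination, gap-tolerant track state, and at most one event per
   lying run.
5. **Skeleton simulator** — labeled synthetic sequences (standing,
   walking, lying, fast/gradual falls, crouch confounder) with exact
   ground truth, per-keypoint jitter, dropout, and mid-fall detector
   blackout, so the whole pipeline is testable without video or a
   pose network.

No video decoding, detection, or pose estimation is included: any
backend that emits 17-keypoint skeletons plugs in via the stream
formats below (a `PoseBackend` callable interface and a null stub are
provided).

## Data formats

- **Keypoint streams (canonical, JSONL)**: one JSON object per
  person-frame with keys `track_id`, `frame_index`, optional
  `timestamp_s`, and `keypoints` = flat list of 51 floats
  (x1, y1, c1, …, x17, y17, c17) in COCO order. A header object
  `{"fps": 30.0}` precedes the records. COCO keypoint JSON is accepted
  read-only.
- **Feature tables (CSV)**: columns `track_id, frame_index, cm_x, cm_y,
  shoulder_nose, torso, hip, shoulder, left_leg, right_leg, nose_ankle`
  plus an optional `label` column (0 = lying, 1 = standing).
- **Events (JSON)**: list of objects with `track_id`, `trigger_frame`,
  `lying_onset_frame`, `criterion`, `transition_duration_frames`.

Coordinates are image coordinates (origin top-left, y down): an upright
person has torso angle ≈ 0°, a horizontal one ≈ 90°.

## Command line

```sh
# generate labeled synthetic sequences + manifest.csv
pifr simulate --scenario fall_fast --n 10 --seed 7 --out sims/

# extract the nine-feature table from a stream
pifr extract --keypoints sims/fall_fast_000.jsonl --out features.csv

# train / evaluate the posture classifier
pifr train --features train.csv --family svm --seed 42 --out model.pifr
pifr eval --model model.pifr --features test.csv --report report.json

# classify a stream and confirm falls
pifr detect --keypoints sims/fall_fast_000.jsonl --model model.pifr --events events.json

# everything driven by a YAML config
pifr run --config pifr.yaml
```

Example config (all keys optional; unknown keys are rejected):

```yaml
preprocess: {smoothing_window: 5, smoothing_mode: causal, angle_norm: degrees_over_180, missing_policy: drop_frame}
classifier: {family: svm, rng_seed: 42}
criteria:   {time_threshold_s: 5.0, combine_mode: any, gap_tolerance: 30}
fps: 30.0
paths:
  keypoints: stream.jsonl
  model: model.pifr
  events: events.json
```

## Python API

```python
from pifr import (generate_training_table, train, ClassifierSpec,
                  generate, detect, FallCriteria)
from pifr.simulate import default_scenario
from pifr.pipeline import label_stream
from pifr.config import PipelineConfig

table = generate_training_table(500, jitter_sd=3.0, seed=42)
model = train(table, ClassifierSpec("svm", rng_seed=42))

seq = generate(default_scenario("fall_fast", seed=7), track_id="p1")
_, labels = label_stream(seq.stream, model, PipelineConfig())
events = detect(labels, FallCriteria(time_threshold_s=5.0), fps=seq.stream.fps)
```

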