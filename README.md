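# armsign

Hardware-independent pipeline for recognizing sign-language words from two
forearm-worn sensor bands, each providing 8 surface-EMG channels at 200 Hz
(integers in [−127, 128]) and a 10-value IMU frame at 50 Hz (accelerometer
in g, gyroscope in rad/s, orientation quaternion). The pipeline:

1. **`armsign.synth`** — seeded synthetic two-armband recordings, continuous
   sessions with ground-truth annotations, and balanced labelled datasets
   (e.g. 80 signs × 10 repetitions → 800 recordings; a 1-second recording
   holds exactly 2 × (8·200 + 10·50) = 4200 raw scalar samples).
2. **`armsign.kinematics`** — Euler/quaternion conversion (intrinsic Z–Y–X)
   and wrap-aware angular differences.
3. **`armsign.segmentation`** — motion detection on continuous streams: an
   EMG frame-to-frame change ≥ 40 or a mean Euler-angle change > 20° opens
   a segment; 60 ms of global quiet (12 EMG frames at 200 Hz) closes it;
   segments shorter than 0.4 s are discarded.
4. **`armsign.features`** — the 1044-value per-segment descriptor:
   16 EMG channels × 46 features (time/frequency/entropy banks: MAV, RMS,
   zero crossings, Willison amplitude, Hjorth parameters, Higuchi/Petrosian
   fractal dimensions, DFA, Hurst, spectral moments, wavelet energy, AR
   coefficients/errors, Shannon/spectral/SVD/Fisher entropies, …),
   12 accel/gyro channels × 17 features, 8 quaternion channels × 13
   features. Stable `device.channel.feature` name registry.
5. **`armsign.classify`** — knn / random_forest / mlp / naive_bayes / svm
   behind a single spec registry, stratified 10-fold cross-validation and
   per-sign train/test splits, with accuracy (%), Cohen's kappa and
   probability-RMSE from the pooled confusion matrix.
6. **`armsign.store`** — plain-text persistence (dictionary.json,
   recordings.jsonl, features.csv), ARFF export/parse-back, model files
   with a feature-registry hash guard.
7. **`armsign.cli`** — the end-to-end command-line application.

## CLI

```sh
# synthesize a labelled dataset (with features) on disk
armsign simulate data/ds --n-signs 80 --reps 10 --seed 1

# synthesize a continuous annotated session
armsign simulate-session data/session.json --n-signs 5 --reps 2 --seed 1

# import a one-word-per-line dictionary (UTF-8)
armsign dict import words.txt --dataset data/ds

# segment a session and record featurized signs (auto-advances the dictionary)
armsign record --session data/session.json --dataset data/ds --auto

# evaluate (10-fold CV or per-sign split) and save a model
armsign train --dataset data/ds --algorithm "random_forest n_trees=100" \
    --model-out model.bin --report-out report.json

# classify each detected segment of a stream
armsign recognize --session data/session.json --model model.bin

# export the feature table for Weka
armsign export-arff --dataset data/ds features.arff
```

Segmenter thresholds are exposed on `record`/`recognize`
(`--emg-threshold`, `--imu-threshold`, `--pause-ms`, `--min-record-s`) or
via `--config config.yaml` with a `segmenter:` mapping.

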