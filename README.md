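# runcoord

Motor-coordination indices for runners, computed from multichannel surface
EMG and shank gyroscope recordings.

The pipeline:

1. **Gait segmentation** (`runcoord.gait`) — running cycles are isolated
   from the tibialis-anterior gyroscope channel: sliding-average smoothing
   with a period-adaptive window, period estimation from the
   autocorrelation function, swing-peak picking, then heel-strike/toe-off
   detection as signal minima between peaks. Each cycle is split into a
   stance and a swing phase.
2. **EMG preprocessing** (`runcoord.emg`) — 4th-order 10 Hz Butterworth
   high-pass plus a Q=30 notch at the mains frequency (50 Hz default), both
   zero-phase.
3. **Symmetry coefficient α** (`runcoord.symmetry`) — per muscle, the
   squared EMG is enveloped by a cubic spline through its local maxima,
   resampled onto a time-normalized per-cycle grid, and the left/right
   envelopes are correlated at the antiphase half-cycle lag. α (%) is the
   mean over muscles.
4. **Stability coefficient K_EMG** (`runcoord.stability`) — per muscle,
   phase and cycle, the shortest window holding ≥ 90% of the phase's EMG
   energy is located; cycle-to-cycle means and population SDs of the window
   energy and of the window/phase duration ratio give two stability
   coefficients `k = (1 − σ/mean)·100`, and K_EMG (%) averages them over
   all muscle × phase combinations.
5. **Reporting** (`runcoord.report`) — merged JSON reports per recording
   and per-stage summary statistics (mean ± sample SD).

A synthetic-data generator (`runcoord.synth`) produces full sessions with
known ground truth (cadence, phase boundaries, burst amplitudes,
cycle-to-cycle jitter, inter-limb asymmetry), so the whole pipeline is
testable without recorded data.

## CLI

```sh
# generate a synthetic 30 s session at 10 km/hr
runcoord simulate --out-dir session/ --seed 1 --sigma-amp 0.05

# analyze a recording (CSV + JSON descriptor -> report JSON)
runcoord analyze --recording session/recording.csv \
                 --descriptor session/descriptor.json \
                 --config config.yaml --out report.json

# aggregate many reports into a per-stage summary CSV
runcoord summarize --reports reports/ --out summary.csv
```

The optional YAML config covers the filter settings, number of cycles,
muscle subset, envelope grid, and side pooling; see
`runcoord.pipeline.AnalysisConfig`.

### Data format

Recordings are wide CSV files (one column per channel, no timestamp column)
plus a JSON descriptor mapping columns to channel metadata:

```json
{"label": "...", "speed_kmh": 10.0,
 "files": [{"path": "recording.csv", "rate_hz": 2000.0, "t0_s": 0.0,
            "columns": [{"name": "emg_rectus_femoris_l", "kind": "emg",
                         "muscle": "rectus_femoris", "side": "left"}]}]}
```

Channels with different sampling rates live in separate CSV files referenced
by one descriptor.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion. One
case is deliberately left failing: the published stage-1 summary mean
(83.09) differs by 0.01 from the mean of its own printed per-athlete
column (83.0838 → 83.08); the implementation reports the honestly computed
value.

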