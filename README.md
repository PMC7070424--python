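# irsring

Simulation and analysis toolkit for an **infrared sensor-ring (IRSR)**
arthropod detector — the kind of opto-electronic light gate mounted on the
cross-section of a trap tube so that every insect, springtail or mite
entering the trap falls through it and shades part of the infrared light
reaching a semicircle of 16 photodiodes.

The package is written for people who design or evaluate such sensors for
integrated pest management and soil-fauna monitoring. It provides:

* **`irsring.geometry`** — the emitter/detector layout of the two ring
  variants (wide 35 mm field for 2–35 mm macroarthropods, narrow 10 mm
  field for 0.1–2 mm microarthropods) and a deterministic ray-sampled
  model of per-channel fractional occlusion.
* **`irsring.fall`** — synthetic 16-channel ADC signals for falling
  objects: free-fall kinematics, two-stage amplifier emulation (15x with a
  ~6.7 kHz bandwidth limit, 5 Hz high-pass, 30x), Gaussian noise, and a
  10-bit ADC at 3.2 kHz per channel.
* **`irsring.detector`** — a bit-faithful integer re-implementation of the
  embedded detection firmware: 32-sample moving-average baseline (10 ms),
  threshold-triggered events (ST = 40 sensitive / ST = 100 robust),
  amplitude summation, and shift-based normalisation by the nearest power
  of two (worst-case error 50%).
* **`irsring.storage`** — the 8 MiB wear-leveled EEProm event store
  (fixed 32-byte records, 262,144 slots: more than 500 detections/day for
  over half a year).
* **`irsring.detectability`** — simulated drop protocols and the binomial
  GLM detectability analysis. Detection (yes/no) is regressed on body
  size with a logit link,

      logit P(detected) = β₀ + β₁·size,      D95 = (logit 0.95 − β₀)/β₁,

  fitted by the package's own IRLS and exposed as a scikit-learn
  compatible estimator (`DetectabilityGLM`), with delta-method standard
  errors for D95.
* **`irsring.cli`** — the `irsring` command: `simulate`, `detect`,
  `experiment`, `fit`, `calibrate`, all driven by YAML configs and a
  master seed, with bit-identical reruns.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

Drop a 0.9 mm grain through the wide ring and run the embedded detector:

```python
import numpy as np
from irsring import (build_ring, FrontEndConfig, ObjectDescriptor,
                     DropParams, simulate_signal, detect_stream, ST100)

ring = build_ring("IRSR1")                      # 35 mm sensing field
grain = ObjectDescriptor(size=0.9)              # opaque 0.9 mm sphere
fe = FrontEndConfig()                           # 3.2 kHz, 10-bit, sigma=8
sig = simulate_signal(ring, grain, fe, DropParams(entry=(3.0, 4.0)), seed=1)
for ev in detect_stream(sig, ST100):
    print(f"channels={ev.channels} n={ev.n_samples} "
          f"raw_sum={ev.raw_sum} amplitude={ev.normalized_amplitude}")
```

prints

```
channels=(6,) n=13 raw_sum=1955 amplitude=122
```

one detection: the grain shaded photodiode 6, thirteen samples (~4 ms)
exceeded the ST = 100 threshold, their summed deviation was 1955 counts,
and the firmware's shift normalisation (divisor 16, the power of two
nearest to 13) reports amplitude 122.

Fitting a detectability curve to a simulated grain protocol:

```python
from irsring import grain_population, run_drop_experiment, fit_detectability

trials = run_drop_experiment(ring, ST100, fe,
                             grain_population(n_per_bin=20, seed=7), seed=7)
fit = fit_detectability(trials)["grain"]
print(f"D95 = {fit.d95:.2f} ± {fit.d95_se:.2f} mm  (n={fit.n_trials})")
```

```
D95 = 0.90 ± 0.08 mm  (n=160)
```

i.e. with the default (calibrated) noise level the wide ring at ST = 100
reaches 95% detectability for grains of about 0.9 mm.

The same experiment from the shell:

```bash
irsring calibrate --variant IRSR1 --st 100 --target 0.9 --out cal.json
irsring experiment --config run.yaml --out results/
```

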