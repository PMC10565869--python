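# bonecc — unilateral bone-conduction crosstalk cancellation, in simulation

When two bone-conduction transducers drive the skull (as in bilateral
bone-conduction hearing aids), each transducer's signal also reaches the
*opposite* cochlea — "crosstalk" — which corrupts the interaural cues
binaural hearing depends on. One remedy borrows the "zone of quiet" idea
from active noise control: put an error sensor near one cochlea (mastoid or
ear canal), estimate a **crosstalk-compensation (CTC) filter** with an
adaptive algorithm, and drive the ipsilateral transducer with an anti-signal
that cancels the contralateral crosstalk at the sensor.

`bonecc` implements that entire workflow as a simulation-first toolkit for
hearing-device and psychoacoustics researchers:

* **signals** — time-stretched pulse (TSP / swept-sine) excitation with an
  exact spectral inverse, deconvolution-based impulse-response measurement,
  band-limited noise, and 3IFC psychoacoustic stimuli;
* **equalization** — Kirkeby regularized inversion
  `C(ω) = conj(T(ω)) / (|T(ω)|² + ε(ω))` with a frequency-dependent
  regularization profile, used to flatten transducer responses over
  200–4000 Hz;
* **synthetic_head** — a seeded generator of plausible skull transfer paths
  (primary `h_RL`: contralateral transducer → sensor; secondary `h_LL`:
  ipsilateral transducer → sensor) and transducer fixtures, plus a virtual
  sensor, so everything runs without hardware;
* **fxlms** — filtered-x LMS estimation of the 512-tap CTC filter `w_RL`
  with the update `w_RL(n+1) = w_RL(n) − μ e(n) s_Rf(n)`, against the
  closed-form Wiener reference `W(ω) = −H_RL(ω)/H_LL(ω)`;
* **verification** — band-limited (224–1122 Hz) noise playback with and
  without the anti-signal, reporting broadband and per-third-octave level
  reductions at the sensor;
* **psychoacoustics** — 2-down/1-up adaptive three-interval forced-choice
  staircases against simulated listeners (logistic psychometric function,
  guess rate 1/3), bracketing audiometry, threshold-improvement and
  occlusion-effect measures.

## Worked example

Run the full pipeline — TSP measurement of the synthetic head, transducer
equalization, FxLMS estimation, verification, and the simulated listening
test — with a 10 s adaptation signal:

```python
from bonecc import RunConfig, FxLMSConfig, run_pipeline

cfg = RunConfig(master_seed=1, fxlms=FxLMSConfig(duration_s=10.0),
                output_dir="out")
summary = run_pipeline(cfg)
```

which prints/returns (abridged):

```json
{
  "reduction_db": 33.19,
  "per_third_octave_reduction_db": {
    "250.0": 33.04, "315.0": 41.44, "397.0": 33.90, "500.0": 32.54,
    "630.0": 26.60, "794.0": 24.36, "1000.0": 31.44
  },
  "equalized_flatness_db": {"left": 0.86, "right": 0.87},
  "fxlms_converged_at_s": 5.152,
  "threshold_improvements_db": {
    "250.0": 11.25, "315.0": 16.5, "397.0": 11.5, "500.0": 11.5,
    "630.0": 9.5, "794.0": 6.75, "1000.0": 12.0
  },
  "mean_threshold_improvement_db": 11.29
}
```

Reading the numbers: the converged CTC filter removes 33 dB of crosstalk
energy in the 224–1122 Hz band at the virtual sensor (well past the 10 dB
working criterion), the Kirkeby-equalized transducers are flat to within
0.9 dB over 200–4000 Hz, adaptation settles after ~5 s, and the simulated
2-down/1-up listening test shows masked-threshold improvements of 7–16 dB
once the sensor-level cancellation is derated (factor 0.35) to model the
imperfect transfer of the zone of quiet from sensor to cochlea. The run
also writes every intermediate artifact (path/filter tap CSVs, error trace,
per-frequency staircase tracks, `summary.json`) into `output_dir`.

The same stages are scriptable from a shell via the `bonecc` CLI
(`make-head`, `measure-ir`, `design-eq`, `fit-ctc`, `verify`, `staircase`,
`pipeline`).

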