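# Methods

This note documents the models, numerical choices and known limitations of
`bonecc`. Everything stated here is computed by the test suite or the
pipeline itself.

## The cancellation problem

Two bone transducers drive one skull. The drive signal of the right
transducer reaches the left-side error sensor through the *primary* path
`h_RL` (transcranial crosstalk); the left transducer reaches the same sensor
through the *secondary* path `h_LL`. A CTC filter `w_RL` applied to the
right-channel signal and played through the left transducer creates an
anti-signal; at the sensor the residual is

    e(n) = s_Rᵀ(n) h_RL + anti_s_Rᵀ(n) h_LL,   anti_s_R(n) = s_Rᵀ(n) w_RL(n)

and the ideal filter is `W(ω) = −H_RL(ω)/H_LL(ω)`. Cancellation is
band-limited by design: the input is white noise band-passed to
224–1122 Hz, the third-octave edges of the 250 and 1000 Hz target
frequencies, because the zone of quiet around the sensor only extends
toward the cochlea at low frequencies.

## Synthetic head model

`generate_paths` draws one set of `n_modes = 6` skull modes — frequencies
uniform in 250–3000 Hz, exponential decay times 1–5 ms — shared by both
paths (same skull), with independent per-mode amplitudes (0.5–1.0, sine
onsets). The secondary path is delayed 0.1 ms, the primary 0.4 ms, and the
primary is scaled to sit exactly 10 dB below the secondary in broadband
energy (transcranial attenuation). Both are truncated to 512 taps
(32 ms at 16 kHz).

Each modal sum passes through a steep causal high-pass
(Chebyshev-II, order 8, 50 dB stopband below 195 Hz) representing the
transducer–skin–skull coupling roll-off: bone-conducted energy below
~200 Hz is physically negligible, and this keeps the measurement chain's
100 Hz high-pass transparent (without it, Lorentzian mode tails put >4% of
path energy below 100 Hz and no sub-1e-3 recovery is possible). The mode
band's lower edge sits at 250 Hz — the cancellation target's lower edge —
for the same reason.

The lower mode-band edge, delays and attenuation are placeholders for
unpublished subject-specific values and are exposed in `HeadConfig`.

`generate_transducer` builds minimum-phase responses (real-cepstrum
construction) from a 200–4000 Hz band-pass magnitude target with seeded
resonance bumps (±3 dB); left/right pairs share the resonance structure and
differ by a perturbation bounded well under 1.5 dB, mirroring a matched
audiometric pair.

What the generator does *not* emulate: nonlinear transducer distortion,
spatially varying sensor placement, physiological noise floors, or any
head-to-head variability beyond the seeded mode draw. Passing tests
demonstrate the algorithms, not fidelity to any individual skull.

## TSP measurement chain

The sweep is the frequency-domain optimized TSP
`H(k) = exp(−j4πmk²/N²)`, `k ≤ N/2`, Hermitian-completed, with stretch
`m = N/4` by default; `|H| = 1` at every bin, so `conj(H)` is an exact
circular inverse. The protocol length is N = 32,728 samples (2.05 s at
16 kHz; the power-of-two 32,768 works identically), played at −20 dB re
1 V RMS with channel onsets at 1 s (left) and 5.1 s (right).

Deconvolution is linear FFT convolution with the inverse sweep. Linear
deconvolution of a circular-inverse pair leaves an aliasing leakage floor
(~7% relative), so `measure_paths_tsp` extracts each response by summing
the three alias windows at offsets `o`, `o+N`, `o+2N` — algebraically equal
to circular deconvolution, hence exact (≈1e−10 relative) when the two
sweeps' windows do not overlap. The protocol onsets space the sweeps 4.1 s
apart, 23 ms less than the 2N + 512 samples needed for full separation;
the resulting overlap contributes a ~5e−4 relative residual, well inside
the 1e−3 end-to-end budget at the default −80 dB sensor noise.

The measurement high-pass is a zero-phase 4th-order Butterworth at 100 Hz
(forward–backward), and analysis band filters are zero-phase Butterworth
as well; noise generation uses a causal order-8 Butterworth band-pass.

## Kirkeby equalization

`ε(ω)` is parametric: `eps_min` strictly inside [f_low, f_high] =
[200, 4000] Hz, `eps_max` outside, raised-cosine transitions over
0.5 octave in log-frequency. Defaults are relative to the response's peak
spectral power (`eps_min = 1e−4·max|T|²`, `eps_max = max|T|²`); the actual
values used in the source measurements are unpublished, so these are the
package's own and are exposed as configuration. The inverse uses
`n_fft = 4096` (≥ 2× the 512-tap responses, avoiding circular wrap) and a
modeling delay of `n_fft/2`, standard for mixed-phase inverses. The
per-bin gain bound `|C| ≤ 1/(2√ε)` holds by construction. Equalized
fixture transducers are flat to <1 dB over 200–4000 Hz (metric:
max−min magnitude after third-octave power smoothing).

## FxLMS

The loop is strictly sample-by-sample: filter output, error, and update
`w ← w − μ_eff e(n) s_Rf(n)` per sample, processed in blocks of p = 512
only for bookkeeping (coefficient-change trace, divergence check). The
secondary-path estimate `c_LL` equals `h_LL` exactly, as in a pure
simulation. The filtered-x signal and the primary-path contribution are
precomputed by convolution since they do not depend on `w`.

Step size: normalized by default, `μ_eff = μ/(‖s_Rf(n)‖² + 1e−8)` with
`μ = 0.02`. The raw (un-normalized) update is retained as an option for
fidelity to the printed rule. The default is set by the *delayed
adaptation* effect: the anti-signal reaches the error through the whole
512-tap `h_LL`, which shrinks the stable range far below the classical
NLMS bound — normalized steps ≥ ~0.05 diverge on the modal fixtures. The
property suite pins the documented stability region μ ≤ 0.02.

Convergence detection: earliest time at which the per-block relative L2
coefficient change stays below 5e−3 for 5 consecutive blocks. With
μ = 0.02 the change plateaus near 2e−3 from gradient noise, so a much
tighter tolerance would never fire; 5e−3 marks the observable "negligible
change" plateau.

Convergence quality at the default settings (10 s of signal): the filter
matches the regularized Wiener solution within 0.5 dB magnitude and
0.1 rad phase per bin over 250–1000 Hz, and removes >30 dB of in-band
crosstalk. Band-limited (colored) excitation makes the last decades of
convergence intrinsically slow (~3 dB per doubling of duration), which is
why the exactly-solvable sanity case (`h_RL = −h_LL`) is exercised on a
memoryless secondary path with μ = 0.5, where it reaches >40 dB in 10 s.

Divergence is declared when a block's error energy exceeds 1e6× the first
block's; the error message names μ as the usual suspect.

## Verification

6 s of band-limited noise drives the primary path alone ("without") and
together with the anti-noise routed through the CTC filter and secondary
path ("with"). Levels are dB re 1 V RMS over the steady-state window
(first/last 100 ms excluded), after zero-phase band-limiting to the
measurement band; both band-limited and broadband levels are reported
since the analysis bandwidth of recorded-level comparisons is a free
choice. Per-third-octave reductions are computed at centers
{250, 315, 397, 500, 630, 794, 1000} Hz from the same two recordings.
A filter is retained after a suspected transducer shift only if its
reduction stays ≥ 10 dB; otherwise the estimation is re-run.

## Psychoacoustics

The 2-down/1-up 3IFC staircase starts at −20 dB re 1 V RMS with 4 dB
steps, halving to 2 dB after the 4th reversal, and stops at 12 reversals;
the threshold is the exact arithmetic mean of the last 8 reversal levels.
Bookkeeping follows the standard transformed up-down conventions: a
reversal is logged at the trial where the prescribed direction flips; the
consecutive-correct counter resets on any incorrect response and on every
level change; the small step applies from the level change that logs the
4th reversal. The staircase converges to the level where
p(correct) = √½ ≈ 70.7%; the suite verifies the mean estimate over 200
simulated runs against that point computed by root-finding on the
listener's psychometric function.

Simulated listeners are logistic: p(L) = γ + (1−γ−λ)·Ψ((L−θ)/σ) with
γ = 1/3 for 3IFC, lapse λ ≤ 0.1, slope σ in dB. Bracketing audiometry
(10 dB down / 5 dB up, threshold = lowest level detected in 2 of 3
presentations, frequencies 250–4000 Hz starting at 1000 Hz) is a yes/no
detection task and therefore uses γ = 0. All randomness is a pure function
of (parameters, seed).

In the end-to-end pipeline the "with cancellation" condition models the
anti-noise as a per-frequency reduction of the crosstalk masker at the
cochlea equal to the sensor-measured third-octave reduction times a
derating factor (default 0.35), capped at the masker's 30 dB sensation
level. The derating encodes the empirical fact that cancellation at the
sensor transfers only partially to the cochlea; it is a configuration
constant, not a fitted quantity. Group-level statistics across human
subjects are out of scope; the module supplies the per-track and pairwise
difference computations only.

## Problem sizes and determinism

Default runs use 16 kHz audio, 512-tap filters and paths, 10–60 s
adaptation signals and 6 s verification noise; the test suite and the
acceptance script use 10 s adaptation, which the convergence measurements
above show is sufficient for the documented tolerances. Every stochastic
stage derives its seed deterministically from a master seed
(`SeedSequence([master, stage_index])`), so a `RunConfig` maps to
byte-identical outputs.

## Known limitations

* No hardware I/O or physical calibration: all levels are electrical
  (dB re 1 V RMS), never SPL/HL or force.
* The head model is modal and linear; no skull FEM, no nonlinear
  (B71-style) transducer distortion — use exponential sweeps, not TSPs,
  if nonlinearity matters.
* Single error sensor, unilateral cancellation only; no bilateral
  (two-sensor) generalization and no closed-form frequency-domain CTC
  design.
* The cochlear-benefit derating is a scalar stand-in for a genuinely
  frequency- and subject-dependent transfer; treat pipeline threshold
  improvements as mechanism demonstrations, not predictions.
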