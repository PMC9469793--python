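# Methods

## The plant: ARX gamma power

The controlled variable is instantaneous RMS gamma power, not the raw field
potential. Modeling power directly keeps the plant linear and scalar and —
because the state vector is simply the last `p` power samples — removes any
need for a state estimator in the loop. The recursion is

    x(t) = −Σₖ aₖ x(t−k) + b_DC·u_DC + b_s·u_s(t) + w(t)

with `x` in µV, inputs in mA, `w ~ N(0, σ_w²)` i.i.d. The package stores
the polynomial `A(z) = 1 + Σ aₖ z⁻ᵏ`; regression coefficients on lagged
outputs are therefore the negated `aₖ`, and `fit_arx` maps signs back
accordingly. Known approximations, inherited by everything downstream: a
linear model of an intrinsically nonnegative, right-skewed quantity can go
negative and has a symmetric noise distribution; stimulation acts purely
through a static gain `b_s` with no frequency dependence.

### The reference process is marginally integrated

The bundled sixth-order reference parameter set (recursion weights
5.6758, −13.6152, 17.6747, −13.0990, 5.2554, −0.8917; b_DC = 3.4689e−4,
b_s = 8.7828e−5, σ_w² = 3.7197e−7) has poles {1.0000, 0.9953 (conj. pair),
0.9688 (conj. pair), 0.9590}: at the stored four-decimal precision the
recursion weights sum to exactly 1, which places one pole exactly on the
unit circle. Realizations therefore drift (the constant input integrates
into a deterministic ramp) the way measured gamma-power baselines do, and
no finite DC steady state exists — `steady_state_gamma` raises a
singular-model error for it. This is deliberate: the identification
benchmarks (tiny normalized a-error, ε*_pred ≈ σ_w², FitPerc ≈ 100%) are
properties of exactly this near-integrated regime, where the signal's
variance dwarfs the driving noise.

Consequences for the API:

- `ARXModel` construction never rejects a parameter set; `simulate_arx`
  refuses only spectral radius > 1 + 1e−9, so marginal processes remain
  simulable while genuinely unstable ones error out.
- Simulation initializes at the no-stimulation steady state when one exists
  (so pre-step records are stationary from the first sample) and at zero
  for marginal plants (no steady state to start from).
- Steady-state, setpoint and closed-loop work uses `demo_plant()`: poles
  {0.96, 0.92, 0.85, 0.7, 0.5, 0.3} with the same published input gains.
  Its small DC denominator (5.04e−5) maps those tiny µV/mA gains onto
  physiologic single-digit-µV mean power (6.88 µV baseline, 10.37 µV under
  a 2 mA step — a 50.6% increase, the ratio implied by the published gains
  regardless of the denominator).

## Identification

The one-step prediction problem `Cv ≈ d` stacks `p` lagged outputs plus the
two exogenous regressors; it is solved by orthogonal decomposition
(LAPACK `gelsy`), with an explicit SVD rank check first. Rank deficiency
raises an error naming the offending columns (pivoted-QR heuristic), and a
condition number above 1e8 triggers a warning before accuracy degrades.
`ε*_pred` is normalized by the record length `N` (not the row count), and
the fit percentage is `100·(1 − ‖Cv*−d‖/‖d−μ_d‖)` — the standard
normalized-error score under which small prediction errors give values near
100%. The residual mean square doubles as the model's noise-variance
estimate.

Cross-validation folds follow trial boundaries (never splitting within a
trial, preserving serial dependence); for each held-out trial the model is
fitted on the remaining trials' stacked design systems. Per-trial fitting
followed by element-wise model averaging is the composite-model path;
averaging stable polynomials can destabilize the mean for orders ≥ 3 (the
stability region is non-convex there — for p ≤ 2 it is a convex triangle,
so destabilization-by-averaging cannot occur), and `average_models` checks
the composite and raises rather than returning an unusable plant.

Excitation: a step input is persistently exciting of order 1. The
diagnostic builds `(1/N)·CᵀC` for the exogenous block and its analytic
limit — nonsingular `[[1,1],[1,2]]` for one stimulus lag (u_DC = 1 mA,
2 mA step), singular for two or more — so step experiments support
consistent estimation only of single-lag stimulus models.

## LQI servo-controller

Augmentation is the canonical one: `z = [x; e_i]`,
`A_aug = [[A, 0], [−T_s·C, 1]]`, `B_aug = [B_s; 0]`, with the reference
entering the integrator row as `+T_s·r` and the constant u_DC channel
treated as a known disturbance through the `b_DC` column (it is not a
control input). The gain solves the infinite-horizon discrete Riccati
problem via `scipy.linalg.solve_discrete_are`, with a value-iteration
fallback (tolerance 1e−12 on successive iterates); the closed-loop spectral
radius is verified < 1. Default weights `Q = diag(0.005·I_p, 100)`, `R = 1`
give sub-second settling on the demo plant's µV scale. The control law is a
plain clamp to [0, 9] mA — amplitudes are physical currents, hence the 0
floor, and 9 mA reflects the charge-density safety ceiling. Optional
conditional-integration anti-windup (freeze the integrator while saturated)
exists but is off by default, so default behavior is the plain clamp.

The 4-second closed-loop protocol runs open loop for t < 0 and engages the
controller at t = 0 with the integrator state zeroed. The command computed
at sample i acts on the same sample's recursion; the controller reads the
last `p` plant outputs directly as its state block. Per-trial Monte-Carlo
seeds derive from the base seed by a counter scheme
(`SeedSequence([base_seed, k])`), so any single trial is reproducible in
isolation.

## Preprocessing

- 60 Hz line removal is a per-record least-squares projection onto one
  sine/cosine pair — zero phase distortion and idempotent by construction.
  Narrow by design; a drifting line frequency is not tracked.
- The stimulation-artifact notch is the smallest odd-tap windowed-sinc
  (Hamming) band-stop meeting ≤ −40 dB across 98–102 Hz and ≥ −1 dB below
  90 Hz at the given rate, applied with reflection padding and group-delay
  compensation so output and input are time-aligned.
- The Morse bank uses symmetry γ = 3 and time-bandwidth βγ = 60; ten peak
  frequencies log-spaced over 30–90 Hz (constant-Q placement — the exact
  discretization behind the original bank is not specified anywhere, so
  this is a documented choice, configurable via `WaveletBankSpec`).
  Responses are exactly zero for f ≤ 0 (analytic). The bank gain is
  calibrated so a unit-amplitude tone at the band center (60 Hz) maps to
  its true RMS, 1/√2; the calibration constant is recorded in the output
  metadata. Filtering is frequency-domain multiplication after reflection
  padding of roughly half the longest wavelet support (≈0.26 s at 30 Hz),
  suppressing boundary transients in 4 s records.

## Trial statistics

Pre/post comparisons are one-sided two-sample t-tests (Welch by default;
pooled available) of the post-onset window against the pre-onset window,
per trial and on the ensemble average, plus the normalized increase
Δγ% = (x̄_s − x̄_ns)/x̄_ns·100. Caveat, reproduced deliberately: samples
within a window are serially correlated for an AR plant, which inflates
the nominal t statistic; the procedure is the standard window test as
practiced, and its type-I calibration is verified under an exchangeable
(independent-sample) null, where it holds 5% ± 2%.

The averaged periodogram uses one non-overlapping Hann window per
2000-sample segment, mean-removed, normalized so white noise of variance σ²
yields a flat estimate at σ² (two-sided density × sampling rate — the same
convention as the model's theoretical PSD
`P(f) = (σ_w² + 4 b_s²/ω²)/|A(e^{jω})|²`, which excludes f = 0 where the
step term diverges). Measured agreement for reference-process ensembles is
≈1.7–1.9 dB median absolute log-deviation over 0–100 Hz.

## Synthetic data

The generators define the study conditions: 4 s records at 500 Hz, ten
trials per ensemble, u_DC = 1 mA, a 2 mA step at the record midpoint, and
the published reference parameters above.

- `make_ma_process` is the order-selection negative control: an order-29
  moving average of the same Gaussian noise class (30-tap Hann windowed-sinc
  lowpass, 1.25 Hz cutoff), tap scale matched to the stochastic-part
  variance of reference realizations (median over five fixed probe seeds),
  direct-feedthrough DC gains matched to the noise-free reference window
  means. Its sub-5 Hz spectral dominance mirrors the reference process, but
  the reference realization's lowest-frequency periodogram bins are ramp-
  leakage-dominated and fall far faster than any MA(29) response — the two
  spectra agree in character and total low-frequency power, not bin by bin.
- `synth_ieeg_trials` is deliberately a plain sum of components (broadband
  background, amplitude-modulated gamma burst with a post-onset envelope
  gain, 60 Hz line, post-onset 100 Hz artifact). It exercises the
  preprocessing chain; it does not emulate 1/f spectra, cross-frequency
  coupling, or electrode physics, so passing tests say the chain recovers
  injected effects, not that it is validated on real iEEG. The default
  burst carrier (45 Hz) sits away from the 60 Hz line so the line notch
  removes only contamination.

All generators are deterministic given their seed.

## Problem sizes and numerical choices

Test and benchmark runs use the protocol's native sizes (2000 samples,
10-trial ensembles); Monte-Carlo summaries use 20–100 trials and the
benchmark medians 20–50 seeded runs — enough to stabilize the medians of
heavy-tailed statistics like the input-gain error, whose single-run values
spread over more than two decades. Numerical-rank thresholds follow the
standard convention (machine epsilon × largest dimension × leading singular
value). Time stamps place t = 0 at the stimulus onset; the "post-settling"
metric window is the final second of a run, reported alongside the full
post-onset window so settling transients cannot masquerade as steady-state
error.

## Known limitations

- Single-channel, linear, amplitude-only control: no stimulation-frequency
  dimension, no multichannel montage, no artifact rejection heuristics.
- Per-subject empirical results from intracranial recordings cannot be
  reproduced without those recordings; the package reproduces the
  computational procedures and the published synthetic benchmark.
- The reference process's exact unit root makes any quantity that divides
  by `1 + Σ aₖ` undefined for it; use `demo_plant()` (or any identified
  stable model) where steady states matter.
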