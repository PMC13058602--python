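# Methods

`padbp` implements and validates a bed-pad blood-pressure (BP) pipeline:
capacitive chest/leg sensor signals are processed into hemodynamic features,
a small neural network maps those features to systolic and diastolic BP, and
a statistical battery quantifies agreement with a reference. Because the
underlying human recordings are not publicly distributable, the package
ships a forward simulator whose ground truth makes every stage falsifiable.
This note records the model, the defaults, and the design choices that were
genuinely open.

## Forward model (synthcap)

The sensing physics is summarised as three serially coupled capacitance
sources (electrode, contact pressure, deep-tissue permittivity): contact
vibrations and blood-volume changes both modulate the measured capacitance,
in different frequency bands. The simulator honours this as additive signal
components rather than a field simulation:

* **Chest slow band (<0.5 Hz).** Intrathoracic blood volume is proxied by
  mean arterial pressure, `MAP = DBP + (SBP − DBP)/3`. The component is
  `volume_coupling · (MAP(t) − MAP(0))` (default 0.02 pF/mmHg), low-passed
  at 0.4 Hz, plus a respiratory sinusoid at `resp_rate` = 0.2 Hz with
  0.15 pF amplitude.
* **Chest BCG band (1–10 Hz).** One I–J–K complex per heart beat, built
  from three Gaussian lobes: J (+1, σ = 20 ms), I (−0.45, 40 ms before J,
  σ = 18 ms) and K (−0.45, 40 ms after J). The I and K troughs are
  symmetric about J so that window-level cross-correlation against the
  symmetric leg pulse lobe peaks at the true transit lag; the 40 ms I–J
  interval sits inside the physiological 20–60 ms range. J amplitude
  defaults to 0.30 pF.
* **Leg pulse.** A single Gaussian lobe (σ = 30 ms, 0.25 pF) per beat,
  delayed from the J peak by the pulse transit time (PTT), plus a slow
  component at 0.25× the chest amplitude (the chest sees stroke volume,
  the leg only peripheral pulse volume).
* **PTT law.** `PTT = a/√MAP + b` with default `a = 1.932 s·√mmHg`,
  `b = 0` (≈200 ms at 120/80, ≈ −1 ms/mmHg sensitivity), clamped to
  0.05–0.40 s. The literature only asserts an inverse PTT–BP relation; the
  inverse-square-root form is a simulator convention, recorded in the
  ground truth so recovery tests are exact. On top of the law, a slow AR(1)
  "vasomotor tone" jitter (`ptt_tone_sd` = 8 ms, 30 s correlation time) is
  added per beat. This is deliberate: transit time in vivo is confounded by
  vascular tone, so part of the BP information travels only through the
  volume channel. It is what makes the mean-ΔC feature genuinely
  informative beyond PTT in end-to-end experiments.
* **Heart rate.** Baseline 62 bpm, +0.15 bpm/mmHg of MAP deviation, plus a
  3 bpm sinusoidal modulation at 0.1 Hz so the low-frequency
  heart-rate-variability (LF HRV) feature is non-degenerate. Beat times
  integrate the instantaneous rate.
* **Channels, noise, artifacts.** Each pad has 4 channels sharing the clean
  signal with per-run gains drawn from U(0.8, 1.2), independent white noise
  (`noise_sd`, default 0.018 pF), and optional body-shift artifacts:
  persistent steps of `artifact_amplitude` (default 0.8 pF) at Poisson
  times. The default noise is calibrated so the chest-pad spectral SNR is
  ≈12, the scale reported for the real pads.
* **Protocol.** The BP trajectory mimics the supine maneuver protocol: a
  baseline lead-in, 20 s Valsalva strains (15 mmHg dip, 18 mmHg release
  overshoot), 30 s isometric handgrip (linear +25 mmHg ramp), and 60 s
  rests with 15 s exponential relaxation. DBP follows systolic
  perturbations at half amplitude. With no maneuvers the trajectory is flat.

The default sample rate is 100 Hz — ten times the upper BCG band edge; no
acquisition rate is published for the real system, so this is a convention.
All randomness flows through one seeded generator; identical seeds yield
bit-identical recordings.

### What the simulator does not emulate

Real pads see posture changes, electrode drift, contact-pressure
nonlinearity, inter-subject BCG morphology differences, and reference-cuff
error; the simulator has none of these. Passing recovery tests therefore
demonstrates that the *pipeline* is correct and self-consistent under the
stated forward model — not that the method achieves any particular accuracy
on human data. The out-of-fold correlations on synthetic cohorts are upper
bounds, inflated by the clean link between MAP and both feature channels.

## Signal processing (sigproc)

Per channel: db4 wavelet decomposition to level 2 with soft universal
thresholding (σ√(2 ln N), σ from the MAD of the finest detail band), then
Savitzky–Golay smoothing (order 4, 15 samples — the window unit is a
convention, the source does not state one). Band separation uses order-4
Butterworth filters applied forward–backward (1–10 Hz band-pass for BCG,
0.5 Hz low-pass for the volume band). Zero phase is mandatory, not
cosmetic: PTT is a timing measurement, and any group delay would bias it.
The band-passed output has its residual DC removed so the BCG band is
exactly zero-mean.

Artifact rejection combines two criteria over 1 s windows: (a) a >0.5 pF
range of the 0.3 s-median-filtered baseline (body-shift steps; the median
prefilter stops ~0.1 s-wide cardiac lobes from masquerading as shifts while
passing true steps unattenuated), and (b) mean pairwise inter-channel
Pearson correlation < 0.5 (contact loss / phase misalignment; correlation
is phase-sensitive at these time scales). Invalid spans are dilated by one
window on each side. The correlation threshold and window are conventions —
the source states neither — and are exposed as parameters. Channels are
fused by a masked mean; invalid samples propagate as gaps. Windows
downstream are dropped when more than 20% of their samples are invalid.

The SNR statistic is the FFT power inside the physiological bands
([0, 0.5] ∪ [1, 10] Hz, DC excluded) over the power elsewhere up to Nyquist.

## Feature extraction (features)

Two windowings: disjoint 40 s windows at cuff-cycle anchors (intermittent
mode) and half-open 10 s windows sliding in 5 s steps (continuous mode).

Beat detection weights the band-passed signal by its smoothed (0.1 s
moving-average) Hilbert-envelope magnitude, then selects peaks with a
minimum distance of 0.4× the running median beat interval (seeded at
60/hr_prior, refined in a second pass, clamped to the 30–180 bpm range) and
an amplitude floor of 0.3× the typical beat amplitude. The floor acts in
linear signal units (using the envelope's 95th percentile as the typical
amplitude) so a half-amplitude beat is retained while filter ringing and
noise are not. The I trough is the most prominent minimum within 0.15 s
before each J peak; the detector does not label the rest of the BCG complex.

PTT is estimated two ways and cross-checked: the argmax of the windowed
chest-BCG × leg cross-correlation restricted to physiological lags
(0.05–0.40 s, preventing lock-on to the next beat), refined by parabolic
interpolation; and the median per-beat delay from each leg peak to its
nearest preceding J peak. Disagreement beyond 0.05 s, or a correlation peak
on a lag bound, invalidates the window. PWV = pad_spacing / PTT exactly.

HR is 60 over the mean J–J interval. LF HRV integrates the 0.004–0.15 Hz
band of the unevenly sampled beat-interval series via Lomb–Scargle; raw
periodogram ordinates are used as relative weights and the interval
variance (ms²) is distributed across the 0.004–0.4 Hz grid, so the band
power has exact ms² units and a sinusoidal modulation of amplitude A ms
yields ≈A²/2. Windows shorter than 30 s inherit the LF HRV of the full
recording. Mean ΔC is the window average of the fused chest low-frequency
band minus the recording's resting baseline (median of the first 10 s);
fusing all chest channels was chosen over picking the single best-SNR
channel ("near the heart" is ambiguous) because fusion is what the BCG path
already uses.

## BP estimation (bpnet)

Inputs per window: mean ΔC, PWV, HR, LF HRV, I–J interval, age, and a
one-time baseline cuff reading for the target (calibration is mandatory).
Separate multilayer perceptrons per target: 16–8–4 hidden neurons
(intermittent) or 128–32–16 (continuous), ReLU activations, linear output.
The network, backpropagation and Adam are implemented directly on numpy —
the composite loss cannot be expressed in stock regressors and the models
are small enough that full-batch training takes seconds.

The loss is

```
L = MSE + λ_grad · mean[(Δpred − Δref)²]
        + λ_mono · mean[relu(−(p_i − p_j)(PWV_i − PWV_j))]
        + λ_l2 · ‖W‖²
```

with defaults λ = (0.5, 0.1, 10⁻⁴). The gradient term runs over consecutive
same-subject windows (matching temporal BP changes, not just levels); the
monotonicity hinge runs over within-batch pairs and penalises predictions
that fall while PWV rises, encoding the physiological direction of the
transit-time law. The penalty forms are this package's reading of
"gradient" and "monotonicity" penalties; they are swappable and their
analytic gradients are verified against finite differences in the tests.
Training: Adam at 10⁻³ for up to 500 full-batch epochs, early stopping on a
seeded 10% validation split (patience 50), inputs z-scored with
training-fold statistics (zero-SD columns guard to 1), targets standardised
internally and mapped back to mmHg.

Cross-validation is a seeded 10-fold split with re-initialisation per fold;
every window is predicted exactly once out-of-fold and each fold's scaler
sees only its training rows. The default split is window-level random; a
subject-grouped split is available (`split="subject"`) because window-level
splitting lets subject identity leak into accuracy for continuous data —
neither mode is endorsed as "correct". Permutation importance shuffles each
feature column 20 times (seeded), averages the RMSE increase, and
normalises by the maximum so the top feature scores exactly 1.

## Evaluation statistics (evalstats)

Agreement: Pearson r, mean error, mean absolute error, the sample SD of
errors, and Bland–Altman 95% limits of agreement ME ± 1.96·SD (reported at
1 decimal in mmHg, 2 decimals for r and MSC). Baseline-offset-removed
correlation subtracts each subject's baseline from both series before
correlating, exposing models that predict only the calibration value.
Concordance is the fraction of consecutive steps in which a feature moves
in the same direction as reference BP, ties excluded.

Wavelet coherence uses an analytic Morlet (ω₀ = 6; pywt `cmor2.0-0.9549`),
periods from 4·dt to a third of the record at 12 voices per octave, with
time smoothing by a half-scale Gaussian and scale smoothing by a 0.6-octave
boxcar. MSC = |S(W_xy/s)|² / (S(|W_x|²/s)·S(|W_y|²/s)) is bounded in [0, 1]
and exactly 1 for self-coherence; the cone of influence (e-folding time
√2·s) is masked before the summary statistic, the time-mean of each
column's maximum MSC. The smoothing widths and the optional pointwise
AR(1)-surrogate significance mask (off by default) are conventions — the
source names only "wavelet coherence".

The bootstrap permutes the estimated mean-BP window series (whole windows,
destroying temporal order), recomputes the average maximum MSC 100 times,
and reports z = (observed − null mean)/null SD against the 1.96 threshold.
On independent white-noise series the null is calibrated (|z| < 1.96 in
≥90% of seeded replicates); on smooth, strongly autocorrelated series the
shuffle null is conservative in the usual way.

## Problem sizes and numerical choices

Recovery experiments use 60–120 s single-subject runs and an 8-subject ×
300 s cohort (two maneuvers per subject, ~470 valid windows) — large enough
for stable fold statistics while keeping the full suite and the acceptance
script fast. Degenerate inputs are handled explicitly: zero-variance series
yield NaN correlations with a warning, constant scaler columns guard to 1,
all-invalid fusion raises, fewer than 10 windows degrade to leave-one-out
cross-validation, and an all-tie concordance is undefined rather than 0.5.

## Known limitations

* The simulator's BP→feature links are cleaner than physiology; synthetic
  accuracies exceed anything attainable on real subjects and should be read
  only as pipeline-correctness evidence.
* The intermittent mode anchors 40 s windows by tiling when no cuff-cycle
  times are supplied; real cuff cycles are irregular.
* The shuffle bootstrap's null ignores autocorrelation in the estimate
  series; z-scores on slow signals are anti-conservative relative to an
  AR-matched surrogate null (the optional AR(1) mask addresses the map,
  not the summary z).
* No side-lying posture, no real-time processing, no formal ISO 81060-2
  grading.
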