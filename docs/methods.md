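# Methods

This note documents the models behind `optopair`, the reasoning for the
defaults, and what the synthetic-data generators do and do not emulate.

## Photocycle model

Each opsin is a three-state kinetic scheme over occupancies C (closed),
O (open) and D (desensitized), C + O + D = 1:

```
dC/dt = -k_a C + (1/τ_off) O + k_recov D
dO/dt =  k_a C - (1/τ_off + k_d) O
dD/dt =  k_d O - k_recov D
```

* **Activation** `k_a = σ_eff · s(λ) · Φ(P, λ)` is linear in photon flux
  Φ = Pλ/hc; simultaneous light sources of different wavelengths add their
  rates. There is no microscopic saturation — the macroscopic response
  saturates only through O → O_ss → 1, which matches the observation that
  responses keep growing up to 20 mW/mm² for several of the channels.
  `σ_eff` is parameterized through the opening rate at a reference
  condition (10 mW/mm² at the peak wavelength), which is the irradiance
  used in most whole-cell characterizations.
* **Spectrum** `s(λ)` is a single Gaussian in wavenumber (the standard
  rhodopsin nomogram surrogate), equal to 1 at the peak. Widths for the
  potassium channels are calibrated (Brent root-finding on the two-state
  steady-state closed form) so that the simulated long-pulse peak ratios
  reproduce the measured 590-nm response fractions (HcKCR1: 73 % of
  530 nm; HcKCR2: 9 % and WiChR: 27.6 % of 470 nm). The ZipACR-family
  widths (1250 cm⁻¹, with I151V narrower at 1200 and I151T wider at 1300)
  encode the measured ordering — I151T is the red-shifted variant — and
  are otherwise model choices.
* **Desensitization** `k_d` scales with the spectrally weighted photon
  flux relative to the reference condition, so dimmer or off-peak light
  desensitizes proportionally less. Recovery `k_recov` is light-
  independent.
* **Conducting photointermediate.** For Chrimson-family channels the
  D state retains a fraction `g_desens_frac` of the open-state
  conductance. This represents the long-lived conducting intermediate
  that gives red-shifted ChRs their slow residual current, most prominent
  under blue illumination. It is essential to the offset-spike
  phenomenon: with a strictly non-conducting D state and a single
  wavelength-independent τ_off, the cation conductance (τ_off 5.6 ms)
  would always decay faster than the anion conductance (9.5–20.2 ms),
  the shunt would outlive the drive, and no light-offset spike could ever
  occur — contradicting what is observed in co-expressing granule cells.
  Anion channels have `g_desens_frac = 0` and reduce to the classical
  three-state scheme.

Membrane current is ohmic, `I = g_scale · g_unit · (O + f_D D) ·
(V − E_rev)` (nS · mV = pA). Occupancies are propagated exactly — eigen-
decomposition of the rate matrix per piecewise-constant light segment,
with a matrix-exponential fallback if the eigenbasis is ill-conditioned —
so integration error is set by the sampling grid, not the solver
(halving dt changes final occupancies by < 1e-4).

### Opsin parameter table

Measured values carried by `builtin_opsin_table()`: off-τ (ms) IvfChr 5.6,
C-ChrimsonR-ts 21.5, ZipACR 9.5, Zip151V 15.5, Zip151T 20.2, GtACR2 161,
RsACR_995 122.7, RlACR_477 95.8, HcKCR1 49.7, HcKCR2 58.6, WiChR 229.3;
E_rev (mV) ZipACR family −39.0 (high-chloride whole-cell conditions),
HcKCR1 −58.0, HcKCR2 −50.7, WiChR −65.2; spectral peaks (nm) ZipACR 515,
Chrimson family 585, HcKCR1 530, HcKCR2/WiChR 470. The cation-channel
reversal potential is set to 0 mV — an assumption, not a measurement.
Rate scales (`σ_eff`, `k_desens`, `k_recov`, `g_desens_frac`) are model
defaults chosen once so that the simulated cells jointly exhibit the
qualitative phenomena that define the pairing (below); they are not
per-experiment dials.

## Neuron model

A single-compartment leaky integrate-and-fire cell (c_m 30 pF, g_l 3 nS,
E_l −70 mV, threshold −50 mV, reset −65 mV, refractory 2 ms; τ_m 10 ms,
granule-cell-like) held at −60 mV by a solved constant bias current.
Opsin conductances are computed first (they do not depend on V) and the
membrane equation is stepped with forward Euler at 25 µs. Optional white
current noise (per-step SD in pA) makes runs stochastic; the default is
deterministic. This is deliberately the smallest model exhibiting
shunting block and rheobase; it has no spike shape, adaptation, or
dendrites.

**Chloride reversal in neurons.** Pairing cells built by
`standard_pairing` override the anion channel's E_rev to −70 mV, the
somatic chloride reversal under physiological (K-gluconate-like)
conditions. The −39 mV table value is a high-chloride HEK measurement;
inside the LIF model a conductance reverting above threshold is net
excitatory at *every* magnitude (the steady-state voltage
(g_l E_l + I + g E_rev_a)/(g_l + g) then always exceeds −50 mV), so
shunting block would be impossible — as it would be in a real neuron with
that chloride gradient.

**Calibrations.** Rheobase is found by bisection to 1 pA; the blocking
conductance is the minimal ACR g_scale (1 % bisection) for which fully
overlapping 5-ms 470-nm pulses at 4 mW/mm² abolish every targeted spike
in the 40-Hz injection protocol, with the drive current fixed at 1.5×
the 5-ms-pulse rheobase (absolute drive currents are cell-specific in
real recordings and are not modeled). Recovery intervals are measured
light-offset → current-onset.

**Default conductances.** The pairing cell uses g_scale 0.8 for the ChR
and 2.0 for the ACR (scale unit g_unit = 10 nS). Together with the
Chrimson defaults (k_desens 0.3 ms⁻¹ at reference flux, k_recov
0.01 ms⁻¹, conducting-D fraction 0.35) and ZipACR's k_desens 0.06, these
were fixed once, by a coarse grid search over the joint qualitative
battery, and then frozen:

* 10-Hz red drive (5-ms, 7 mW/mm² 635 nm) of the Zip151T pairing evokes
  exactly one spike per pulse; the same protocol at 470 nm (4 mW/mm²)
  and 10-ms blue pulses up to 10 mW/mm² evoke none.
* 500-ms blue light on the ZipACR pairing produces no spike during the
  pulse and a spike within 15 ms of light offset (the net light-evoked
  current turns inward before offset as the ACR desensitizes and the
  conducting ChR intermediate accumulates); the Zip151T pairing produces
  no spike at all at identical conductances.
* Calibrated blue blocking is 100 %, red blocking 0 %; co-illumination
  (470 + 635 simultaneously) evokes nothing.
* Recovery thresholds are ordered in ACR off-τ (10 ms at τ 15.5, 20 ms
  at τ 20.2, unrecovered within 20 ms at τ 161), and the 161-ms
  surrogate remains fully suppressed 10 ms after light offset.

Known limitation: at these conductances the ChR-alone cell does not reach
threshold under blue drive (real IvfChr neurons do); the model
underestimates Chrimson's blue-evoked depolarization relative to its red
one. None of the pairing conclusions depend on this. Recovery in the
model is also slower than the measured < 5 ms for the I151T pairing: a
hard-threshold LIF needs a larger safety margin of shunt to block an
overlapping pulse than a real neuron with conductance-based spike
initiation, and that margin takes longer to decay. The asserted ordering
across variants is unaffected.

## Photocurrent analysis

Off-decays are fitted as A·exp(−t/τ) **to a zero baseline** with
Levenberg–Marquardt least squares (tolerance 1e-10, ≤ 2000 evaluations);
the initial τ comes from the 1/e crossing, the fit window defaults to 5×
that initial estimate (capped at the trace end). A free-baseline variant
exists but is non-default. Non-convergence sets `converged=False` rather
than raising. Rises are fitted as I_ss·(1−exp(−t/τ)). Peak detection
subtracts a 50-ms pre-light baseline. Action spectra are normalized
within each cell by that cell's maximum absolute response before
averaging, making the group curve invariant to per-cell expression gain.
Ramp reversal potentials subtract a light-off leak ramp when provided and
locate the zero crossing by a local straight-line fit through the
smallest-|I| samples (5 % of the ramp), which is robust to additive
recording noise.

Recovery performance (2 % amplitude noise, τ ∈ [2, 300] ms, 200 decays):
median relative error ≈ 0.1 %, bias < 0.01 %; reversal potentials within
0.1 mV at 1 pA ramp noise.

## Whisker pipeline

The generator renders whiskers as anti-aliased bright line segments
(intensity 200/255, length 40 px) rotating about fixed pivots on a dark
background at 750 fps, adds Gaussian pixel noise (default SD 8 on the
8-bit scale), and returns per-frame ground-truth angles. Light-evoked
responses are protraction transients A·(1−e^{−t/20 ms})·e^{−t/150 ms}.
It emulates the geometry and sampling of a head-fixed high-speed whisker
video; it does **not** emulate whisker curvature, occlusions, crossing
whiskers, identity switches, illumination drift or camera artifacts — so
a passing tracker here demonstrates angular accuracy on well-isolated
straight whiskers, not robustness to real-world clutter.

The tracker thresholds each ROI at the Otsu level, skeletonizes, fits all
skeleton pixels by total least squares, and only if the RMS residual
exceeds 0.75 px falls back to a RANSAC consensus search (32 candidate
pairs, 1-px inlier distance) before re-fitting the inliers. "The slope of
the line" is interpreted as the TLS direction angle arctan in degrees,
mapped to (−90, 90], which avoids the infinite-slope singularity near
vertical. Frames with fewer than 10 candidate pixels are flagged missing,
never silently interpolated. Typical accuracy: RMSE ≈ 0.5° at noise SD 8,
independent of the absolute angle.

Scoring: per whisker, d(t) = |θ(t) − μ_baseline|; Z(t) standardizes d
against the baseline mean and sample SD (ddof 1) of d — the d-based
reading of an ambiguous convention, documented here; whisker Z-traces are
averaged pointwise ("averaged Z-score"; averaging angles first is
available behind a flag). AUC = Z̄ × W with the fixed window W = 200 ms
from light onset, expressed in seconds (units Z·s); a fixed window is
used in preference to a response-duration window. The baseline is the
500 ms preceding onset by default (trials arrive every 3 s at 0.33 Hz);
the group experiments in this package use a 300-ms baseline and 300-ms
post-onset segment per trial, 3 whiskers and 4 animals × 3 trials per
wavelength — sizes chosen to keep a full ten-seed two-group replication
comfortably inside a desktop run while leaving > 200 baseline frames per
trial.

Because absolute AUC magnitudes depend on the unit convention for W, only
AUC *ratios* (450 nm / 638 nm within animal) are compared across
conditions; the control group's built-in blue/red response amplitude
ratio (10°/15° ≈ 0.67) is recovered as a group ratio ≈ 0.65, while the
suppressed condition (0.5° blue response) yields ratios ≈ 0.

## Statistics

Unpaired comparisons default to Welch's unequal-variance t-test (with
Welch–Satterthwaite degrees of freedom); within-cell wavelength
comparisons use the paired t-test. Identical groups return t = 0, p = 1
by convention.

## Seeds and determinism

All stochastic components consume an explicit seed or Generator. The
experiment runner derives named substreams from a single config seed via
`SeedSequence(seed, crc32(name))`, so runs are reproducible and
independent stages are decoupled; noise-free simulations are bit-exact
across repeats.
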