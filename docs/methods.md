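# Methods

## The measurement being modelled

A 27-laser solid-state near-infrared spectrometer is pressed against a
gelatin/Intralipid/water phantom and collects diffuse-reflectance spectra over
the first overtone of the water O–H stretch while the phantom is stepped
through five temperatures between 20 and 24 °C (the gelatin matrix liquefies
above 24 °C). Each laser is pulsed in an off–on–off pattern; 99 % of its power
goes to the sample, 1 % to an internal reference photodiode. A wire thermistor
1–2 mm below the surface logs the matrix temperature. Seven phantoms with
different constituent fractions provide seven distinct sample matrices; each
runs a unique permutation of the five set points, 20 min per step, twenty 10-s
recordings per step at 15.7 Hz (157 modulation cycles per recording), giving
7 × 5 × 20 = 700 recording-level spectra.

Temperature information enters through the water band's blue-shift on warming;
the calibration task is to invert it with a linear multivariate model that
tolerates phantom-to-phantom differences in composition and interface coupling.

## Synthetic data generator

The real instrument's wavelengths and data are proprietary, so the package
carries a generator that reproduces the *statistical structure* the analysis
depends on, not the radiometry of any physical device.

**Spectral forward model.** On an even 27-point grid from 1350 to 1590 nm, the
noise-free absorbance of a phantom at temperature T is

    A(λ, T) = w·a_w·[(1 − φ)G(λ; 1460, 45) + φ·G(λ; 1412, 45)]
              + g·a_g·G(λ; 1510, 35) + s·IL·(λ_max − λ) + δ_p

with G a unit-height Gaussian, w and g the water and gelatin weight fractions,
IL the Intralipid weight-percent, and

    φ(T) = clip(0.5 + r·(T − 22 °C), 0, 1).

The two-Gaussian weight exchange is the simplest closed form that produces a
blue-shift with an isosbestic-like crossing; r = 0.02 /°C puts the temperature
signal (≈ 5×10⁻³ A/°C at the cold-band centre) near the scale implied by the
kind of sub-0.3 °C errors such instruments report. Water and gelatin
absorptivities default to 1.0 and 0.3 per unit weight fraction; the scattering
baseline slope is 5×10⁻⁵ A/(nm·IL-%), a gentle Intralipid-dependent tilt
(~0.12 A across the grid at 10 % Intralipid). δ_p ~ N(0, 0.02 A) is a flat
per-phantom offset standing in for interface/placement variability. None of
these constants is measured; they are design choices made once (the instrument
noise magnitude is nowhere published).

**Raw streams.** A modulation cycle is 84 detector samples: 27 off–on–off
triplets plus three trailing dark samples. Per recording, the sample channel's
on-signal is g_s·(1−f)·P·drift·10^(−A) and the reference channel's is
g_r·f·P·drift, with f = 0.01 the reference split, common-mode drift
1 + N(0, 5×10⁻³) per recording, dark level 0.01 everywhere, and additive
Gaussian noise of relative amplitude 10⁻³ per channel. Optional
interface-instability events add a flat absorbance offset over a contiguous
block of recordings. Randomness is split per phantom from the master seed
(`SeedSequence([seed, phantom_id, ...])`), so adding a phantom never changes
another phantom's stream.

**Thermal model.** The phantom temperature relaxes toward each Peltier set
point as a first-order system, T(t) = T_set + (T_entry − T_set)e^(−Δt/τ), with
τ = 300 s and a 22 °C ambient start; the trace is continuous across step
boundaries and sampled every 5 s as the thermistor log. Within a 10-s
recording the temperature is treated as constant at its mid-time value (the
drift within 10 s is < 0.15 °C/τ·10 s ≈ 5 mK at the largest swing, far below
every other error source).

**What the generator does not emulate.** Radiative transfer and photon
migration (the scattering baseline is a deterministic tilt, not a transport
model), refractive-index effects, wavelength-correlated (pink) noise,
drift *within* a recording, thermistor self-error, or spectrally structured
interface artefacts (events are flat offsets). Consequently, passing tests
demonstrate the correctness and robustness of the *analysis chain* under a
plausible data-generating process — not instrument performance on real tissue.

## Signal chain

Per laser, V = V_on − mean(V_off1, V_off2); the three trailing dark samples of
a cycle enter only a dark-level diagnostic. The dark-corrected reference is
multiplied by (g_s/g_r)·((1−f)/f) to estimate the incident sample-path power
("air reference"), and A = −log₁₀(V_sample/V_ref,corrected). Because drift and
laser power multiply both channels identically, absorbance is exactly invariant
to them — asserted to 1e−10 in tests. The 157 per-frame absorbance spectra of a
recording are combined by arithmetic mean (median available via `stat=`);
averaging after the log is the variance-minimising choice at these noise levels
and keeps one spectrum per recording, matching the 20-spectra-per-step
bookkeeping. Non-positive intensities abort the recording with an error naming
the laser, rather than being clipped: detector faults should be visible.
Temperatures are assigned by linear interpolation of the thermistor trace at
the recording mid-time; no extrapolation outside the trace span.

## Screening

PCA (column-mean-centred SVD) is run on the raw recording-level spectra with no
other pre-processing. Score–temperature regressions per phantom quantify
temperature sensitivity (slope), between-phantom offsets (intercepts — both the
plain variance of the seven intercepts and variance/|mean| are reported, since
"relative variance" admits either reading), and within-phantom linearity (R²).
Score–composition regressions relate components to gelatin/Intralipid/water
content; the constituent design itself is strongly collinear (gelatin–water
R² = 0.98), which limits how well composition effects can be attributed.

Interface-instability outliers are flagged automatically (the original analysis
boxed them by hand, which is not reproducible): per phantom and per component
2–4 — where instability jumps are most visible — a least-absolute-deviation
line of score on temperature is fitted by 20 IRLS iterations and points with
|residual| > 5×MAD on any component are flagged. Two numerical guards: if
MAD = 0 with nonzero residuals the criterion falls back to the standard
deviation (with a warning), and the residual scale is floored at 10⁻⁵
(absorbance units) so that numerically or physically negligible structure —
e.g. the sub-mK curvature left by interpolated temperature assignment on
noise-free data — is never flagged. A contiguous event block must be a minority
of a phantom's recordings for the robust line to reject it; at the study
cadence (100 recordings per phantom) blocks up to a few dozen recordings are
handled. Manual per-phantom index lists can augment or replace detection.
Masking is non-destructive: the original table is kept and the report records
the criterion.

## Calibration model

PLS1 by NIPALS with deflation; for a single response the inner loop is exact in
one pass. The regression vector is b = W(PᵀW)⁻¹q. A weight vector with norm
below 10⁻¹⁰ (relative) means the residual response is orthogonal to the
spectra and raises a rank error.

Prediction always follows ĉ = (A − Ā_cal)·b + c̄_cal with the *pooled*
calibration means, so an unseen phantom needs no phantom-specific statistics.

**Centring.** Two training-centring modes exist. `pooled` (default) subtracts
the grand calibration mean; `per_phantom` subtracts each phantom's own mean
spectrum. The default is pooled, for a structural reason: with per-phantom
centring the training matrix contains no between-phantom variance at all, so
the fitted vector is the pure temperature-signature direction and retains full
sensitivity to flat interface offsets and composition differences — on the
default synthetic conditions this inflates held-out-phantom biases to ~1 °C.
Pooled centring leaves those directions in the training data; the extra latent
variables (AIC selects h = 4 on default data) span them, and the regression
vector becomes nearly orthogonal to them, which is precisely what
generalisation to an unseen phantom requires. It is also the centring that the
prediction equation itself uses. Temperatures are always centred by the pooled
calibration mean.

**Model order.** h is the only optimised parameter, chosen by
leave-one-phantom-out cross-validation on the calibration set: for h = 1..10
each phantom is left out, the model is refit (re-centred) on the rest, the
left-out spectra are predicted, and PRESS(h) accumulated. Then
AIC(h) = n·ln(PRESS/n) + 2(h + 1) is minimised; the +1 counts the intercept,
consistent with the n − h − 1 degrees of freedom of the SECV. Ties break to the
smaller h, and PRESS/n is floored at 10⁻¹² °C² inside the log so that curves at
the numerical noise floor resolve to the most parsimonious model instead of
chasing rounding noise. If h exceeds what the smallest training fold can
support, the curve is truncated with a warning.

**Evaluation strategies.**
*Step split*: the first three temperature steps of every phantom (in each
phantom's own acquisition order) form the calibration subset, the last two the
prediction subset — a short-horizon extrapolation test. SECV and the
calibration-side fit come from the cross-validated predictions at the selected
h; SEP/RSEP/R²/bias/slope/intercept from the prediction subset.
*Leave-one-phantom-out*: each phantom in turn is excluded entirely; h is chosen
by nested leave-one-phantom-out among the remaining six; the report carries one
row per held-out phantom (latent variables, SECV, SEP, RSEP, R² calibration, R²
prediction, bias) — the unseen-matrix generalisation test.

## Figures of merit

SECV = √(Σ(c−ĉ)²/(n−h−1)) over cross-validated predictions,
SEP = √(Σ(c−ĉ)²/n) over prediction-set residuals, bias = mean(ĉ−c)
(predicted-minus-assigned sign convention), and slope/intercept/R² from the OLS
of predicted on assigned temperature. RSEP is normalised by the mean reference
temperature (RSEP = 100·SEP/mean(c)); the normaliser is a package convention —
it is the one consistent with errors of ~0.2 °C around 22 °C mapping to ~1 % —
and is explicit in `nirtherm.metrics.rsep`. SECV ≥ SEP for equal residuals
whenever h ≥ 0.

## Problem sizes and determinism

The default study size (700 recordings × 157 frames × 84 samples × 2 channels
≈ 18M raw samples) generates and processes in about two seconds, so tests and
the acceptance script run it at full size; unit tests use reduced cadences
(3–7 frames, 1–4 recordings per step) where the full stream adds nothing.
Identical seed and configuration give bit-identical output everywhere; the CLI
writes a manifest (config hash, seed, library versions) beside every stage's
outputs.

## Known limitations

- The generator's error scale is a design choice, not a measurement; absolute
  SEP values from synthetic runs characterise the pipeline, not an instrument.
  With the default conditions the leave-one-phantom-out median SEP is ≈0.05 °C,
  comfortably below the 0.5 °C wellness target but not evidence about hardware.
- A single linear regression vector cannot be exact across phantoms whose
  water fraction scales the temperature response (the response is w·r·ΔG);
  the residual slope mismatch (~±6 % across the design) is part of the
  held-out-phantom error budget.
- Flat instability events are detectable only as score jumps; spectrally
  structured artefacts would need a richer event model.
- The composition design is nearly collinear in gelatin and water (R² = 0.98),
  so composition-resolved attribution of offsets is intrinsically weak.
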