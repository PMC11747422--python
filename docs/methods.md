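# Methods

This note documents the models, conventions and numerical choices behind
`carotidwave`, and what the synthetic-data validation does and does not
establish about real ultrasound data.

## Linear wave model and synthesis

The generator treats the carotid pulse as a linear wave on a uniform
vessel.  One cardiac cycle of forward flow is a diastolic baseline plus a
single systolic pulse with a raised-cosine upstroke (duration `t_rise`,
default 15 ms) and an exponential decay (`t_decay`, default 25 ms) — a
smooth, differentiable shape with one systolic peak inside the first 40 %
of the cycle.  A recording is the superposition of one pulse per cycle
(two virtual preceding cycles put the record start in steady state), with
optional heavy-tailed per-cycle RR jitter (Student-t, df = 3) to emulate
the arrhythmic beats seen in a quarter of the study animals.

The reflected wave is a delayed (`tau`, default 20 ms), scaled (Γ) copy of
the *pulsatile* forward perturbation p(t) with flow sign inverted, while
its area contribution adds:

    Q_f(t) = Q_dia + p(t)
    Q_r(t) = −Γ · p(t − τ)
    A(t)   = A_dia + (p(t) + Γ · p(t − τ)) / c
    V(t)   = Q(t) / A(t),     Q = Q_f + Q_r

The diastolic baseline is treated as purely forward; reflecting it too
would displace the end-diastolic area from `A_dia` and has no effect on
any harmonic-based quantity (a constant carries no first harmonic).  With
Γ = 0 the construction gives Q − Q_dia = c · (A − A_dia) identically, which
is what makes the QA-loop slope equal the planted wave speed and gives the
analysis chain an exact oracle.

All computation is in SI units (m², m³/s, m/s); conversions to mm, mL/min,
beats/min and kPa happen only at I/O boundaries, so the QA slope is
dimensionally a velocity with no hidden factors.

Default physiology (mouse common carotid under anesthesia): diameter
0.5 mm, wall 0.05 mm, heart rate 450 bpm, cycle-mean flow ≈ 0.65 mL/min,
PWV 3 m/s, Γ 0.3, blood density 1.05 g/mL.  Measurement noise is additive
Gaussian on the area and velocity channels, scaled as a fraction (default
0.02) of each channel's pulsatile amplitude; `Q_f`/`Q_r` stay the
noiseless truth so recovery errors are attributable.

## Image rendering and trace extraction

M-mode images place Gaussian-profile wall bands (FWHM = wall thickness)
with centres on the lumen boundary, so the centre-to-centre separation
equals the inner diameter; the band-centre convention is a declared
modeling choice, not a claim about any instrument's echo appearance.
Speckle is multiplicative Rayleigh noise (unit mean) blended with weight
0.5 by default.  Doppler spectrograms fill each column up to
V_max(t) = 2·V(t) — the parabolic-profile convention whose inverse is the
envelope-halving rule used in analysis — plus a rectified-Gaussian noise
floor.

Wall outlining finds, per column, the two most prominent peaks of the
depth-smoothed profile (Gaussian, σ = 1.5 px; minimum separation 0.15 mm)
and refines each band centre as the midpoint of its interpolated
half-maximum crossings, which is exact for a symmetric band and in
practice recovers the diameter to ~0.01 px noiseless and ~0.3 px RMSE at
default speckle.  Wall thickness is the FWHM with the smoothing kernel
deconvolved in quadrature.  Columns with fewer than two bands (tolerated
up to 10 %, otherwise extraction fails with a diagnostic) are interpolated
from neighbours.  Envelope tracing takes the highest velocity bin
exceeding a noise-floor threshold (99.5th percentile of the top-decile
bins) as part of a ≥3-bin contiguous run, which rejects isolated noise
pixels above the envelope.

Both traces then pass a **despike** filter: a sample is replaced by the
running median (width 5) only if it deviates by more than 2 px (walls) or
8 bins (envelope).  Unlike a plain median filter this leaves the sharp
systolic peak untouched — a plain median was observed to clip the peak by
several bins — while still removing speckle outliers.

## Cycle processing

Feet are located by intersecting tangents: the horizontal tangent through
the pre-upstroke minimum and the tangent at the maximum-upstroke-slope
point (prominent maxima of the smoothed derivative, ≥ 60 ms apart).  The
intersecting-tangents rule is a declared convention; it is sub-sample
accurate and phase-consistent across cycles, which is all ensemble
averaging requires.  Feet are detected once, on the velocity signal, and
reused for area and flow so the signals stay phase-locked.  Cycles whose
RR deviates from the median by > 20 % are rejected and logged; the final
partial cycle is always discarded.  Retained cycles are linearly resampled
to 256 samples (power of two, convenient for harmonic analysis) and
averaged pointwise; the heart rate is 60 / median RR.

## Hemodynamic metrics

- **QA loop**: the fit is restricted to the ascending limb (foot → peak
  flow) and to samples whose flow lies between 20 % and 80 % of the
  foot-to-peak excursion *above the foot flow*, i.e. the band is measured
  on the systolic upstroke, the interval the method assumes
  reflection-free.  Ordinary least squares of Q on A; slope = PWV;
  R², window indices and a negative-slope flag are always reported.
- **Wave separation** uses end-diastolic (foot) values as the perturbation
  baseline — the only unambiguous landmark on an averaged cycle.
  Conservation Q_f + Q_r = Q holds by construction on every input.
- **Reflection coefficient** is reflected/forward (bounded, interpretable)
  at the first DFT harmonic of the single averaged cycle treated as one
  period, no windowing.  The reciprocal is available as a diagnostic.  The
  orientation of the ratio is fixed here by convention since "ratio of the
  first harmonics" is order-ambiguous.
- **PI** uses the foot velocity as end-diastolic velocity and the cycle
  mean as denominator.
- **Moens–Korteweg** uses the thin-wall form with the inner (lumen)
  end-diastolic diameter: E = c²ρD/h, ρ = 1.05 g/mL, reported in kPa.
- The reported diameter is the end-diastolic diameter of the mean cycle,
  chosen to pair with the `A_dia` baseline used by the wave separation.

Validated recovery at these defaults (noiseless, reflection delay past the
QA window): PWV to < 0.01 % (Γ = 0) and < 0.5 % (Γ = 0.3); reflected-wave
RMSE < 1 % of forward amplitude; Γ̂ within 0.002 over
c ∈ {2,3,4,6} m/s × Γ ∈ {0,…,0.45}.  With 2 % channel noise the median
PWV error over 100 seeds is ~1.5 %.

## Cohort simulation

The cohort simulator works at the metric level: each value is a product of
a baseline, a common age trajectory, a right-side asymmetry (RCCA larger
in diameter and flow), a planted dcr effect interpolated in age per sex, a
lognormal per-mouse intercept and lognormal residual noise; Young's
modulus is derived from the simulated PWV, diameter and wall thickness so
the metrics stay mutually consistent.  The planted effect table mirrors
the reported disease course: early flow deficit (−25 %) and heart-rate
drop (−29 %) in females with late normalization, early diameter increase
(+12 %) and PWV decrease (−22 → −30 %) in males, late female PWV (+21 %)
and reflection-coefficient rises, elevated pulsatility index, thicker
walls, two male dcr dropouts before the final age and ~25 % arrhythmic
mice.  Waveform-level rendering maps each cohort row to generator truth
(PWV, diameter, thickness, heart rate, Γ directly; the forward pulse is
rescaled so the analytic cycle-mean flow matches the row), so the full
image chain can be run on a whole cohort; the pulsatility index is then
emergent rather than planted.

## Statistics

Mixed models are REML random-intercept fits (statsmodels `MixedLM`) with
genotype, sex, age (categorical across the three imaging ages by default;
continuous optional) and side as fixed effects; interactions are
configurable, with `genotype * sex * age + side` the default and a
body-weight variant without side supported.  Fixed-effect p-values use the
Wald normal approximation.  With 24 mice this is known to be mildly
anti-conservative, and the package's own null simulation shows it: the
empirical type-I error of the genotype test is ≈ 6 % at a nominal 5 %.
This is deliberate — the approximation is documented and its calibration
is measured rather than hidden.  No multiple-testing correction is applied
by default (a Benjamini–Hochberg flag exists).  Post-hoc simple effects
come from releveling (refitting with a different reference level), which
leaves the likelihood unchanged.

ROC analysis evaluates midpoints between sorted unique values plus ±∞,
chooses the orientation with AUC ≥ 0.5 (recorded), computes the
trapezoidal AUC (equal to the Mann–Whitney statistic with ties counted
half — verified against a brute-force pair count), and takes the Youden
cut-off J = max(sens + spec − 1) with ties broken toward the lower
threshold.  The day-50 screen reads each (sex, metric) genotype simple
effect from the releveled full model (a per-sex stratified refit is
optional), and runs ROC on per-mouse side-averaged day-50 values for
significant metrics.

## What the synthetic validation does not show

The generator realizes the same linear, thin-wall, parabolic-profile
assumptions the analysis inverts, so passing tests demonstrate internal
consistency, correct implementation and noise robustness — not robustness
to model violations in real arteries (tapering, viscoelastic walls,
non-parabolic profiles, angle-of-insonation error, probe motion, spectral
broadening).  No pressure is simulated or measured; wave separation is
flow/area-based throughout.  The two-band M-mode appearance and the foot
and band-centre conventions are declared choices; an instrument's
"outline" may track a different interface, which would bias absolute
diameters but not longitudinal contrasts.

## Problem sizes

Default runs are sized for a laptop CPU: 6–10 cycles per recording at
1–2 kHz sampling, 24-mouse cohorts imaged at three ages on both sides
(~140 recordings per demo run, ~25 s end to end), 400–500 simulated
cohorts for calibration studies.
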