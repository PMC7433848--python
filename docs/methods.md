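# Methods

This note records the models behind `ironstrip`, the defaults they ship
with, and what the synthetic data do and do not establish.

## Assay model

The strip's colour signal is treated as a decadic pseudo-absorbance,
`A_c = -log10(I_sensing,c / I_reference,c)` per RGB channel, computed from
the arithmetic mean 8-bit intensity of a fixed rectangular sensing region
and a fixed reference region. Choices and caveats:

- **Log base.** Base 10, so sensitivities carry decadic absorbance units
  and compose with Beer–Lambert constants.
- **Region statistic.** Arithmetic mean by default (what a minimal phone
  app computes); the median is available via `statistic="median"` for
  robustness to specks. Means are region-size invariant on uniform pads,
  so geometry mismatches bias results only through genuine non-uniformity.
- **No colour management.** Intensities are used as stored, without gamma
  or white-balance correction. Real camera pipelines are not linear; this
  is a known limitation, mitigated in hardware by the fixed mount and LED.
  Pseudo-absorbance divides out any *shared* multiplicative illumination
  factor, which is why the reference pad exists.
- **QC.** Pixels at 0 or 255 are counted; a region with more than 1%
  saturated pixels flags the reading. A zero sensing mean yields a +inf
  sentinel rather than an exception; a zero reference mean is an error.
- **Channel selection** fits per-channel slopes of absorbance on
  concentration and picks the largest positive one, tie-breaking in the
  fixed order red, green, blue. On-spec strips this selects red
  (~0.00049 a.u./(μg/dL)) over green (~0.00032) with blue insensitive.

## Calibration and quality metrics

Calibration is ordinary least squares of absorbance on concentration with a
free intercept (a blank standard is part of the series; the intercept
absorbs its offset). Through-origin fitting is available. Inversion
`c = (A - intercept)/slope` reports negative or out-of-range concentrations
unclamped but flagged: for a screening assay, transparency beats cosmetic
truncation. The calibrated range defaults to 25–300 μg/dL, with a
conservative 50–300 preset.

- **LoD** = 3·SD(blank absorbances)/slope, the standard 3-sigma form on the
  absorbance scale; sample SD (n−1) everywhere, as for all SDs here.
- **CV%** = 100·SD(slopes)/mean(slopes) over replicate calibration fits.
- **Environmental model.** Sensitivity is regressed linearly on operating
  temperature (reference 23 °C, validity 10–50 °C; outside is flagged, not
  refused). Humidity gets per-temperature diagnostic slopes only — observed
  humidity effects are an order of magnitude below the temperature effect,
  so no humidity correction is applied to predictions. The temperature
  coefficient's sign is whatever the data give; adjustment shifts the slope
  only, never the intercept, and is exactly invertible.
- **Accelerated aging.** Q10 = 2: `AAF = 2^((T_heat − T_room)/10)`,
  equivalent shelf time = duration × AAF. Multiplicative in temperature
  deltas by construction.

## Kinetics

Complex formation is integrated as a one-state ODE,
`d[COM]/dt = k'(iron0 − COM)^α (ferene0 − 3·COM)^β`, with iron and ferene
eliminated by stoichiometry, so conservation holds to machine precision at
every output time. LSODA with rtol 1e-10 and a state-scaled atol keeps the
endpoint stable under grid halving to < 1e-6 relative; [COM] is clamped to
[0, min(iron0, ferene0/3)]. Ascorbic acid is assumed in excess and not
modelled dynamically; a warning fires when the excess ratio drops
below 100. Units are mol/L and seconds internally, with
`KineticConditions.from_assay` converting bench units (μg/dL iron via the
55.845 g/mol molar mass; mM ferene).

Reaction orders come from the classical 2×2 initial-rate design (two iron
levels × two ferene levels, matching the 50/100 μg/dL × 2/4 mM
characterisation): `α = log(r_hi/r_lo)/log(iron_hi/iron_lo)` averaged over
ferene levels, β symmetrically, k′ from the four rate/(Fe^α·ferene^β)
ratios; a global log-log regression of the four rates serves as a built-in
cross-check. The initial rate itself is estimated inside the window where
conversion stays below `window_fraction` (default 10%) of the initial iron:

- default `rate_method="poly"`: a local quadratic fit of the progress curve
  whose slope at t = 0 is the rate — the standard initial-slope reading of
  a progress curve, robust to measurement noise;
- `rate_method="derivative"`: central-difference rates (optionally after a
  centred moving average) extrapolated linearly back to t = 0.

Both recover (α, β, k′) within a few percent on noise-free simulations; the
derivative route degrades under realistic absorbance noise because
differencing amplifies it, which is why it is not the default. Note the
moving-average/central-difference combination shrinks interior derivative
noise roughly in proportion to the window width (its differences telescope),
not like the square root.

The extinction coefficient ships as the supplied constant
ε = 33 366 L·cm⁻¹·mol⁻¹ (0.6 cm path). It is *not* derived in-code from a
calibration slope: no standard dilution convention reproduces that value
from the 0.00093 a.u./(μg/dL) sensitivity, so deriving it would bake in an
unverifiable convention. Absorbance and concentration traces round-trip
exactly through the Beer–Lambert pair. No k′ value is established for the
bench reaction; simulations default to k′ = 5000 L²·mol⁻²·s⁻¹, chosen so
that with orders (1, 2) and millimolar ferene the observed rate constant is
0.02–0.08 s⁻¹, i.e. colour development on the assay's ~2-minute timescale.

**Reagent accounting.** Mixing schemes (reference 5:1:1, optimized 3:1:1,
dry strip) carry stock concentrations and volumes; molar ratios to iron are
exact arithmetic. The optimized scheme at 100 μg/dL gives ferene:iron ≈ 223
with the other reagents 3–5 orders of magnitude in excess. The strip
preset's dried reagent load is a *synthetic nominal assumption* (3:1
volume-equivalents rehydrated by a 30 μL sample, placing ferene:iron ≈ 300);
real strip loadings are a fabrication detail not represented here.

## Method comparison

Percent Bland–Altman uses the pair mean as denominator (the standard
percent-difference convention): bias = mean of `100·(test − ref)/pair-mean`,
limits of agreement = bias ± 1.96·SD, always computed from the data and
never forced symmetric. Regression is OLS of test on reference with Pearson
r; inter-laboratory percent error uses the external laboratory's value as
denominator. Interferents are "negligible" below 10% of the iron response
(configurable). Note one subtlety the synthetic generator exposes: a
multiplicative disturbance `test = ref·(1 + d)` with `E[d] = −4%` produces
pair-mean percent differences `200d/(2+d)` whose mean is ≈ −4.6%, not
−4.0% — the two bias conventions differ at second order in the dispersion,
which matters once the SD reaches ~10%.

## Synthetic data: what it emulates, and not

Generators are pure functions of (design, seed); identical inputs give
identical outputs, and noise-free settings reproduce the closed-form models
to machine precision.

Defaults encode the characterised study conditions: standards
(0, 25, 50, 100, 150, 300 μg/dL); optimized-method sensitivity 0.00093
a.u./(μg/dL) with 2.2% between-run CV and 0.001 a.u. residual SD over 100
runs; strip red/green sensitivities 0.00049/0.00032 with blue flat; blank
noise 0.0027 a.u. — *back-computed* from the 16.5 μg/dL detection limit and
the 0.00049 slope, as no direct blank-noise figure exists; paired designs
with n = 20 on 25–300 μg/dL, proportional offset −4% and SD 10.2% (so the
1.96·SD limits of agreement span ±20% around the bias); environmental
records at 10–51 °C with a 7×10⁻⁶ a.u./(μg/dL)/°C temperature coefficient,
~1e-7-scale humidity slopes, and 5×10⁻⁶ record noise.

Noise forms: Gaussian and additive on absorbance; multiplicative
(proportional) on paired concentrations — the simplest forms reproducing
the stated CV-type dispersions. Images are 160×100 8-bit RGB with
40×40-pixel pads, base intensity 200, Gaussian pixel noise (SD 2 by
default) added before rounding; out-of-range pixels are clipped with a
count kept on the image. An optional linear illumination gradient spans the
raster width and hits both pads, as a shared LED would. Quantization
matters: at base 200 a half-count rounding error is ~0.0026 absorbance
units end-to-end, the dominant error on noise-free renders. A kinetic trace
can carry an additive baseline drift (a.u./min) to mimic the turbidity
artifact of surfactant-containing chemistry — rising apparent absorbance at
a non-absorbing wavelength.

What passing on these inputs does **not** show: robustness to real serum
matrices, membrane flow and drying physics, camera nonlinearity, white
balance, perspective, or operator variation. The synthetic world is linear,
Gaussian and geometrically perfect by design; results on it validate the
*computations*, not the chemistry or the hardware.

## Problem sizes

Replicate counts mirror the study conditions where stated (30 blanks, 100
calibration runs, n = 20 pairs, 2×2 kinetics) and otherwise use 30–500
seeded replicates, enough to pin means well inside the tolerances tested.
Kinetic grids default to 1201 points over 120 s (6001 when traces carry
noise, so the initial-rate window keeps enough points in its fastest cell).
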