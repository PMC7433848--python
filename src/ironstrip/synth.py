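"""Seeded generators for every input the analysis pipeline consumes.

No deposited data accompany the assay, so the pipeline is exercised on
synthetic inputs whose statistical structure matches the study conditions:

* calibration tables with run-to-run slope variation (relative SD = the
  between-run CV) and additive Gaussian residuals on absorbance;
* blank replicate sets whose SD sets the limit of detection;
* strip images whose sensing-pad channels are attenuated per Beer-Lambert,
  with shared linear illumination gradient, Gaussian pixel noise, and 8-bit
  quantization;
* paired test-vs-reference measurements with a proportional offset
  (multiplicative Gaussian disturbance), matching a percent Bland-Altman
  structure;
* kinetic absorbance traces driven by the rate-law simulator, optionally
  with an additive drift emulating a turbidity baseline.

Every generator is a pure function of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import BlankSet
from .errors import ConfigurationError
from .kinetics import (
    KineticConditions,
    KineticTrace,
    OpticalConstants,
    RateLawParams,
    absorbance_from_complex,
    simulate_complex_formation,
)
from .strip_image import RegionSpec
from .validation import PairedMeasurements

#: Iron standards (ug/dL): a blank plus five levels spanning the
#: physiologically relevant total-iron range.
STANDARD_SERIES = (0.0, 25.0, 50.0, 100.0, 150.0, 300.0)

#: Sensitivities (a.u. per ug/dL): optimized reference method, original
#: reference method, and the strip red/green channels.
SLOPE_OPTIMIZED = 0.00093
SLOPE_ORIGINAL = 0.00072
SLOPE_STRIP_RED = 0.00049
SLOPE_STRIP_GREEN = 0.00032

#: Blank absorbance noise (a.u.).  Not measured directly in the assay
#: characterisation; back-computed from the 16.5 ug/dL detection limit and
#: the 0.00049 strip sensitivity via LoD = 3*SD/slope.
BLANK_NOISE_SD = 0.0027


def _positive(name: str, value: float) -> None:
    if value < 0:
        raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CalibrationDesign:
    """Design of replicate synthetic calibration runs."""

    standards: tuple = STANDARD_SERIES
    true_slope: float = SLOPE_OPTIMIZED
    true_intercept: float = 0.0
    slope_cv: float = 0.022  # run-to-run relative SD of the slope
    residual_sd: float = 0.001  # additive absorbance noise per point
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        std = np.asarray(self.standards, dtype=float)
        if std.size < 2 or np.any(std < 0) or np.any(np.diff(std) <= 0):
            raise ConfigurationError(
                "CalibrationDesign.standards must be non-negative and strictly increasing"
            )
        _positive("CalibrationDesign.slope_cv", self.slope_cv)
        _positive("CalibrationDesign.residual_sd", self.residual_sd)
        if self.n_runs < 1:
            raise ConfigurationError("CalibrationDesign.n_runs must be >= 1")


def gen_calibration_tables(design: CalibrationDesign) -> list[pd.DataFrame]:
    """Generate ``n_runs`` calibration tables.

    Run r draws its slope from Normal(true_slope, slope_cv*true_slope) and
    each absorbance is run_slope*c + true_intercept + Normal(0, residual_sd).
    """
    rng = np.random.default_rng(design.seed)
    std = np.asarray(design.standards, dtype=float)
    tables = []
    for run in range(design.n_runs):
        run_slope = design.true_slope * (1.0 + design.slope_cv * rng.standard_normal())
        absorbance = (
            run_slope * std
            + design.true_intercept
            + design.residual_sd * rng.standard_normal(std.size)
        )
        tables.append(
            pd.DataFrame(
                {
                    "concentration_ug_dl": std,
                    "absorbance_au": absorbance,
                    "run_id": run,
                }
            )
        )
    return tables


def gen_blank_set(n: int = 30, noise_sd: float = BLANK_NOISE_SD, seed: int = 0) -> BlankSet:
    """Blank absorbances ~ Normal(0, noise_sd), n >= 2."""
    if n < 2:
        raise ConfigurationError("gen_blank_set: n must be >= 2 (SD undefined below)")
    _positive("gen_blank_set.noise_sd", noise_sd)
    rng = np.random.default_rng(seed)
    return BlankSet(values=noise_sd * rng.standard_normal(n))


@dataclass(frozen=True)
class StripImage:
    """Rendered 8-bit RGB strip raster with quantization bookkeeping."""

    pixels: np.ndarray  # (H, W, 3) uint8
    concentration_ug_dl: float
    n_clipped: int = 0


@dataclass(frozen=True)
class StripRenderSpec:
    """Rendering model for synthetic strip images.

    The reference pad shows the base intensity; the sensing pad's red and
    green channels are attenuated by 10^(-slope_c * concentration) per
    Beer-Lambert (blue is insensitive to iron).  A linear illumination
    gradient across the raster width applies to both pads, mimicking the
    shared LED lighting; Gaussian pixel noise is added before 8-bit
    rounding and clipping.
    """

    image_width: int = 160
    image_height: int = 100
    sensing_region: RegionSpec = field(default_factory=lambda: RegionSpec(20, 30, 40, 40))
    reference_region: RegionSpec = field(default_factory=lambda: RegionSpec(100, 30, 40, 40))
    base_intensity: float = 200.0
    slope_red: float = SLOPE_STRIP_RED
    slope_green: float = SLOPE_STRIP_GREEN
    pixel_noise_sd: float = 2.0
    illumination_gradient: float = 0.0  # full-width relative span
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.base_intensity <= 255:
            raise ConfigurationError("StripRenderSpec.base_intensity must lie in [1, 255]")
        _positive("StripRenderSpec.pixel_noise_sd", self.pixel_noise_sd)
        for name, region in (
            ("sensing_region", self.sensing_region),
            ("reference_region", self.reference_region),
        ):
            if not region.within(self.image_height, self.image_width):
                raise ConfigurationError(f"StripRenderSpec.{name} extends outside the raster")
        if self.sensing_region.overlaps(self.reference_region):
            raise ConfigurationError(
                "StripRenderSpec.sensing_region overlaps reference_region"
            )


def gen_strip_image(concentration: float, spec: StripRenderSpec) -> StripImage:
    """Render one strip image at the given iron concentration (ug/dL)."""
    _positive("concentration", concentration)
    h, w = spec.image_height, spec.image_width
    img = np.full((h, w, 3), spec.base_intensity, dtype=float)
    atten = np.array(
        [
            10.0 ** (-spec.slope_red * concentration),
            10.0 ** (-spec.slope_green * concentration),
            1.0,  # blue channel is not iron-sensitive
        ]
    )
    img[spec.sensing_region.slices()] *= atten
    if spec.base_intensity * atten.min() < 1.0:
        raise ConfigurationError(
            "rendered sensing intensity < 1 (saturated dark); reduce slope or concentration"
        )
    if spec.illumination_gradient != 0.0:
        x = np.arange(w) / (w - 1) - 0.5
        img *= (1.0 + spec.illumination_gradient * x)[None, :, None]
    if spec.pixel_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img += spec.pixel_noise_sd * rng.standard_normal(img.shape)
    rounded = np.rint(img)
    n_clipped = int(np.sum((rounded < 0) | (rounded > 255)))
    return StripImage(
        pixels=np.clip(rounded, 0, 255).astype(np.uint8),
        concentration_ug_dl=float(concentration),
        n_clipped=n_clipped,
    )


def gen_strip_series(
    concentrations, spec: StripRenderSpec, seed: int | None = None
) -> list[StripImage]:
    """Render a calibration series, one image per concentration, with
    per-image seeds spawned from ``seed`` (defaults to ``spec.seed``)."""
    root = np.random.default_rng(spec.seed if seed is None else seed)
    images = []
    for c in concentrations:
        sub_seed = int(root.integers(0, 2**31 - 1))
        images.append(gen_strip_image(c, _with_seed(spec, sub_seed)))
    return images


def _with_seed(spec: StripRenderSpec, seed: int) -> StripRenderSpec:
    from dataclasses import replace

    return replace(spec, seed=seed)


@dataclass(frozen=True)
class PairedDesign:
    """Design of synthetic paired test-vs-reference measurements."""

    n_pairs: int = 20
    conc_range: tuple[float, float] = (25.0, 300.0)
    proportional_bias: float = -0.04
    proportional_sd: float = 0.102
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ConfigurationError("PairedDesign.n_pairs must be >= 2")
        low, high = self.conc_range
        if not (0 < low < high <= 1000):
            raise ConfigurationError("PairedDesign.conc_range must satisfy 0 < low < high <= 1000")
        _positive("PairedDesign.proportional_sd", self.proportional_sd)


def gen_paired_measurements(design: PairedDesign, max_redraws: int = 100) -> PairedMeasurements:
    """Reference values uniform on conc_range; test = reference*(1 + d) with
    d ~ Normal(proportional_bias, proportional_sd).  Non-positive test
    values are redrawn (they are vanishingly rare at realistic designs)."""
    rng = np.random.default_rng(design.seed)
    low, high = design.conc_range
    reference = rng.uniform(low, high, design.n_pairs)
    d = rng.normal(design.proportional_bias, design.proportional_sd, design.n_pairs)
    for _ in range(max_redraws):
        bad = 1.0 + d <= 0
        if not bad.any():
            break
        d[bad] = rng.normal(design.proportional_bias, design.proportional_sd, bad.sum())
    else:
        raise ConfigurationError(
            "PairedDesign.proportional_bias/sd keep producing non-positive test values"
        )
    return PairedMeasurements(reference=reference, test=reference * (1.0 + d))


def gen_kinetic_trace(
    conditions: KineticConditions,
    params: RateLawParams,
    optics: OpticalConstants | None = None,
    noise_sd: float = 0.0,
    drift_per_min: float = 0.0,
    seed: int = 0,
    suppress_complex: bool = False,
) -> KineticTrace:
    """Absorbance trace from the rate-law simulator plus measurement noise.

    A(t) = epsilon*l*[COM](t) + Normal(0, noise_sd) + drift_per_min * t/60.
    A nonzero drift on a ``suppress_complex`` run reproduces a turbidity
    baseline: rising apparent absorbance at a non-absorbing setting.
    """
    _positive("gen_kinetic_trace.noise_sd", noise_sd)
    optics = optics or OpticalConstants()
    trace = simulate_complex_formation(conditions, params)
    if suppress_complex:
        trace = KineticTrace(
            times=trace.times,
            values=np.zeros_like(trace.values),
            conditions=conditions,
        )
    abs_trace = absorbance_from_complex(trace, optics)
    values = abs_trace.values + drift_per_min * abs_trace.times / 60.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_sd * rng.standard_normal(values.size)
    return KineticTrace(
        times=abs_trace.times,
        values=values,
        conditions=conditions,
        value_kind="absorbance_au",
    )


def gen_environmental_records(
    temperatures=(10.0, 25.0, 40.0, 51.0),
    humidities=(10.0, 60.0),
    reference_sensitivity: float = SLOPE_STRIP_RED,
    reference_temperature: float = 23.0,
    temp_coefficient: float = 7e-6,
    humidity_coefficients: dict | None = None,
    sensitivity_sd: float = 5e-6,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic (temperature, humidity, fitted-sensitivity) records.

    Sensitivity = reference + temp_coefficient*(T - T_ref) + per-temperature
    humidity slope * (RH - 50) + Normal(0, sensitivity_sd).  Humidity slopes
    default to the negligible values observed for the strips (order 1e-7).
    """
    _positive("gen_environmental_records.sensitivity_sd", sensitivity_sd)
    if humidity_coefficients is None:
        humidity_coefficients = {10.0: 4e-7, 25.0: -2e-7}
    rng = np.random.default_rng(seed)
    rows = []
    for t in temperatures:
        for rh in humidities:
            sens = (
                reference_sensitivity
                + temp_coefficient * (t - reference_temperature)
                + humidity_coefficients.get(float(t), 0.0) * (rh - 50.0)
                + sensitivity_sd * rng.standard_normal()
            )
            rows.append(
                {
                    "temperature_c": t,
                    "humidity_pct": rh,
                    "sensitivity_au_per_ug_dl": sens,
                }
            )
    return pd.DataFrame(rows)
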