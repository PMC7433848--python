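"""Calibration, limit of detection, environmental sensitivity and shelf-life.

The assay response is linear in total iron over the physiological range,

    A = slope * c + intercept,

with the slope ("sensitivity", a.u. per ug/dL) the figure of merit.  This
module fits that line by ordinary least squares, inverts it to report
concentrations, and derives the standard analytical quality metrics:

* limit of detection, LoD = 3 * SD(blank absorbances) / slope;
* between-run coefficient of variation, CV% = 100 * SD(slopes) / mean(slopes);
* a linear temperature model for the sensitivity (humidity is treated as a
  nuisance with per-temperature slopes, reported but not applied);
* accelerated-aging equivalence under the Q10 = 2 rule,
  AAF = 2^((T_heat - T_room)/10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ComputationError, ConfigurationError

#: Calibrated concentration range of the assay (ug/dL).  The strips are
#: characterised from 25 to 300 ug/dL; a 50-300 preset is also provided.
DYNAMIC_RANGE_STRIP = (25.0, 300.0)
DYNAMIC_RANGE_CONSERVATIVE = (50.0, 300.0)

#: Environmental validity range of the temperature correction (deg C).
TEMPERATURE_VALIDITY_RANGE = (10.0, 50.0)


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted straight-line calibration: absorbance = slope*c + intercept."""

    slope: float
    intercept: float
    r2: float
    residual_sd: float
    n_points: int
    method: str = "ols"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ConfigurationError("CalibrationCurve.n_points must be >= 3")
        if not (np.isnan(self.r2) or 0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ConfigurationError("CalibrationCurve.r2 must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "residual_sd": self.residual_sd,
            "n": self.n_points,
            "method": self.method,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r2=float(d.get("r2", np.nan)),
            residual_sd=float(d.get("residual_sd", np.nan)),
            n_points=int(d.get("n", 3)),
            method=str(d.get("method", "ols")),
            flags=tuple(d.get("flags", ())),
        )


@dataclass(frozen=True)
class BlankSet:
    """Absorbance readings of blank (zero-iron) replicates."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise ConfigurationError("BlankSet.values needs >= 2 replicates (SD undefined below)")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class AgingSpec:
    """Accelerated-aging storage condition: hot box vs room temperature."""

    t_heat_c: float
    t_room_c: float
    duration_days: float

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ConfigurationError("AgingSpec.duration_days must be > 0")


@dataclass(frozen=True)
class AgingResult:
    aaf: float
    equivalent_days: float


class CalibrationModel(RegressorMixin, BaseEstimator):
    """OLS straight-line calibration of absorbance on iron concentration.

    Parameters
    ----------
    fit_intercept : bool, default True
        A free intercept absorbs any blank offset (a blank standard is part
        of the design); set False to force the line through the origin after
        external blank subtraction.
    calibrated_range : (low, high), default (25, 300)
        Concentration range (ug/dL) outside which inverse predictions are
        flagged as extrapolations.

    Attributes
    ----------
    slope_, intercept_ : float
    r2_ : float            coefficient of determination
    residual_sd_ : float   SD of fit residuals (ddof = number of parameters)
    n_points_ : int
    """

    def __init__(self, fit_intercept: bool = True, calibrated_range=DYNAMIC_RANGE_STRIP):
        self.fit_intercept = fit_intercept
        self.calibrated_range = calibrated_range

    def fit(self, X, y):
        c = np.asarray(X, dtype=float).reshape(-1)
        a = np.asarray(y, dtype=float).reshape(-1)
        if c.size != a.size:
            raise ConfigurationError("X and y must have equal length")
        if np.unique(c).size < (3 if self.fit_intercept else 2):
            raise ComputationError("calibration needs >= 3 distinct concentrations")
        if self.fit_intercept:
            slope, intercept = np.polyfit(c, a, 1)
            dof = c.size - 2
        else:
            slope = float(c @ a / (c @ c))
            intercept = 0.0
            dof = c.size - 1
        resid = a - (slope * c + intercept)
        ss_tot = float(np.sum((a - a.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r2_ = float(np.clip(r2, 0.0, 1.0))
        self.residual_sd_ = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
        self.n_points_ = int(c.size)
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Forward model: absorbance predicted at concentration(s) X."""
        c = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * c + self.intercept_

    def predict_concentration(self, absorbance) -> tuple[np.ndarray, list[tuple[str, ...]]]:
        """Invert the calibration: c = (A - intercept) / slope, with flags.

        Values outside ``calibrated_range`` (including negatives) are
        returned untouched but flagged -- transparency is preferred over
        clamping for a screening assay.
        """
        if self.slope_ == 0:
            raise ComputationError("cannot invert a zero-slope calibration")
        a = np.atleast_1d(np.asarray(absorbance, dtype=float))
        conc = (a - self.intercept_) / self.slope_
        low, high = self.calibrated_range
        flags = []
        for c in conc:
            f = []
            if c < 0:
                f.append("negative")
            if c < low:
                f.append("below_range")
            elif c > high:
                f.append("above_range")
            flags.append(tuple(f))
        return conc, flags

    def to_curve(self, method: str = "ols") -> CalibrationCurve:
        return CalibrationCurve(
            slope=self.slope_,
            intercept=self.intercept_,
            r2=self.r2_,
            residual_sd=self.residual_sd_,
            n_points=self.n_points_,
            method=method,
        )

    @classmethod
    def from_curve(cls, curve: CalibrationCurve, **kwargs) -> "CalibrationModel":
        model = cls(**kwargs)
        model.slope_ = curve.slope
        model.intercept_ = curve.intercept
        model.r2_ = curve.r2
        model.residual_sd_ = curve.residual_sd
        model.n_points_ = curve.n_points
        model.n_features_in_ = 1
        return model


def fit_calibration(table, method: str = "ols", fit_intercept: bool = True) -> CalibrationCurve:
    """Fit a calibration line from a table with columns
    ``concentration_ug_dl`` and ``absorbance_au`` (or a (conc, abs) pair)."""
    if isinstance(table, pd.DataFrame):
        c = table["concentration_ug_dl"].to_numpy(dtype=float)
        a = table["absorbance_au"].to_numpy(dtype=float)
    else:
        c, a = table
    return CalibrationModel(fit_intercept=fit_intercept).fit(c, a).to_curve(method=method)


def predict_concentration(curve: CalibrationCurve, absorbance: float):
    """Functional form of :meth:`CalibrationModel.predict_concentration`."""
    model = CalibrationModel.from_curve(curve)
    conc, flags = model.predict_concentration(absorbance)
    if np.isscalar(absorbance):
        return float(conc[0]), flags[0]
    return conc, flags


def limit_of_detection(curve: CalibrationCurve | CalibrationModel, blanks) -> float:
    """LoD (ug/dL) as three blank-noise SDs divided by the sensitivity.

    ``blanks`` may be a :class:`BlankSet` or a plain array of blank
    absorbances.  The sample SD (n-1 denominator) is used.
    """
    slope = curve.slope if isinstance(curve, CalibrationCurve) else curve.slope_
    if slope <= 0:
        raise ComputationError("limit_of_detection requires a positive slope")
    if not isinstance(blanks, BlankSet):
        blanks = BlankSet(np.asarray(blanks, dtype=float))
    return 3.0 * blanks.sd / slope


def slope_cv(curves) -> float:
    """Between-run CV% of calibration slopes: 100 * SD(slopes)/mean(slopes)."""
    slopes = np.array(
        [c.slope if isinstance(c, CalibrationCurve) else float(c) for c in curves], dtype=float
    )
    if slopes.size < 2:
        raise ConfigurationError("slope_cv needs >= 2 curves")
    mean = slopes.mean()
    if mean == 0:
        raise ComputationError("slope_cv undefined: mean slope is 0")
    return float(100.0 * np.std(slopes, ddof=1) / mean)


class EnvironmentalSensitivityModel(BaseEstimator):
    """Linear model of assay sensitivity versus operating temperature.

    Sensitivity drifts linearly with temperature over the tested 10-50 degC
    window; relative humidity has no practically significant effect, so
    humidity enters only as per-temperature diagnostic slopes.

    Parameters
    ----------
    reference_temperature : float, default 23.0
        Temperature (degC) at which laboratory calibrations are acquired.
    validity_range : (low, high), default (10, 50)
        Temperatures outside this window flag the adjustment as
        extrapolated.

    Attributes
    ----------
    temp_coefficient_ : float          a.u./(ug/dL)/degC
    reference_sensitivity_ : float     fitted line at the reference temperature
    humidity_coefficients_ : dict      temperature -> a.u./(ug/dL)/%RH
    """

    def __init__(
        self,
        reference_temperature: float = 23.0,
        validity_range=TEMPERATURE_VALIDITY_RANGE,
    ):
        self.reference_temperature = reference_temperature
        self.validity_range = validity_range

    def fit(self, X, y=None):
        """Fit from records of (temperature, humidity, sensitivity).

        ``X`` may be a DataFrame with columns ``temperature_c``,
        ``humidity_pct``, ``sensitivity_au_per_ug_dl`` or an (n, 3) array in
        that column order.
        """
        if isinstance(X, pd.DataFrame):
            temp = X["temperature_c"].to_numpy(dtype=float)
            hum = X["humidity_pct"].to_numpy(dtype=float)
            sens = X["sensitivity_au_per_ug_dl"].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            temp, hum, sens = arr[:, 0], arr[:, 1], arr[:, 2]
        if np.unique(temp).size < 2:
            raise ComputationError("environmental fit needs >= 2 distinct temperatures")
        coef, intercept = np.polyfit(temp, sens, 1)
        self.temp_coefficient_ = float(coef)
        self.reference_sensitivity_ = float(coef * self.reference_temperature + intercept)
        self.humidity_coefficients_ = {}
        for t in np.unique(temp):
            mask = temp == t
            if np.unique(hum[mask]).size >= 2:
                hslope = np.polyfit(hum[mask], sens[mask], 1)[0]
                self.humidity_coefficients_[float(t)] = float(hslope)
        self.n_features_in_ = 3
        return self

    def sensitivity_at(self, temperature: float) -> float:
        return self.reference_sensitivity_ + self.temp_coefficient_ * (
            temperature - self.reference_temperature
        )

    def adjust_curve(self, curve: CalibrationCurve, temperature: float) -> CalibrationCurve:
        """Shift a calibration slope from the reference temperature to
        ``temperature``; the intercept is left unchanged.  Temperatures
        outside the validity range are allowed but flagged."""
        delta = self.temp_coefficient_ * (temperature - self.reference_temperature)
        flags = list(curve.flags)
        low, high = self.validity_range
        if not (low <= temperature <= high):
            flags.append("temperature_out_of_validity_range")
        return CalibrationCurve(
            slope=curve.slope + delta,
            intercept=curve.intercept,
            r2=curve.r2,
            residual_sd=curve.residual_sd,
            n_points=curve.n_points,
            method=curve.method,
            flags=tuple(flags),
        )

    def to_dict(self) -> dict:
        return {
            "reference_sensitivity": self.reference_sensitivity_,
            "temp_coefficient": self.temp_coefficient_,
            "humidity_coefficients": {str(k): v for k, v in self.humidity_coefficients_.items()},
            "reference_temperature": self.reference_temperature,
            "validity_range": list(self.validity_range),
        }


def fit_environmental_model(records, reference_temperature: float = 23.0):
    """Fit an :class:`EnvironmentalSensitivityModel` from (T, RH, sensitivity)
    records (DataFrame, array, or iterable of 3-tuples)."""
    if not isinstance(records, pd.DataFrame):
        records = np.asarray(list(records), dtype=float)
    return EnvironmentalSensitivityModel(reference_temperature=reference_temperature).fit(records)


def temperature_adjust(
    curve: CalibrationCurve, model: EnvironmentalSensitivityModel, temperature: float
) -> CalibrationCurve:
    return model.adjust_curve(curve, temperature)


def aging_equivalent(spec: AgingSpec) -> AgingResult:
    """Q10 accelerated-aging equivalence.

    AAF = 2^X with X = (T_heat - T_room)/10; the equivalent room-temperature
    shelf time is the accelerated duration multiplied by the AAF.
    """
    aaf = 2.0 ** ((spec.t_heat_c - spec.t_room_c) / 10.0)
    return AgingResult(aaf=float(aaf), equivalent_days=float(spec.duration_days * aaf))
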