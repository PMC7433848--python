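"""Method-comparison statistics: regression, percent Bland-Altman,
inter-laboratory percent error, and interferent specificity.

The assay is validated against a reference spectrophotometric method on
paired serum determinations.  Agreement is summarised two ways:

* ordinary least squares of test on reference with the Pearson r, and
* a percent Bland-Altman analysis, where each pair contributes
  100*(test - reference)/pair-mean; the bias is the mean of these percent
  differences and the limits of agreement are bias +/- 1.96 SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ComputationError, ConfigurationError

#: Interferents are "negligible" below this fraction of the iron response.
DEFAULT_NEGLIGIBILITY_THRESHOLD = 0.10

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired test-vs-reference iron concentrations (ug/dL)."""

    reference: np.ndarray
    test: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", np.asarray(self.reference, dtype=float))
        object.__setattr__(self, "test", np.asarray(self.test, dtype=float))
        if self.reference.shape != self.test.shape:
            raise ConfigurationError("PairedMeasurements.reference/test lengths differ")
        if self.reference.size < 2:
            raise ConfigurationError("PairedMeasurements needs >= 2 pairs")
        if np.any(self.reference <= 0) or np.any(self.test <= 0):
            raise ConfigurationError("PairedMeasurements values must be positive")

    @property
    def n(self) -> int:
        return int(self.reference.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"reference_ug_dl": self.reference, "test_ug_dl": self.test})


@dataclass(frozen=True)
class MethodRegression:
    slope: float
    intercept: float
    r: float
    r2: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias_percent: float
    loa_lower: float
    loa_upper: float
    sd_percent: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_lower <= self.bias_percent <= self.loa_upper):
            raise ConfigurationError(
                "BlandAltmanResult.loa_lower/upper must bracket bias_percent"
            )

    def to_dict(self) -> dict:
        return {
            "bias_percent": self.bias_percent,
            "loa_lower_percent": self.loa_lower,
            "loa_upper_percent": self.loa_upper,
            "sd_percent": self.sd_percent,
            "n": self.n,
        }


@dataclass(frozen=True)
class SpecificityPanel:
    """Responses of candidate interferents next to the iron reference signal.

    ``analytes`` maps label -> (concentration mg/dL, measured absorbance).
    """

    analytes: dict[str, tuple[float, float]]
    iron_response: float

    def __post_init__(self) -> None:
        if self.iron_response <= 0:
            raise ConfigurationError("SpecificityPanel.iron_response must be > 0")


def method_regression(pairs: PairedMeasurements) -> MethodRegression:
    """OLS of test on reference concentrations with Pearson correlation."""
    if pairs.n < 3:
        raise ConfigurationError("method_regression needs >= 3 pairs")
    if np.ptp(pairs.reference) == 0:
        raise ComputationError("reference values have zero variance")
    res = stats.linregress(pairs.reference, pairs.test)
    return MethodRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        n=pairs.n,
    )


def percent_differences(pairs: PairedMeasurements) -> np.ndarray:
    """Per-pair percent difference, 100*(test - reference)/pair-mean."""
    means = (pairs.test + pairs.reference) / 2.0
    if np.any(means <= 0):
        raise ComputationError("a pair mean is <= 0; percent difference undefined")
    return 100.0 * (pairs.test - pairs.reference) / means


def bland_altman_percent(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Percent Bland-Altman: bias and 95% limits of agreement.

    bias = mean percent difference; LoA = bias +/- 1.96 * sample SD.  The
    limits are computed from the data and are not forced symmetric about 0.
    """
    d = percent_differences(pairs)
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias_percent=bias,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        sd_percent=sd,
        n=pairs.n,
    )


def percent_error(test: float, reference: float) -> float:
    """Inter-laboratory percent error, 100*(test - reference)/reference.

    The external laboratory's value is the denominator.
    """
    if reference <= 0:
        raise ConfigurationError("percent_error requires reference > 0")
    return 100.0 * (test - reference) / reference


def specificity_summary(
    panel: SpecificityPanel,
    negligibility_threshold: float = DEFAULT_NEGLIGIBILITY_THRESHOLD,
) -> pd.DataFrame:
    """Relative response of each interferent versus the iron signal.

    An analyte is flagged ``interfering`` when its absorbance exceeds the
    threshold fraction (default 10%) of the iron response.
    """
    rows = []
    for label, (conc, absorbance) in panel.analytes.items():
        ratio = absorbance / panel.iron_response
        rows.append(
            {
                "analyte": label,
                "concentration_mg_dl": conc,
                "absorbance_au": absorbance,
                "relative_response": ratio,
                "interfering": bool(ratio > negligibility_threshold),
            }
        )
    return pd.DataFrame(rows)


class MethodComparison(BaseEstimator):
    """Estimator bundling the regression and percent Bland-Altman analyses.

    ``fit(reference, test)`` computes: ``slope_``, ``intercept_``, ``r_``,
    ``r2_`` (OLS of test on reference) and ``bias_percent_``,
    ``sd_percent_``, ``loa_lower_``, ``loa_upper_`` (percent Bland-Altman).
    """

    def fit(self, X, y):
        pairs = PairedMeasurements(reference=np.asarray(X).reshape(-1), test=np.asarray(y).reshape(-1))
        reg = method_regression(pairs)
        ba = bland_altman_percent(pairs)
        self.slope_ = reg.slope
        self.intercept_ = reg.intercept
        self.r_ = reg.r
        self.r2_ = reg.r2
        self.bias_percent_ = ba.bias_percent
        self.sd_percent_ = ba.sd_percent
        self.loa_lower_ = ba.loa_lower
        self.loa_upper_ = ba.loa_upper
        self.n_ = pairs.n
        self.n_features_in_ = 1
        return self

    def to_dict(self) -> dict:
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "r": self.r_,
            "r2": self.r2_,
            "bias_percent": self.bias_percent_,
            "sd_percent": self.sd_percent_,
            "loa_lower_percent": self.loa_lower_,
            "loa_upper_percent": self.loa_upper_,
            "n": self.n_,
        }
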