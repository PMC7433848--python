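"""Fe(II)-ferene complex-formation kinetics and reaction-order estimation.

With ascorbic acid in large excess the colour-forming reaction reduces to

    Fe(III) + 3 ferene  -->  Fe(II)-(ferene)3          (rate constant k')

and the empirical rate law for the complex COM is

    d[COM]/dt = k' * [Fe3+]^alpha * [ferene]^beta,

with [Fe3+] = iron0 - [COM] and [ferene] = ferene0 - 3[COM] by
stoichiometry.  The absorbance trace follows Beer-Lambert,
A(t) = epsilon * l * [COM](t), with epsilon = 33366 L cm^-1 mol^-1 at
590 nm and a 0.6 cm well path length (epsilon is treated as a supplied
constant).

Orders are estimated the way a bench kineticist would from a 2x2
initial-rate design (two iron levels x two ferene levels): numerical
derivatives of the trace inside the initial-rate window give per-cell
initial rates, and

    alpha = log(r_hiFe / r_loFe) / log(iron_hi / iron_lo)

averaged over ferene levels (beta analogously over iron levels).  A global
log-log regression of the four rates is kept as a secondary estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from sklearn.base import BaseEstimator

from .errors import ComputationError, ConfigurationError

#: Iron molar mass (g/mol), used for the ug/dL <-> mol/L conversion.
IRON_MOLAR_MASS = 55.845

#: 1 ug/dL expressed in mol/L (1e-6 g per 0.1 L, divided by the molar mass).
UG_DL_TO_MOL_L = 1e-5 / IRON_MOLAR_MASS

#: Molar extinction coefficient of the Fe(II)-ferene complex (L cm^-1 mol^-1)
#: and the 250 uL 96-well path length (cm) of the plate reader.
EPSILON_FERENE = 33366.0
WELL_PATH_LENGTH_CM = 0.6
LAMBDA_MAX_NM = 590.0


def ug_dl_to_mol_l(conc_ug_dl: float) -> float:
    """Convert a total-iron concentration from ug/dL to mol/L."""
    return conc_ug_dl * UG_DL_TO_MOL_L


def mol_l_to_ug_dl(conc_mol_l: float) -> float:
    return conc_mol_l / UG_DL_TO_MOL_L


@dataclass(frozen=True)
class KineticConditions:
    """Initial composition and sampling grid of one kinetic run."""

    iron0: float  # mol/L
    ferene0: float  # mol/L
    ascorbic0: float = 20.4e-3  # mol/L; in excess, not dynamically modelled
    duration: float = 120.0  # s
    n_points: int = 1201

    def __post_init__(self) -> None:
        for name in ("iron0", "ferene0", "ascorbic0"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"KineticConditions.{name} must be >= 0")
        if self.duration <= 0:
            raise ConfigurationError("KineticConditions.duration must be > 0")
        if self.n_points < 3:
            raise ConfigurationError("KineticConditions.n_points must be >= 3")
        if self.iron0 > 0 and self.ascorbic0 / self.iron0 < 100:
            warnings.warn(
                "ascorbic0/iron0 < 100: the excess-ascorbate simplification of the "
                "rate law may not hold",
                stacklevel=2,
            )

    @classmethod
    def from_assay(
        cls, iron_ug_dl: float, ferene_mM: float, duration: float = 120.0, n_points: int = 1201
    ) -> "KineticConditions":
        """Conditions from bench units (iron in ug/dL, ferene in mM)."""
        return cls(
            iron0=ug_dl_to_mol_l(iron_ug_dl),
            ferene0=ferene_mM * 1e-3,
            duration=duration,
            n_points=n_points,
        )

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_points)


@dataclass(frozen=True)
class RateLawParams:
    """Empirical rate-law parameters (k', alpha, beta)."""

    k_prime: float
    alpha: float = 1.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        if self.k_prime < 0:
            raise ConfigurationError("RateLawParams.k_prime must be >= 0")
        for name in ("alpha", "beta"):
            if not 0.0 <= getattr(self, name) <= 3.0:
                raise ConfigurationError(f"RateLawParams.{name} must lie in [0, 3]")


@dataclass(frozen=True)
class OpticalConstants:
    epsilon: float = EPSILON_FERENE  # L cm^-1 mol^-1
    path_length: float = WELL_PATH_LENGTH_CM  # cm
    wavelength: float = LAMBDA_MAX_NM  # nm, annotation only

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ConfigurationError("OpticalConstants.epsilon must be > 0")
        if self.path_length <= 0:
            raise ConfigurationError("OpticalConstants.path_length must be > 0")


@dataclass(frozen=True)
class KineticTrace:
    """Time series of complex concentration (mol/L) or absorbance (a.u.)."""

    times: np.ndarray
    values: np.ndarray
    conditions: KineticConditions
    value_kind: str = "concentration_mol_l"  # or "absorbance_au"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise ConfigurationError("KineticTrace.times and values must have equal shape")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("KineticTrace.times must be strictly increasing")
        if self.value_kind not in ("concentration_mol_l", "absorbance_au"):
            raise ConfigurationError("KineticTrace.value_kind unknown")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "value": self.values, "value_kind": self.value_kind}
        )


@dataclass(frozen=True)
class RateSeries:
    times: np.ndarray
    rates: np.ndarray


@dataclass(frozen=True)
class RateLawEstimate:
    alpha: float
    beta: float
    k_prime: float
    cell_rates: pd.DataFrame
    residuals: np.ndarray
    alpha_loglog: float
    beta_loglog: float
    k_prime_loglog: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "k_prime": self.k_prime,
            "alpha_loglog": self.alpha_loglog,
            "beta_loglog": self.beta_loglog,
            "k_prime_loglog": self.k_prime_loglog,
            "cells": self.cell_rates.to_dict(orient="records"),
            "relative_residuals": self.residuals.tolist(),
        }


def simulate_complex_formation(
    conditions: KineticConditions, params: RateLawParams
) -> KineticTrace:
    """Integrate the rate law for [COM](t) on the conditions' time grid.

    The state is the complex concentration alone; iron and ferene follow by
    conservation.  Adaptive LSODA integration with tight tolerances keeps
    the endpoint stable to < 1e-6 relative under grid refinement.
    """
    iron0, ferene0 = conditions.iron0, conditions.ferene0
    com_max = min(iron0, ferene0 / 3.0)

    def rhs(_t, y):
        com = min(y[0], com_max)
        fe = max(iron0 - com, 0.0)
        fer = max(ferene0 - 3.0 * com, 0.0)
        return [params.k_prime * fe**params.alpha * fer**params.beta]

    times = conditions.times
    if params.k_prime == 0 or com_max == 0:
        com = np.zeros_like(times)
    else:
        sol = solve_ivp(
            rhs,
            (times[0], times[-1]),
            [0.0],
            t_eval=times,
            method="LSODA",
            rtol=1e-10,
            atol=1e-14 * max(com_max, 1.0),
        )
        if not sol.success:
            raise ComputationError(f"kinetic integration failed: {sol.message}")
        com = sol.y[0]
        if np.any(com < -1e-12 * com_max):
            warnings.warn("negative complex concentration clamped to 0", stacklevel=2)
        com = np.clip(com, 0.0, com_max)
    return KineticTrace(times=times, values=com, conditions=conditions)


def absorbance_from_complex(trace: KineticTrace, optics: OpticalConstants) -> KineticTrace:
    """Beer-Lambert forward transform A(t) = epsilon * l * [COM](t)."""
    if trace.value_kind != "concentration_mol_l":
        raise ConfigurationError("trace is already absorbance-valued")
    return replace(
        trace, values=optics.epsilon * optics.path_length * trace.values,
        value_kind="absorbance_au",
    )


def complex_from_absorbance(trace: KineticTrace, optics: OpticalConstants) -> KineticTrace:
    """Inverse Beer-Lambert transform; round-trips to machine precision."""
    if trace.value_kind != "absorbance_au":
        raise ConfigurationError("trace is already concentration-valued")
    return replace(
        trace, values=trace.values / (optics.epsilon * optics.path_length),
        value_kind="concentration_mol_l",
    )


def estimate_rates(trace: KineticTrace, smoothing_window: int = 1) -> RateSeries:
    """Numerical time derivative of a trace.

    The trace is optionally smoothed by a centred moving average of odd
    width, then differentiated by central differences (one-sided at the
    endpoints).
    """
    if trace.times.size < 3:
        raise ConfigurationError("estimate_rates needs >= 3 points")
    w = smoothing_window
    if w < 1 or w % 2 == 0 or w >= trace.times.size:
        raise ConfigurationError(
            "smoothing_window must be odd, >= 1 and shorter than the trace"
        )
    values = trace.values
    if w > 1:
        pad = w // 2
        padded = np.pad(values, pad, mode="edge")
        values = np.convolve(padded, np.ones(w) / w, mode="valid")
    rates = np.gradient(values, trace.times)
    return RateSeries(times=trace.times, rates=rates)


def _initial_rate(
    trace: KineticTrace,
    window_fraction: float,
    smoothing_window: int,
    rate_method: str = "poly",
) -> float:
    """Initial rate d[COM]/dt at t = 0 from the low-conversion window.

    The window is the contiguous run of points from t = 0 whose conversion
    stays below ``window_fraction`` of the initial iron.  Two estimators:

    * ``"poly"`` (default): fit a quadratic (linear for very short windows)
      to the progress curve inside the window and take its slope at t = 0.
      This is a local-polynomial smoothed derivative; it tolerates
      measurement noise far better than differencing the raw trace.
    * ``"derivative"``: central-difference rates from
      :func:`estimate_rates` inside the window, extrapolated linearly back
      to t = 0 so depletion inside the window does not bias the estimate.
    """
    iron0 = trace.conditions.iron0
    exceed = np.flatnonzero(trace.values > window_fraction * iron0)
    end = int(exceed[0]) if exceed.size else trace.values.size
    end = max(end, 3)
    t_w = trace.times[:end]
    if rate_method == "poly":
        v_w = trace.values[:end]
        deg = 2 if t_w.size >= 8 else 1
        return float(np.polyfit(t_w, v_w, deg)[-2])
    if rate_method == "derivative":
        series = estimate_rates(trace, smoothing_window=smoothing_window)
        r_w = series.rates[:end]
        if t_w.size >= 3 and np.ptp(t_w) > 0:
            return float(np.polyfit(t_w, r_w, 1)[1])
        return float(r_w.mean())
    raise ConfigurationError("rate_method must be 'poly' or 'derivative'")


class RateLawEstimator(BaseEstimator):
    """Initial-rate estimator of (alpha, beta, k') from a 2x2 kinetic design.

    Parameters
    ----------
    window_fraction : float, default 0.10
        Fraction of the initial iron that may be converted inside the
        initial-rate window.
    smoothing_window : int, default 1
        Odd moving-average width applied before differentiation (useful for
        noisy absorbance traces).

    ``fit`` expects concentration-valued traces at two iron levels crossed
    with two ferene levels.  Fitted attributes: ``alpha_``, ``beta_``,
    ``k_prime_``, per-cell ``cell_rates_`` and relative ``residuals_``, plus
    ``alpha_loglog_``/``beta_loglog_``/``k_prime_loglog_`` from the global
    log-log regression cross-check.
    """

    def __init__(
        self,
        window_fraction: float = 0.10,
        smoothing_window: int = 1,
        rate_method: str = "poly",
    ):
        self.window_fraction = window_fraction
        self.smoothing_window = smoothing_window
        self.rate_method = rate_method

    def fit(self, X, y=None):
        traces = list(X)
        if len(traces) != 4:
            raise ConfigurationError("fit needs exactly the 4 traces of a 2x2 design")
        for tr in traces:
            if tr.value_kind != "concentration_mol_l":
                raise ConfigurationError(
                    "traces must be concentration-valued; apply complex_from_absorbance first"
                )
        irons = sorted({tr.conditions.iron0 for tr in traces})
        ferenes = sorted({tr.conditions.ferene0 for tr in traces})
        if len(irons) != 2 or len(ferenes) != 2:
            raise ConfigurationError("design must cross two iron levels with two ferene levels")
        rates = {}
        for tr in traces:
            r = _initial_rate(
                tr, self.window_fraction, self.smoothing_window, rate_method=self.rate_method
            )
            if r <= 0:
                raise ComputationError("non-positive initial rate; cannot take logarithms")
            rates[(tr.conditions.iron0, tr.conditions.ferene0)] = r

        alpha = np.mean(
            [
                np.log(rates[(irons[1], f)] / rates[(irons[0], f)])
                / np.log(irons[1] / irons[0])
                for f in ferenes
            ]
        )
        beta = np.mean(
            [
                np.log(rates[(fe, ferenes[1])] / rates[(fe, ferenes[0])])
                / np.log(ferenes[1] / ferenes[0])
                for fe in irons
            ]
        )
        k_cells = [r / (fe**alpha * f**beta) for (fe, f), r in rates.items()]
        k_prime = float(np.mean(k_cells))

        cells = pd.DataFrame(
            [
                {
                    "iron0_mol_l": fe,
                    "ferene0_mol_l": f,
                    "initial_rate_mol_l_s": r,
                    "predicted_rate_mol_l_s": k_prime * fe**alpha * f**beta,
                }
                for (fe, f), r in sorted(rates.items())
            ]
        )
        resid = (
            cells["initial_rate_mol_l_s"] / cells["predicted_rate_mol_l_s"] - 1.0
        ).to_numpy()

        # secondary estimator: one global log-linear fit of all four rates
        design = np.column_stack(
            [np.ones(4), np.log(cells["iron0_mol_l"]), np.log(cells["ferene0_mol_l"])]
        )
        coef, *_ = np.linalg.lstsq(design, np.log(cells["initial_rate_mol_l_s"]), rcond=None)

        self.alpha_ = float(alpha)
        self.beta_ = float(beta)
        self.k_prime_ = k_prime
        self.cell_rates_ = cells
        self.residuals_ = resid
        self.k_prime_loglog_ = float(np.exp(coef[0]))
        self.alpha_loglog_ = float(coef[1])
        self.beta_loglog_ = float(coef[2])
        self.n_features_in_ = 4
        return self

    def estimate_(self) -> RateLawEstimate:
        return RateLawEstimate(
            alpha=self.alpha_,
            beta=self.beta_,
            k_prime=self.k_prime_,
            cell_rates=self.cell_rates_,
            residuals=self.residuals_,
            alpha_loglog=self.alpha_loglog_,
            beta_loglog=self.beta_loglog_,
            k_prime_loglog=self.k_prime_loglog_,
        )


def fit_reaction_orders(
    traces,
    window_fraction: float = 0.10,
    smoothing_window: int = 1,
    rate_method: str = "poly",
) -> RateLawEstimate:
    """Functional wrapper over :class:`RateLawEstimator`."""
    est = RateLawEstimator(
        window_fraction=window_fraction,
        smoothing_window=smoothing_window,
        rate_method=rate_method,
    ).fit(traces)
    return est.estimate_()


# ---------------------------------------------------------------------------
# Reagent schemes and molar-ratio accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReagentScheme:
    """Mixing scheme of one assay variant.

    Reagent A carries citric acid (strips Fe(III) from transferrin),
    ascorbic acid (reduces Fe(III) to Fe(II)) and thiourea (masks Cu(II));
    reagent B is the ferene chromophore.  For the dry strip, ``dried=True``
    means the reagent loads are dried-down volume equivalents rehydrated by
    the sample alone, so the final volume is the sample volume.
    """

    label: str
    volume_reagent_a_ul: float
    volume_reagent_b_ul: float
    volume_sample_ul: float
    citric_stock_mM: float = 200.0
    ascorbic_stock_mM: float = 34.0
    thiourea_stock_mM: float = 100.0
    ferene_stock_mM: float = 4.0
    sample_iron_ug_dl: float = 100.0
    dried: bool = False

    def __post_init__(self) -> None:
        for name in ("volume_reagent_a_ul", "volume_reagent_b_ul", "volume_sample_ul"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"ReagentScheme.{name} must be > 0")

    @property
    def final_volume_ul(self) -> float:
        if self.dried:
            return self.volume_sample_ul
        return self.volume_reagent_a_ul + self.volume_reagent_b_ul + self.volume_sample_ul


#: Reference spectrophotometric scheme: reagent A : ferene : sample = 5:1:1
#: in a 250 uL well (sample ~36 uL into ~214 uL of reagents).
ORIGINAL_SCHEME = ReagentScheme(
    label="original",
    volume_reagent_a_ul=250.0 * 5 / 7,
    volume_reagent_b_ul=250.0 / 7,
    volume_sample_ul=250.0 / 7,
)

#: Optimized scheme: 3:1:1 (surfactant removed, relatively more iron and
#: ferene), 50 uL sample into 200 uL of reagents.
OPTIMIZED_SCHEME = ReagentScheme(
    label="optimized",
    volume_reagent_a_ul=150.0,
    volume_reagent_b_ul=50.0,
    volume_sample_ul=50.0,
)

#: Dry sensor strip: 30 uL sample rehydrates reagents dried at a nominal
#: 3:1 A:B volume-equivalent load (synthetic assumption; the true loading
#: of the strips is proprietary to their fabrication).
STRIP_SCHEME = ReagentScheme(
    label="strip",
    volume_reagent_a_ul=120.0,
    volume_reagent_b_ul=40.0,
    volume_sample_ul=30.0,
    dried=True,
)

SCHEME_PRESETS = {s.label: s for s in (ORIGINAL_SCHEME, OPTIMIZED_SCHEME, STRIP_SCHEME)}


def compute_molar_ratios(scheme: ReagentScheme) -> pd.DataFrame:
    """Final mixed concentration of every reagent and its molar ratio to iron.

    Each stock is diluted by its volume fraction of the final mix; the iron
    molarity comes from the ug/dL sample concentration diluted likewise.
    """
    if scheme.sample_iron_ug_dl <= 0:
        raise ConfigurationError(
            "ReagentScheme.sample_iron_ug_dl must be > 0 (ratio to iron undefined)"
        )
    v_final = scheme.final_volume_ul
    f_a = scheme.volume_reagent_a_ul / v_final
    f_b = scheme.volume_reagent_b_ul / v_final
    f_s = scheme.volume_sample_ul / v_final
    iron_mol_l = ug_dl_to_mol_l(scheme.sample_iron_ug_dl) * f_s
    rows = [
        ("citric_acid", scheme.citric_stock_mM * 1e-3 * f_a),
        ("ascorbic_acid", scheme.ascorbic_stock_mM * 1e-3 * f_a),
        ("thiourea", scheme.thiourea_stock_mM * 1e-3 * f_a),
        ("ferene", scheme.ferene_stock_mM * 1e-3 * f_b),
    ]
    return pd.DataFrame(
        [
            {
                "species": name,
                "final_mol_l": conc,
                "ratio_to_iron": conc / iron_mol_l,
            }
            for name, conc in rows
        ]
        + [{"species": "iron", "final_mol_l": iron_mol_l, "ratio_to_iron": 1.0}]
    )
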