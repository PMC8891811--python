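"""Skull-thickness attenuation statistics and the exponential transmission law.

The central quantity is the transmitted-pressure percentage

    tau(z) = 100 * P_z / P_water,

the peak focal pressure behind a skull slab of thickness ``z`` (mm)
relative to the same source radiating in pure water.  System
identification on simulated thickness sweeps shows tau follows an
exponential decay law

    tau(z) = a * exp(-b * z)        [percent, z in mm],

with published reference coefficients a = 61.85 %, b = 0.2537 /mm.
Because the law is a pure ratio, site-to-site pressure prediction
depends only on the decay coefficient:

    P(x2) = P(x1) * tau(x2) / tau(x1) = P(x1) * exp(-b * (x2 - x1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

#: Reference coefficients of the identified exponential transmission law.
REFERENCE_A = 61.85   # percent at zero thickness (extrapolated intercept)
REFERENCE_B = 0.2537  # 1/mm decay coefficient


@dataclass(frozen=True)
class ThicknessSample:
    """One (skull thickness, transmission) observation.

    ``transmission_percent`` is tau in [0, 100]; ``transmitted_peak`` (Pa)
    is optional raw pressure; ``provenance`` labels the source of the
    record: ``"simulation"``, ``"phantom"`` or ``"synthetic"``.
    """

    thickness_mm: float
    transmission_percent: float
    transmitted_peak: float | None = None
    provenance: str = "simulation"

    def __post_init__(self) -> None:
        if self.thickness_mm < 0:
            raise ValueError("thickness must be >= 0")
        if not (0.0 <= self.transmission_percent <= 100.0):
            raise ValueError("transmission_percent must lie in [0, 100]")

    @property
    def attenuation_percent(self) -> float:
        return 100.0 - self.transmission_percent


@dataclass(frozen=True)
class AttenuationFit:
    """Identified exponential law tau(z) = a * exp(-b z) with fit quality."""

    a: float
    b: float
    r_squared: float = float("nan")
    residuals: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be > 0 for a decaying transmission")


#: The published model coefficients, used as the default for validation.
REFERENCE_FIT = AttenuationFit(a=REFERENCE_A, b=REFERENCE_B, r_squared=0.9996)


@dataclass(frozen=True)
class ReferencePressure:
    """Free-water focal peak used as the attenuation reference."""

    p_water: float
    excitation: str = ""
    provenance: str = "phantom"

    def __post_init__(self) -> None:
        if self.p_water <= 0:
            raise ValueError("p_water must be > 0")


def tau_model(z_mm: float | np.ndarray, fit: AttenuationFit = REFERENCE_FIT):
    """Transmitted-pressure percentage at skull thickness ``z_mm`` (mm)."""
    z = np.asarray(z_mm, dtype=float)
    if np.any(z < 0):
        raise ValueError("thickness must be >= 0")
    out = fit.a * np.exp(-fit.b * z)
    return float(out) if np.isscalar(z_mm) else out


def attenuation_percent(z_mm, fit: AttenuationFit = REFERENCE_FIT):
    """Attenuation percentage 100 - tau(z)."""
    tau = tau_model(z_mm, fit)
    return 100.0 - tau


def attenuation_pressure(
    p_water: float, z_mm: float, fit: AttenuationFit = REFERENCE_FIT
) -> tuple[float, float]:
    """Absolute attenuation and transmitted pressure at thickness ``z_mm``.

    Returns ``(A_z, P_z)`` in Pa, with ``A_z = P_water * (1 - tau/100)``
    and ``P_z = P_water * tau/100``.
    """
    if p_water < 0:
        raise ValueError("p_water must be >= 0")
    frac = tau_model(z_mm, fit) / 100.0
    return p_water * (1.0 - frac), p_water * frac


def tau_from_measurement(p_z: float, p_water: float) -> float:
    """Measured transmission percentage 100 * P_z / P_water."""
    if p_water <= 0:
        raise ValueError("reference pressure must be > 0")
    if p_z < 0:
        raise ValueError("transmitted pressure must be >= 0")
    return 100.0 * p_z / p_water


def attenuation_from_measurement(p_z: float, p_water: float) -> float:
    """Measured attenuation percentage 100 * (1 - P_z / P_water)."""
    return 100.0 - tau_from_measurement(p_z, p_water)


class FitError(RuntimeError):
    """Nonlinear fit failure; carries the log-linear fallback coefficients."""

    def __init__(self, message: str, fallback: AttenuationFit | None = None):
        super().__init__(message)
        self.fallback = fallback


def _loglinear_seed(z: np.ndarray, tau: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(z, np.log(tau), 1)
    return math.exp(intercept), -slope


def fit_attenuation(samples: Sequence[ThicknessSample]) -> AttenuationFit:
    """Identify tau(z) = a * exp(-b z) by nonlinear least squares.

    The fit is performed on the tau values themselves (not their logs),
    seeded by a log-linear regression.  Reports R^2 against the sample
    mean and per-sample residuals (observed - fitted).

    Raises
    ------
    FitError
        On non-convergence (the log-linear fallback rides along) or a
        degenerate thickness spread.
    ValueError
        Fewer than three samples or a thickness span below 1 mm.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to identify the law")
    z = np.array([s.thickness_mm for s in samples], dtype=float)
    tau = np.array([s.transmission_percent for s in samples], dtype=float)
    if np.ptp(z) <= 1.0:
        raise ValueError("thickness span must exceed 1 mm")
    if np.any(tau <= 0):
        raise FitError("non-positive transmission values cannot be fitted")

    a0, b0 = _loglinear_seed(z, tau)
    if b0 <= 0:
        raise FitError("samples do not decay with thickness; fit degenerate")
    try:
        (a, b), _ = curve_fit(
            lambda x, a, b: a * np.exp(-b * x), z, tau,
            p0=(a0, b0), maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"nonlinear least squares did not converge: {exc}",
            fallback=AttenuationFit(a=a0, b=b0),
        ) from exc
    if a <= 0 or b <= 1e-12:
        raise FitError("fitted law does not decay; identification degenerate")

    fitted = a * np.exp(-b * z)
    resid = tau - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((tau - tau.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return AttenuationFit(a=float(a), b=float(b), r_squared=r2,
                          residuals=tuple(float(x) for x in resid))


def predict_pressure(
    p_x1: float, x1_mm: float, x2_mm: float, fit: AttenuationFit = REFERENCE_FIT
) -> float:
    """Predict the transcranial peak at thickness ``x2`` from one at ``x1``.

    ``P_x2 = P_x1 * tau(x2)/tau(x1)``; the amplitude coefficient cancels,
    so the prediction equals ``P_x1 * exp(-b (x2 - x1))``.
    """
    if p_x1 < 0:
        raise ValueError("anchor pressure must be >= 0")
    t1 = tau_model(x1_mm, fit)
    if t1 == 0.0:
        raise ZeroDivisionError("tau(x1) is zero; prediction undefined")
    return p_x1 * (tau_model(x2_mm, fit) / t1)


def relative_error(model_value: float, reference_value: float) -> float:
    """Percent disagreement with the model value as the denominator.

    ``100 * |model - reference| / model`` — the bookkeeping convention
    that reproduces the published per-site error figures.
    """
    if model_value == 0:
        raise ZeroDivisionError("model value must be nonzero")
    return 100.0 * abs(model_value - reference_value) / abs(model_value)


def correlation(series_a: Sequence[float], series_b: Sequence[float]) -> float:
    """Pearson correlation coefficient between two equal-length series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal lengths")
    if a.size < 2:
        raise ValueError("need at least two points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("series must have nonzero variance")
    return float(np.corrcoef(a, b)[0, 1])
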