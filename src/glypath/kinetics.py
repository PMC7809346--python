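"""Enzyme kinetics: intensity calibration, Michaelis–Menten fits, Eyring link.

Product release monitored by quantitative mass spectrometry is calibrated by
plotting the product/internal-standard intensity ratio against known product
concentrations; initial velocities are then fit to the Michaelis–Menten form
v0/[E] = kcat·[S]/(K_M + [S]).  Transition-state theory (the Eyring
equation, transmission coefficient 1) converts a turnover rate into an
apparent activation free energy ΔG‡ = RT·ln(k_B·T/(h·k)) and back, linking
the measured kcat to computed reaction barriers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

R_KCAL = 0.0019872          # gas constant, kcal mol^-1 K^-1
KB_OVER_H = 2.0836619e10    # k_B / h, s^-1 K^-1
DEFAULT_ASSAY_T = 313.15    # K (40 °C, standard assay temperature here)


class KineticsError(RuntimeError):
    """Raised for unusable kinetics data or failed fits."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line: intensity ratio = slope × concentration + intercept."""

    slope: float        # ratio per mM
    intercept: float
    r_squared: float

    def apply(self, ratio) -> np.ndarray:
        """Invert the calibration: intensity ratio -> concentration (mM)."""
        return (np.asarray(ratio, dtype=float) - self.intercept) / self.slope


def fit_calibration(concentrations, ratios) -> CalibrationCurve:
    """Fit the internal-standard calibration line (free intercept).

    Requires at least 3 points with non-zero concentration variance.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if c.size < 3:
        raise KineticsError("need at least 3 calibration points")
    if np.std(c) == 0:
        raise KineticsError("calibration concentrations have zero variance")
    res = stats.linregress(c, r)
    return CalibrationCurve(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2))


@dataclass(frozen=True)
class MMFit:
    """Michaelis–Menten parameters from a v0/[E] vs [S] fit."""

    kcat: float            # s^-1
    km: float              # mM
    kcat_se: float
    km_se: float
    saturating: bool       # False when the data never approach Vmax

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/K_M (s^-1 mM^-1)."""
        return self.kcat / self.km


def fit_mm(concentrations, velocities) -> MMFit:
    """Nonlinear least-squares Michaelis–Menten fit.

    ``velocities`` are v0/[E] (units of s^-1).  Warns when fewer than 4
    distinct concentrations are supplied or when the data do not span K_M on
    both sides; flags non-saturating designs (max [S] < 2·K_M), for which
    only kcat/K_M is reliably identified.
    """
    s = np.asarray(concentrations, dtype=float)
    v = np.asarray(velocities, dtype=float)
    distinct = np.unique(s)
    if distinct.size < 4:
        warnings.warn("fewer than 4 substrate concentrations: MM fit is fragile", stacklevel=2)

    def mm(sv, kcat, km):
        return kcat * sv / (km + sv)

    p0 = (float(v.max()) * 1.2 or 1.0, float(np.median(s)))
    try:
        popt, pcov = optimize.curve_fit(mm, s, v, p0=p0, maxfev=10_000)
    except RuntimeError as exc:
        raise KineticsError(f"Michaelis–Menten fit did not converge: {exc}") from None
    kcat, km = (float(p) for p in popt)
    if kcat <= 0 or km <= 0:
        raise KineticsError(f"non-physical fit: kcat={kcat:.3g}, km={km:.3g}")
    se = np.sqrt(np.diag(pcov))
    saturating = bool(distinct.max() >= 2.0 * km)
    if not saturating:
        warnings.warn(
            "saturation not reached (max [S] < 2 K_M); only kcat/K_M is well determined",
            stacklevel=2,
        )
    if not (distinct.min() < km < distinct.max()):
        warnings.warn("concentrations do not bracket K_M; estimates are extrapolated",
                      stacklevel=2)
    return MMFit(kcat=kcat, km=km, kcat_se=float(se[0]), km_se=float(se[1]),
                 saturating=saturating)


@dataclass(frozen=True)
class EyringParams:
    """A (rate, ΔG‡) pair consistent under transition-state theory."""

    temperature: float     # K
    rate: float            # s^-1
    delta_g: float         # kcal/mol
    transmission: float = 1.0


def eyring_barrier(rate: float, temperature: float = DEFAULT_ASSAY_T) -> float:
    """Apparent activation free energy (kcal/mol) from a first-order rate.

    ΔG‡ = RT·ln(k_B·T / (h·k)), transmission coefficient 1.
    """
    if rate <= 0 or temperature <= 0:
        raise ValueError("rate and temperature must be positive")
    return R_KCAL * temperature * math.log(KB_OVER_H * temperature / rate)


def eyring_rate(delta_g: float, temperature: float = DEFAULT_ASSAY_T) -> float:
    """First-order rate (s^-1) from an activation free energy; exact inverse."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_OVER_H * temperature * math.exp(-delta_g / (R_KCAL * temperature))


def eyring_params(rate: float, temperature: float = DEFAULT_ASSAY_T) -> EyringParams:
    return EyringParams(temperature=temperature, rate=rate,
                        delta_g=eyring_barrier(rate, temperature))
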