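"""Multi-temperature analysis of exchange parameters.

Two-state van't Hoff analysis extracts the standard enthalpy and entropy of
the ground-to-excited-state equilibrium from the temperature dependence of the
excited-state population, ln K = ln(p_b/(1-p_b)) = -dH/(R T) + dS/R.  An
Eyring-type analysis of the forward (or backward) rate, ln(k/T) =
ln(kB/h) + dS'/R - dH'/(R T), extracts the transition enthalpy dH' (the
transmission coefficient is fixed at 1, which shifts dS' only).  The two are
linked by the thermodynamic cycle dH = dH'_forward - dH'_backward, which
holds exactly for any series generated from a single free-energy surface and
is used both as a correctness check and to adjudicate between alignment
protocols of slow-exchange dispersion fits.

Units: temperatures in K (converted from deg C in exactly one place,
:func:`celsius_to_kelvin`), dH in kcal/mol, dS in cal/mol/K,
R = 1.98720425 cal/mol/K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "R_CAL",
    "KB_OVER_H",
    "ThermoSeries",
    "ThermoFit",
    "celsius_to_kelvin",
    "vant_hoff",
    "eyring_barrier",
    "series_from_energies",
]

R_CAL = 1.98720425  # cal / mol / K
KB_OVER_H = 2.0836619123e10  # Boltzmann/Planck, 1 / (s K)


def celsius_to_kelvin(t_celsius: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(t_celsius, dtype=float) + 273.15


@dataclass(frozen=True)
class ThermoSeries:
    """Temperature series of populations and rates for one spin."""

    temperatures: tuple[float, ...]  # K, strictly increasing
    p_b: tuple[float, ...] | None = None
    p_b_sd: tuple[float, ...] | None = None
    k1: tuple[float, ...] | None = None
    k1_sd: tuple[float, ...] | None = None
    k_minus1: tuple[float, ...] | None = None
    k_minus1_sd: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        T = self.temperatures
        if len(T) < 2:
            raise ValueError("need at least 2 temperatures")
        if any(b <= a for a, b in zip(T, T[1:])):
            raise ValueError("temperatures must be strictly increasing (K)")
        for name in ("p_b", "p_b_sd", "k1", "k1_sd", "k_minus1", "k_minus1_sd"):
            v = getattr(self, name)
            if v is not None and len(v) != len(T):
                raise ValueError(f"{name} must match temperatures in length")
        if self.p_b is not None and any(not (0 < p <= 0.5) for p in self.p_b):
            raise ValueError("populations must lie in (0, 0.5]")


@dataclass(frozen=True)
class ThermoFit:
    """Linear van't Hoff or Eyring fit result.

    ``delta_h``/``delta_s`` hold the standard enthalpy (kcal/mol) and entropy
    (cal/mol/K) for a van't Hoff fit; ``delta_h_barrier``/``delta_s_barrier``
    hold the Eyring transition values (dS' assumes unit transmission and is
    flagged accordingly in ``note``).  ``r_squared`` is the linearity
    diagnostic of the fit line.
    """

    kind: str
    delta_h: float | None = None
    delta_s: float | None = None
    delta_h_se: float | None = None
    delta_s_se: float | None = None
    delta_h_barrier: float | None = None
    delta_s_barrier: float | None = None
    delta_h_barrier_se: float | None = None
    r_squared: float = 1.0
    slope: float = 0.0
    intercept: float = 0.0
    weighted: bool = True
    note: str = ""

    @property
    def delta_h_forward_barrier(self) -> float | None:
        return self.delta_h_barrier

    def line(self, inv_T: np.ndarray) -> np.ndarray:
        """Reconstructed fit line evaluated at 1/T."""
        return self.slope * np.asarray(inv_T) + self.intercept


def _weighted_line(x: np.ndarray, y: np.ndarray, sy: np.ndarray | None):
    """Weighted linear fit y = a x + b; returns a, b, se_a, se_b, R^2, weighted."""
    weighted = bool(sy is not None and np.all(np.asarray(sy) > 0))
    w = 1.0 / np.asarray(sy) ** 2 if weighted else np.ones_like(y)
    W = w.sum()
    xb = (w * x).sum() / W
    yb = (w * y).sum() / W
    sxx = (w * (x - xb) ** 2).sum()
    sxy = (w * (x - xb) * (y - yb)).sum()
    a = sxy / sxx
    b = yb - a * xb
    resid = y - (a * x + b)
    if weighted:
        var_a = 1.0 / sxx
        var_b = 1.0 / W + xb**2 / sxx
    else:
        dof = max(len(x) - 2, 1)
        s2 = (resid**2).sum() / dof if len(x) > 2 else np.nan
        var_a = s2 / sxx
        var_b = s2 * (1.0 / W + xb**2 / sxx)
    syy = (w * (y - yb) ** 2).sum()
    r2 = 1.0 - (w * resid**2).sum() / syy if syy > 0 else 1.0
    return a, b, float(np.sqrt(var_a)), float(np.sqrt(var_b)), float(r2), weighted


def vant_hoff(series: ThermoSeries) -> ThermoFit:
    """Two-state van't Hoff fit of ln(p_b/(1-p_b)) against 1/T.

    slope = -dH/R and intercept = dS/R, weighted by the population standard
    deviations when available (propagated as s_lnK = s_p / (p(1-p))); missing
    s.d.s fall back to an unweighted fit with a warning.
    """
    if series.p_b is None:
        raise ValueError("van't Hoff analysis needs populations")
    T = np.asarray(series.temperatures)
    p = np.asarray(series.p_b)
    x = 1.0 / T
    y = np.log(p / (1.0 - p))
    sy = None
    if series.p_b_sd is not None and np.all(np.asarray(series.p_b_sd) > 0):
        sy = np.asarray(series.p_b_sd) / (p * (1.0 - p))
    else:
        warnings.warn("no population s.d. supplied; unweighted van't Hoff fit", stacklevel=2)
    a, b, se_a, se_b, r2, weighted = _weighted_line(x, y, sy)
    return ThermoFit(
        kind="vant_hoff",
        delta_h=-a * R_CAL / 1000.0,
        delta_s=b * R_CAL,
        delta_h_se=se_a * R_CAL / 1000.0,
        delta_s_se=se_b * R_CAL,
        r_squared=r2,
        slope=a,
        intercept=b,
        weighted=weighted,
        note="ln(p_b/(1-p_b)) vs 1/T; slope=-dH/R, intercept=dS/R",
    )


def eyring_barrier(series: ThermoSeries, which: str = "forward") -> ThermoFit:
    """Transition enthalpy from an Eyring fit of ln(k/T) against 1/T.

    Uses k1 (``which='forward'``) or k_minus1 (``'backward'``);
    dH' = -R * slope, dS' = R * (intercept - ln(kB/h)) under unit
    transmission.  Rates propagate their s.d.s as s_ln k = s_k / k.
    """
    if which == "forward":
        k, sk = series.k1, series.k1_sd
    elif which == "backward":
        k, sk = series.k_minus1, series.k_minus1_sd
    else:
        raise ValueError("which must be 'forward' or 'backward'")
    if k is None:
        raise ValueError(f"Eyring analysis needs {which} rates")
    k = np.asarray(k)
    if np.any(k <= 0):
        raise ValueError("rates must be positive for an Eyring fit")
    T = np.asarray(series.temperatures)
    x = 1.0 / T
    y = np.log(k / T)
    sy = None
    if sk is not None and np.all(np.asarray(sk) > 0):
        sy = np.asarray(sk) / k
    a, b, se_a, _, r2, weighted = _weighted_line(x, y, sy)
    return ThermoFit(
        kind=f"eyring_{which}",
        delta_h_barrier=-a * R_CAL / 1000.0,
        delta_s_barrier=(b - np.log(KB_OVER_H)) * R_CAL,
        delta_h_barrier_se=se_a * R_CAL / 1000.0,
        r_squared=r2,
        slope=a,
        intercept=b,
        weighted=weighted,
        note="ln(k/T) vs 1/T; dH'=-R*slope; dS' assumes transmission coefficient 1",
    )


def series_from_energies(
    temperatures_k: Sequence[float],
    delta_h: float,
    delta_s: float,
    delta_h_forward: float,
    delta_s_forward: float = -5.0,
) -> ThermoSeries:
    """Exact population/rate series from one free-energy surface.

    Populations follow K = exp(-dH/RT + dS/R) with p_b = K/(1+K); forward
    rates follow the Eyring equation with barrier (dH', dS'); backward rates
    are k1/K so that the thermodynamic cycle closes by construction.  dH, dH'
    in kcal/mol; dS, dS' in cal/mol/K.
    """
    T = np.asarray(temperatures_k, dtype=float)
    lnK = -delta_h * 1000.0 / (R_CAL * T) + delta_s / R_CAL
    K = np.exp(lnK)
    p_b = K / (1.0 + K)
    k1 = KB_OVER_H * T * np.exp(-delta_h_forward * 1000.0 / (R_CAL * T) + delta_s_forward / R_CAL)
    km1 = k1 / K
    return ThermoSeries(
        temperatures=tuple(T),
        p_b=tuple(p_b),
        k1=tuple(k1),
        k_minus1=tuple(km1),
    )
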