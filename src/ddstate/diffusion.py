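"""Translational diffusion from pulsed-field-gradient NMR.

A stimulated-echo experiment with gradient pulses of strength ``g``,
duration ``delta`` and diffusion delay ``Delta`` attenuates the signal of a
species with diffusion coefficient ``D`` following the Stejskal-Tanner law

    I(g) = I0 * exp(-D * (gamma * g * delta * s)^2 * (Delta - delta/3)),

where ``gamma`` is the gyromagnetic ratio of the observed nucleus and ``s``
a gradient shape factor (1 for rectangular pulses, 2/pi for sine-shaped).
Fitting the attenuation over a gradient ramp yields ``D``; repeating at
several protein concentrations and extrapolating linearly to zero
concentration yields the self-diffusion coefficient at infinite dilution
``D0``, free of obstruction and crowding effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import GAMMA_H1
from .relaxation import FitError

__all__ = [
    "GradientSeries",
    "DilutionSeries",
    "stejskal_tanner_fit",
    "extrapolate_D0",
]


@dataclass(frozen=True)
class GradientSeries:
    """Echo intensities over a gradient ramp with acquisition parameters."""

    gradient_strengths: np.ndarray  # T m^-1, strictly increasing
    intensities: np.ndarray  # a.u.
    delta: float  # gradient pulse length, s
    Delta: float  # diffusion delay, s
    gamma: float = GAMMA_H1  # rad s^-1 T^-1 (1H observed by default)
    shape_factor: float = 1.0  # 1 rectangular, 2/pi sine

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "gradient_strengths", np.asarray(self.gradient_strengths, dtype=float)
        )
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        g, y = self.gradient_strengths, self.intensities
        if g.size < 5:
            raise ValueError(f"need >= 5 gradient points, got {g.size}")
        if np.any(np.diff(g) <= 0):
            raise ValueError("gradient strengths must be strictly increasing")
        if g.size != y.size:
            raise ValueError("gradients and intensities must have equal length")
        if not (0 < self.delta < self.Delta):
            raise ValueError(
                f"require 0 < delta < Delta, got delta={self.delta}, Delta={self.Delta}"
            )
        if y[0] <= 0:
            raise ValueError("intensity at minimum gradient must be positive")

    @property
    def b_values(self) -> np.ndarray:
        """Diffusion weighting ``b(g) = (gamma g delta s)^2 (Delta - delta/3)``, s m^-2."""
        q = self.gamma * self.gradient_strengths * self.delta * self.shape_factor
        return q**2 * (self.Delta - self.delta / 3.0)


def stejskal_tanner_fit(series: GradientSeries) -> tuple[float, float, float]:
    """Least-squares estimate of the diffusion coefficient from one ramp.

    Returns ``(D, D_stderr, I0)`` with ``D`` in m^2 s^-1.  A warning is
    emitted when the attenuation is non-monotone beyond ~5x the residual
    scatter, which usually indicates convection or phase instability.
    """
    b, y = series.b_values, series.intensities
    pos = y > 0
    if pos.sum() < 3:
        raise FitError("too few positive intensities for a diffusion fit")
    slope, icept = np.polyfit(b[pos], np.log(y[pos]), 1)
    p0 = (max(-slope, 1e-14), math.exp(icept))
    try:
        popt, pcov = curve_fit(
            lambda bb, D, I0: I0 * np.exp(-D * bb), b, y, p0=p0, maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"Stejskal-Tanner fit failed: {exc}") from exc
    D, I0 = popt
    resid = y - I0 * np.exp(-D * b)
    # robust scatter estimate so one aberrant point cannot mask itself
    resid_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    increments = np.diff(y)
    if np.any(increments > 5.0 * max(resid_sd, 1e-12 * y[0])):
        warnings.warn(
            "non-monotone echo attenuation beyond noise; check for convection",
            stacklevel=2,
        )
    D_err = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.inf
    return float(D), D_err, float(I0)


@dataclass(frozen=True)
class DilutionSeries:
    """Diffusion coefficients measured at several protein concentrations."""

    concentrations: np.ndarray  # mol L^-1
    D_values: np.ndarray  # m^2 s^-1
    D_errors: np.ndarray | None = None  # m^2 s^-1

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, dtype=float))
        object.__setattr__(self, "D_values", np.asarray(self.D_values, dtype=float))
        if self.D_errors is not None:
            object.__setattr__(self, "D_errors", np.asarray(self.D_errors, dtype=float))
        if self.concentrations.size != self.D_values.size:
            raise ValueError("concentrations and D_values must have equal length")
        if np.any(self.concentrations < 0) or np.any(self.D_values <= 0):
            raise ValueError("concentrations must be >= 0 and D values > 0")


def extrapolate_D0(series: DilutionSeries) -> tuple[float, float, float, bool]:
    """Extrapolate a dilution series to infinite dilution.

    Fits ``D(c) = D0 * (1 - k_c * c)`` as a weighted straight line
    (weights ``1/sigma^2`` when per-point errors are given).  Returns
    ``(D0, D0_stderr, k_c, extrapolated)``; with a single distinct
    concentration the measured mean is passed through with
    ``extrapolated=False``.
    """
    c, D = series.concentrations, series.D_values
    if np.unique(c).size < 2:
        err = (
            float(series.D_errors.mean())
            if series.D_errors is not None
            else float(D.std(ddof=0))
        )
        return float(D.mean()), err, 0.0, False
    if series.D_errors is not None:
        if np.any(series.D_errors <= 0):
            raise ValueError("D_errors must be positive when provided")
        w = 1.0 / series.D_errors**2
        scale_cov = False  # absolute errors: covariance is inv(X'WX) as-is
    else:
        w = np.ones_like(c)
        scale_cov = True  # scale by residual variance
    X = np.column_stack([c, np.ones_like(c)])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    slope, D0 = cov @ (XtW @ D)
    if scale_cov and c.size > 2:
        resid = D - (slope * c + D0)
        cov = cov * float(w @ resid**2) / (c.size - 2)
    D0 = float(D0)
    D0_err = float(np.sqrt(cov[1, 1]))
    k_c = float(-slope / D0)
    return D0, D0_err, k_c, True
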