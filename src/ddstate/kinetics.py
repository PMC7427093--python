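"""Kinetic models: first-order deamidation, second-order dimerization, LPR.

Two reaction models cover the time-resolved experiments:

* **First-order decay** of the unmodified-asparagine species during
  spontaneous deamidation, ``I(t) = I0 exp(-k t)`` with half-life
  ``t_1/2 = ln 2 / k``.  Fitted as a weighted straight line in log space,
  matching how such data are plotted and inspected.

* **Irreversible second-order dimerization** of a membrane-confined
  monomer, ``d[M]/dt = -k [M]^2`` with the closed-form solution
  ``[M]_t = [M]0 / (1 + [M]0 k t)``.  Concentrations are expressed in
  mole-protein per mole-lipid (the natural unit when the reaction volume is
  a bilayer), so ``[M]0 = 1 / LPR`` and ``k`` carries units of
  (mole_lipid/mole_protein) s^-1.

The lipid-to-protein ratio (LPR) estimator converts bulk culture
observables (cell surface area, lipid head-group area, expression level,
cell density) into the per-cell molar lipid:protein ratio of a membrane
fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

from .constants import N_A
from .relaxation import FitError

__all__ = [
    "TimeCourse",
    "KineticFit",
    "CellGeometry",
    "LprResult",
    "fit_first_order",
    "second_order_monomer",
    "fit_second_order",
    "gel_monomer_fraction",
    "lpr_ecoli",
    "ECOLI_GEOMETRY",
    "round_to_one_sig_fig",
]

MONOMER_BAND_ALIASES = {"monomer", "m"}


@dataclass(frozen=True)
class TimeCourse:
    """(time, value, error) triples with an explicit time unit tag."""

    times: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    unit: str = "days"  # "days" | "seconds" | "hours"
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.errors is not None:
            object.__setattr__(self, "errors", np.asarray(self.errors, dtype=float))
        if self.unit not in ("days", "seconds", "hours"):
            raise ValueError(f"unit must be days|seconds|hours, got {self.unit!r}")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")

    def in_seconds(self) -> "TimeCourse":
        """Return a copy with times converted to seconds."""
        factor = {"seconds": 1.0, "hours": 3600.0, "days": 86400.0}[self.unit]
        return TimeCourse(
            self.times * factor, self.values, self.errors, "seconds", self.label
        )


@dataclass(frozen=True)
class KineticFit:
    """Fitted rate constant for either kinetic model."""

    model: str  # "first_order" | "second_order"
    k: float  # days^-1 (first order) or (mole_lipid/mole_protein) s^-1
    k_err: float
    t_half: float | None = None  # first order only, in the course's time unit
    M0: float | None = None  # second order only, mole/mole lipid
    unit: str = "days"


def fit_first_order(tc: TimeCourse, min_points: int = 4) -> KineticFit:
    """Fit exponential decay by weighted linear regression of log intensity.

    ``ln I = ln I0 - k t``; weights are ``(I/sigma)^2`` when per-point
    errors are supplied (errors transform as ``sigma_lnI = sigma_I / I``).
    A slope indistinguishable from zero (|k| below twice its standard
    error) triggers a degenerate-fit warning: the course shows no decay.
    """
    if tc.times.size < min_points:
        raise FitError(f"need >= {min_points} time points, got {tc.times.size}")
    if np.any(tc.values <= 0):
        raise ValueError("first-order fit requires strictly positive values (log taken)")
    t, y = tc.times, np.log(tc.values)
    if tc.errors is not None:
        if np.any(tc.errors <= 0):
            raise ValueError("errors must be positive when provided")
        w = (tc.values / tc.errors) ** 2
    else:
        w = np.ones_like(t)
    X = np.column_stack([t, np.ones_like(t)])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    slope, icept = cov @ (XtW @ y)
    if tc.errors is None and t.size > 2:
        resid = y - (slope * t + icept)
        cov = cov * float(w @ resid**2) / (t.size - 2)
    k = float(-slope)
    k_err = float(np.sqrt(cov[0, 0]))
    if abs(k) <= 2.0 * k_err:
        warnings.warn(
            "degenerate first-order fit: decay rate indistinguishable from zero",
            stacklevel=2,
        )
    t_half = math.log(2.0) / k if k > 0 else math.inf
    return KineticFit(
        model="first_order", k=k, k_err=k_err, t_half=t_half, unit=tc.unit
    )


def second_order_monomer(t: float | np.ndarray, M0: float, k: float):
    """Monomer concentration [M]_t = [M]0 / (1 + [M]0 k t) (mole/mole lipid)."""
    if M0 <= 0:
        raise ValueError(f"M0 must be positive, got {M0}")
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = M0 / (1.0 + M0 * k * t)
    return float(out) if out.ndim == 0 else out


def fit_second_order(tc: TimeCourse, M0: float) -> KineticFit:
    """Fit the irreversible dimerization rate constant to a monomer course.

    ``tc.values`` are monomer *fractions* in (0, 1]; they are rescaled by
    ``M0`` (mole-protein per mole-lipid, i.e. 1/LPR) before fitting the
    closed form, so the returned ``k`` is in (mole_lipid/mole_protein) s^-1
    regardless of the LPR the experiment was run at.
    """
    if M0 <= 0:
        raise ValueError(f"M0 must be positive, got {M0}")
    if np.any(tc.values <= 0) or np.any(tc.values > 1.0 + 1e-9):
        raise ValueError("second-order fit expects monomer fractions in (0, 1]")
    tc_s = tc.in_seconds()
    t, M = tc_s.times, tc_s.values * M0
    # closed-form two-point initial guess from the first and last points
    if M[-1] < M[0] and t[-1] > t[0]:
        k0 = (M[0] / M[-1] - 1.0) / (M[0] * (t[-1] - t[0]))
    else:
        k0 = 0.0
    sigma = tc_s.errors * M0 if tc_s.errors is not None else None
    try:
        popt, pcov = curve_fit(
            lambda tt, k: second_order_monomer(tt, M0, k),
            t,
            M,
            p0=(max(k0, 1e-12),),
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=(0.0, np.inf),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"second-order fit failed to converge: {exc}") from exc
    k = float(popt[0])
    k_err = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.inf
    return KineticFit(
        model="second_order", k=k, k_err=k_err, M0=M0, unit="seconds"
    )


def gel_monomer_fraction(band_intensities: Mapping[str, float]) -> float:
    """Monomer fraction of one gel lane from band densitometry.

    Band intensity is taken as proportional to protein *mass*, so the
    fraction is ``I_monomer / sum(I)`` with no molar correction for the
    oligomer bands.  Keys are matched case-insensitively; ``"M"`` and
    ``"monomer"`` denote the monomer band, everything else counts as
    oligomer.
    """
    if any(v < 0 for v in band_intensities.values()):
        raise ValueError("band intensities must be non-negative")
    total = sum(band_intensities.values())
    if total == 0:
        raise ValueError("all-zero lane: cannot form a monomer fraction")
    mono = sum(
        v for kk, v in band_intensities.items() if kk.strip().lower() in MONOMER_BAND_ALIASES
    )
    return mono / total


@dataclass(frozen=True)
class CellGeometry:
    """Bulk observables determining the membrane LPR of a bacterial culture."""

    S_cell: float  # cell surface area, um^2
    S_lip: float  # area per lipid head group, um^2
    C_prot: float  # expression level, g per litre of culture
    MW: float  # protein molecular mass, g mol^-1
    C_cell: float  # cell density, cells per mL
    N_A_used: float = N_A  # Avogadro constant used in the conversion

    def __post_init__(self) -> None:
        for name in ("S_cell", "S_lip", "C_prot", "MW", "C_cell", "N_A_used"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class LprResult:
    n_lip: float  # lipids per cell
    n_prot: float  # protein molecules per cell
    lpr: float  # mole lipid per mole protein
    lpr_1sf: float  # rounded to one significant figure


#: bulk observables of an E. coli membrane-expression culture: ~4 um^2 of
#: (doubled, bilayer) cell surface, DMPC-like 0.6 nm^2 head groups, 6 mg/L
#: expression of a 21.5 kDa construct at 2.4e9 cells/mL.
ECOLI_GEOMETRY = CellGeometry(
    S_cell=4.0,
    S_lip=0.6e-6,
    C_prot=6e-3,
    MW=21486.0,
    C_cell=24e8,
    N_A_used=6e23,
)


def round_to_one_sig_fig(x: float) -> float:
    """Round a positive number to one significant figure (191 -> 200)."""
    if x <= 0:
        raise ValueError(f"expected a positive value, got {x}")
    exp = math.floor(math.log10(x))
    return round(x / 10**exp) * 10.0**exp


def lpr_ecoli(geom: CellGeometry = ECOLI_GEOMETRY) -> LprResult:
    """Lipid-to-protein molar ratio of a bacterial membrane fraction.

    ``N_lip = 2 S_cell / S_lip`` (the factor 2 counts both bilayer
    leaflets) and ``N_prot = C_prot N_A / (MW C_cell)`` with ``C_cell``
    converted from cells/mL to cells/L so the protein amount is per litre
    of culture over cells per litre.
    """
    n_lip = 2.0 * geom.S_cell / geom.S_lip
    n_prot = geom.C_prot * geom.N_A_used / (geom.MW * geom.C_cell * 1e3)
    lpr = n_lip / n_prot
    return LprResult(n_lip=n_lip, n_prot=n_prot, lpr=lpr, lpr_1sf=round_to_one_sig_fig(lpr))
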