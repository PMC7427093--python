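"""Hydrodynamic conversions and oligomeric-state calls.

The oligomeric state of a small protein in solution can be read directly
off its hydrodynamics: the rotational correlation time ``tau_c`` and the
translational self-diffusion coefficient ``D`` both report on the radius of
the equivalent sphere (the hydrodynamic radius ``r_h``), which in turn maps
onto an effective molecular weight of a globular protein.  Comparing that
effective weight with the sequence weight of the monomer gives the oligomer
number ``n`` without any reference structure.

Two Stokes-Einstein relationships are used, both for an isotropic sphere in
a continuum solvent of viscosity ``eta`` at temperature ``T``:

* rotation (Stokes-Einstein-Debye):  ``tau_c = 4 pi eta r_h^3 / (3 k_B T)``
* translation (Stokes-Einstein):     ``D = k_B T / (6 pi eta r_h)``

The ``r_h -> MW`` step uses a two-parameter power law
``MW = A * r_h^b`` (kDa, nm) calibrated once against globular-protein
reference data; the calibrated constants live in :class:`~ddstate.config.RunConfig`,
and :func:`calibrate_rh_mw` re-derives them from any set of (r_h, MW) pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

from .constants import K_B, WATER_MASS_DA

__all__ = [
    "Conditions",
    "HydroMeasurement",
    "OligomerCall",
    "water_viscosity",
    "tau_c_to_rh",
    "rh_to_tau_c",
    "d_to_rh",
    "rh_to_d",
    "rh_to_mw",
    "mw_to_rh",
    "calibrate_rh_mw",
    "sequence_mw",
    "classify_oligomer",
]

#: default r_h -> MW power-law constants, MW[kDa] = MW_A * (r_h/nm)**MW_B
MW_A_DEFAULT = 1.91
MW_B_DEFAULT = 2.85

_CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Conditions:
    """Sample conditions shared by every hydrodynamic computation.

    Parameters
    ----------
    temperature:
        Absolute temperature, K.
    viscosity:
        Solvent dynamic viscosity, Pa s.  When ``None`` the pure-water
        value at ``temperature`` is used; buffer / D2O corrections are a
        caller override, not a default.
    field_MHz:
        Proton Larmor frequency of the spectrometer, MHz (relaxation only).
    """

    temperature: float = 303.15
    viscosity: float | None = None
    field_MHz: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature} K")
        if self.viscosity is not None and self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity} Pa s")
        if self.field_MHz is not None and not (400.0 <= self.field_MHz <= 1000.0):
            raise ValueError(
                f"field_MHz must lie in [400, 1000], got {self.field_MHz}"
            )

    @property
    def eta(self) -> float:
        """Effective viscosity, Pa s (explicit value or pure water at T)."""
        if self.viscosity is not None:
            return self.viscosity
        return water_viscosity(self.temperature)


@dataclass(frozen=True)
class HydroMeasurement:
    """One row of a hydrodynamic-parameters table: a (tau_c, D) pair.

    At least one of the two observables must be present; uncertainties are
    optional and carried through for reporting only.
    """

    construct_name: str
    tau_c: float | None = None  # ns
    tau_c_err: float | None = None  # ns
    D: float | None = None  # m^2 s^-1
    D_err: float | None = None  # m^2 s^-1
    concentration: float | None = None  # mol L^-1

    def __post_init__(self) -> None:
        if self.tau_c is None and self.D is None:
            raise ValueError(
                f"{self.construct_name!r}: at least one of tau_c, D required"
            )
        for name in ("tau_c", "D", "concentration"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{self.construct_name!r}: {name} must be > 0, got {v}")


@dataclass(frozen=True)
class OligomerCall:
    """Result of the oligomeric-state inference for one construct."""

    construct_name: str
    mw_monomer: float  # kDa
    n_oligomer: int
    label: str  # monomer | dimer | higher-order
    mw_rot: float | None = None  # kDa, from tau_c
    mw_trans: float | None = None  # kDa, from D
    rh_rot: float | None = None  # nm
    rh_trans: float | None = None  # nm
    disagreement: bool = False  # rotational vs translational rounding differ


def water_viscosity(temperature: float) -> float:
    """Dynamic viscosity of pure water, Pa s (Vogel-type correlation).

    Uses ``eta = 2.414e-5 * 10**(247.8 / (T - 140))``, accurate to ~1%
    over liquid water at ambient pressure.

    Raises
    ------
    ValueError
        If ``temperature`` is outside the liquid range (273.15, 373.15) K.
    """
    if not (273.15 < temperature < 373.15):
        raise ValueError(
            "water_viscosity valid only for liquid water, "
            f"273.15 K < T < 373.15 K; got {temperature} K"
        )
    return 2.414e-5 * 10.0 ** (247.8 / (temperature - 140.0))


def tau_c_to_rh(tau_c: float, cond: Conditions) -> float:
    """Hydrodynamic radius (nm) from a rotational correlation time (ns).

    Inverts the Stokes-Einstein-Debye relation for an isotropic sphere,
    ``tau_c = 4 pi eta r^3 / (3 k_B T)``.
    """
    if tau_c <= 0:
        raise ValueError(f"tau_c must be positive, got {tau_c} ns")
    r = (3.0 * K_B * cond.temperature * tau_c * 1e-9 / (4.0 * math.pi * cond.eta)) ** (
        1.0 / 3.0
    )
    return r * 1e9


def rh_to_tau_c(r_h: float, cond: Conditions) -> float:
    """Rotational correlation time (ns) of a sphere of radius ``r_h`` (nm)."""
    if r_h <= 0:
        raise ValueError(f"r_h must be positive, got {r_h} nm")
    tau = 4.0 * math.pi * cond.eta * (r_h * 1e-9) ** 3 / (3.0 * K_B * cond.temperature)
    return tau * 1e9


def d_to_rh(D: float, cond: Conditions) -> float:
    """Hydrodynamic radius (nm) from a translational diffusion coefficient.

    ``D`` is in m^2 s^-1; inverts ``D = k_B T / (6 pi eta r)``.
    """
    if D <= 0:
        raise ValueError(f"D must be positive, got {D} m^2/s")
    r = K_B * cond.temperature / (6.0 * math.pi * cond.eta * D)
    return r * 1e9


def rh_to_d(r_h: float, cond: Conditions) -> float:
    """Translational diffusion coefficient (m^2 s^-1) of a sphere (nm)."""
    if r_h <= 0:
        raise ValueError(f"r_h must be positive, got {r_h} nm")
    return K_B * cond.temperature / (6.0 * math.pi * cond.eta * r_h * 1e-9)


def rh_to_mw(r_h: float, A: float = MW_A_DEFAULT, b: float = MW_B_DEFAULT) -> float:
    """Effective molecular weight (kDa) of a globular protein of radius r_h (nm).

    Power law ``MW = A * r_h**b``; the default constants are calibrated so
    the relation reproduces reference globular-protein hydrodynamics in the
    1-3 nm range.  The relation is an empirical approximation: compact
    folded proteins scatter by several percent around it.
    """
    if r_h <= 0:
        raise ValueError(f"r_h must be positive, got {r_h} nm")
    return A * r_h**b


def mw_to_rh(mw: float, A: float = MW_A_DEFAULT, b: float = MW_B_DEFAULT) -> float:
    """Inverse of :func:`rh_to_mw` (kDa -> nm)."""
    if mw <= 0:
        raise ValueError(f"mw must be positive, got {mw} kDa")
    return (mw / A) ** (1.0 / b)


def calibrate_rh_mw(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Fit the power law ``MW = A * r_h**b`` to (r_h [nm], MW [kDa]) pairs.

    Ordinary least squares in log-log space; with exactly two pairs the fit
    is exact.  Returns ``(A, b)``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two (r_h, MW) pairs to calibrate")
    import numpy as np

    r = np.log([p[0] for p in pairs])
    m = np.log([p[1] for p in pairs])
    b, loga = np.polyfit(r, m, 1)
    return float(math.exp(loga)), float(b)


def sequence_mw(sequence: str) -> float:
    """Average (not monoisotopic) mass of a peptide chain, kDa.

    Sum of average residue masses plus one water; the empty sequence
    returns the mass of water alone.  Only the 20 canonical one-letter
    codes are accepted.
    """
    seq = sequence.strip().upper()
    for i, ch in enumerate(seq):
        if ch not in _CANONICAL_AA:
            raise ValueError(
                f"unknown amino-acid code {ch!r} at position {i + 1}; "
                "only the 20 canonical one-letter codes are supported"
            )
    if not seq:
        return WATER_MASS_DA / 1000.0
    return _bio_molecular_weight(seq, seq_type="protein") / 1000.0


def _round_half_away(x: float) -> int:
    """Round half away from zero (1.5 -> 2), unlike banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def classify_oligomer(
    m: HydroMeasurement,
    cond: Conditions,
    mw_monomer: float,
    A: float = MW_A_DEFAULT,
    b: float = MW_B_DEFAULT,
) -> OligomerCall:
    """Infer the oligomeric state of one construct from its hydrodynamics.

    Each available observable is chained through radius and effective
    weight (``tau_c -> r_h -> MW`` and/or ``D -> r_h -> MW``); the oligomer
    number is the mean predicted weight over the monomer sequence weight,
    rounded half away from zero and clamped to >= 1.  When rotation and
    translation round to different oligomer numbers the rotational call is
    reported and the result flagged -- rotation senses volume (r^3) and is
    the more discriminating observable.
    """
    if mw_monomer <= 0:
        raise ValueError(f"mw_monomer must be positive, got {mw_monomer} kDa")

    rh_rot = mw_rot = rh_trans = mw_trans = None
    if m.tau_c is not None:
        rh_rot = tau_c_to_rh(m.tau_c, cond)
        mw_rot = rh_to_mw(rh_rot, A, b)
    if m.D is not None:
        rh_trans = d_to_rh(m.D, cond)
        mw_trans = rh_to_mw(rh_trans, A, b)

    preds = [p for p in (mw_rot, mw_trans) if p is not None]
    n = max(1, _round_half_away(sum(preds) / len(preds) / mw_monomer))
    disagreement = False
    if mw_rot is not None and mw_trans is not None:
        n_rot = max(1, _round_half_away(mw_rot / mw_monomer))
        n_trans = max(1, _round_half_away(mw_trans / mw_monomer))
        if n_rot != n_trans:
            n = n_rot
            disagreement = True

    label = {1: "monomer", 2: "dimer"}.get(n, "higher-order")
    return OligomerCall(
        construct_name=m.construct_name,
        mw_monomer=mw_monomer,
        n_oligomer=n,
        label=label,
        mw_rot=mw_rot,
        mw_trans=mw_trans,
        rh_rot=rh_rot,
        rh_trans=rh_trans,
        disagreement=disagreement,
    )
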