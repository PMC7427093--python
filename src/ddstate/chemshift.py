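"""Chemical-shift analytics: perturbations, secondary shifts, populations.

Four kinds of information are extracted from assigned chemical shifts:

* **Generalized chemical-shift (GCS) perturbation** per residue between two
  states, the weighted Euclidean norm
  ``sqrt(dH^2 + (w * dN)^2)`` with the conventional amide nitrogen weight
  ``w = 0.2`` compensating the wider 15N shift dispersion.
* **Threshold classification** of perturbed residues (strictly greater
  than a ppm cutoff, 0.1 ppm by default).
* **Secondary Calpha shifts**, observed minus random coil; sustained
  positive runs mark alpha-helix.
* **Two-state populations** from the least-squares deconvolution of a 1D
  spectral projection into Lorentzian components; populations are the
  normalized component areas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import TimeCourse
from .relaxation import FitError

__all__ = [
    "Peak",
    "PeakList",
    "Projection1D",
    "gcs",
    "classify_perturbed",
    "load_random_coil_ca",
    "secondary_shift_ca",
    "two_state_populations",
    "population_course_to_kinetics",
]

GCS_N_WEIGHT_DEFAULT = 0.2
GCS_THRESHOLD_DEFAULT = 0.1  # ppm

# plausible amide windows used for flagging (not rejecting) outliers
_H_WINDOW = (5.0, 12.0)
_N_WINDOW = (100.0, 135.0)


@dataclass(frozen=True)
class Peak:
    """One assigned amide cross-peak."""

    residue_id: int
    residue_name: str
    atom: str  # e.g. "N-H"
    shift_H: float  # ppm
    shift_N: float  # ppm
    intensity: float = 1.0
    state_label: str | None = None
    time_stamp: float | None = None  # days

    @property
    def outside_amide_window(self) -> bool:
        return not (
            _H_WINDOW[0] <= self.shift_H <= _H_WINDOW[1]
            and _N_WINDOW[0] <= self.shift_N <= _N_WINDOW[1]
        )


class PeakList:
    """A collection of peaks with uniqueness on (residue, atom, state, time)."""

    def __init__(self, peaks: Sequence[Peak]):
        keys = set()
        for p in peaks:
            key = (p.residue_id, p.atom, p.state_label, p.time_stamp)
            if key in keys:
                raise ValueError(f"duplicate peak for {key}")
            keys.add(key)
        self.peaks = list(peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def get(
        self,
        residue_id: int,
        atom: str = "N-H",
        state_label: str | None = None,
        time_stamp: float | None = None,
    ) -> Peak | None:
        for p in self.peaks:
            if (
                p.residue_id == residue_id
                and p.atom == atom
                and (state_label is None or p.state_label == state_label)
                and (time_stamp is None or p.time_stamp == time_stamp)
            ):
                return p
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "residue": p.residue_id,
                    "resname": p.residue_name,
                    "atom": p.atom,
                    "w_H_ppm": p.shift_H,
                    "w_N_ppm": p.shift_N,
                    "intensity": p.intensity,
                    "state": p.state_label,
                    "time": p.time_stamp,
                }
                for p in self.peaks
            ]
        )


@dataclass(frozen=True)
class Projection1D:
    """A 1D spectral projection on a uniform ppm grid."""

    axis: np.ndarray  # ppm
    amplitude: np.ndarray  # a.u.
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        object.__setattr__(self, "amplitude", np.asarray(self.amplitude, dtype=float))
        if self.axis.size < 32:
            raise ValueError(f"need >= 32 grid points, got {self.axis.size}")
        steps = np.diff(self.axis)
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("projection axis must be uniformly spaced")
        if self.axis.size != self.amplitude.size:
            raise ValueError("axis and amplitude must have equal length")


def gcs(delta_H: float, delta_N: float, weight: float = GCS_N_WEIGHT_DEFAULT) -> float:
    """Generalized chemical-shift change, ppm: sqrt(dH^2 + (w dN)^2)."""
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    return math.hypot(delta_H, weight * delta_N)


def gcs_profile(
    state_a: PeakList,
    state_b: PeakList,
    weight: float = GCS_N_WEIGHT_DEFAULT,
    atom: str = "N-H",
) -> dict[int, float]:
    """Per-residue GCS between two states, matched by (residue_id, atom)."""
    out: dict[int, float] = {}
    for pa in state_a:
        if pa.atom != atom:
            continue
        pb = state_b.get(pa.residue_id, atom)
        if pb is None:
            continue
        out[pa.residue_id] = gcs(pb.shift_H - pa.shift_H, pb.shift_N - pa.shift_N, weight)
    return out


def classify_perturbed(
    profile: Mapping[int, float], threshold: float = GCS_THRESHOLD_DEFAULT
) -> set[int]:
    """Residues whose GCS is strictly greater than ``threshold`` (ppm)."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return {rid for rid, v in profile.items() if v > threshold}


def load_random_coil_ca() -> dict[str, float]:
    """Random-coil Calpha reference shifts, ppm, keyed by one-letter code."""
    with resources.files("ddstate.data").joinpath("random_coil_ca.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df["residue"], df["ca_ppm"]))


def secondary_shift_ca(
    delta_obs: float, residue: str, rc_table: Mapping[str, float] | None = None
) -> float:
    """Secondary Calpha shift ``ddCa = d_obs - d_random_coil``, ppm.

    Positive values indicate alpha-helical propensity, negative extended/
    beta conformation.
    """
    table = rc_table if rc_table is not None else load_random_coil_ca()
    res = residue.strip().upper()
    if res not in table:
        raise ValueError(f"no random-coil Calpha reference for residue {residue!r}")
    return delta_obs - table[res]


def _lorentzian(x: np.ndarray, area: float, center: float, fwhm: float) -> np.ndarray:
    hw = fwhm / 2.0
    return area / math.pi * hw / ((x - center) ** 2 + hw**2)


def two_state_populations(
    proj: Projection1D,
    n_components: int = 2,
    degenerate_area_fraction: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Deconvolve a projection into Lorentzian lines and report populations.

    Returns ``(populations, centers, fwhms, degenerate)`` with populations
    the component areas normalized to unit sum (descending-area order is
    NOT imposed; components keep their center order on the axis).  The fit
    is flagged degenerate when any component carries less than
    ``degenerate_area_fraction`` of the total area.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    x, y = proj.axis, proj.amplitude
    span = x[-1] - x[0]
    dx = abs(span) / (x.size - 1)

    # initial guesses: split the axis, put a line at the local max of each part
    edges = np.linspace(0, x.size, n_components + 1).astype(int)
    p0 = []
    for i in range(n_components):
        seg = slice(edges[i], max(edges[i + 1], edges[i] + 2))
        j = edges[i] + int(np.argmax(y[seg]))
        amp = max(y[j], 1e-12)
        fwhm0 = abs(span) / (6.0 * n_components)
        p0.extend([amp * fwhm0 * math.pi / 2.0, x[j], fwhm0])

    lo = [0.0, min(x[0], x[-1]), 2 * dx] * n_components
    hi = [np.inf, max(x[0], x[-1]), abs(span)] * n_components

    def model(params: np.ndarray) -> np.ndarray:
        out = np.zeros_like(y)
        for i in range(n_components):
            a, c, w = params[3 * i : 3 * i + 3]
            out += _lorentzian(x, a, c, w)
        return out

    sol = least_squares(lambda p: model(p) - y, p0, bounds=(lo, hi))
    if not sol.success:
        raise FitError(f"lineshape deconvolution failed: {sol.message}")
    params = sol.x
    areas = params[0::3]
    centers = params[1::3]
    fwhms = params[2::3]
    order = np.argsort(centers)
    areas, centers, fwhms = areas[order], centers[order], fwhms[order]
    total = areas.sum()
    if total <= 0:
        raise FitError("deconvolution collapsed to zero total area")
    pops = areas / total
    degenerate = bool(np.any(pops < degenerate_area_fraction))
    if degenerate:
        warnings.warn(
            "degenerate deconvolution: a component carries negligible area",
            stacklevel=2,
        )
    return pops, centers, fwhms, degenerate


def population_course_to_kinetics(
    peaklists: Sequence[PeakList],
    probe_residue: int,
    state_label: str = "reference",
    atom: str = "N-H",
    min_points: int = 4,
) -> TimeCourse:
    """Extract a probe residue's reference-state intensity over time.

    Each peak list must be time-stamped; the reference-state intensity of
    ``probe_residue`` at each time point becomes one (t, I) pair of the
    returned :class:`~ddstate.kinetics.TimeCourse` (unit: days), directly
    consumable by :func:`~ddstate.kinetics.fit_first_order`.  Time points
    where the probe is missing are recorded as gaps and skipped, never
    interpolated.
    """
    times: list[float] = []
    values: list[float] = []
    gaps: list[float] = []
    for pl in peaklists:
        stamps = {p.time_stamp for p in pl if p.time_stamp is not None}
        if len(stamps) != 1:
            raise ValueError("each peak list must carry exactly one time stamp")
        (t,) = stamps
        peak = pl.get(probe_residue, atom=atom, state_label=state_label)
        if peak is None:
            gaps.append(t)
            continue
        times.append(t)
        values.append(peak.intensity)
    if not times:
        raise ValueError(f"probe residue {probe_residue} absent from every time point")
    order = np.argsort(times)
    tc = TimeCourse(
        np.asarray(times)[order],
        np.asarray(values)[order],
        unit="days",
        label=f"residue {probe_residue} {state_label} state",
    )
    if gaps:
        warnings.warn(
            f"probe residue {probe_residue} missing at time points {sorted(gaps)}",
            stacklevel=2,
        )
    if tc.times.size < min_points:
        warnings.warn(
            f"only {tc.times.size} time points: below the first-order fit minimum",
            stacklevel=2,
        )
    return tc
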