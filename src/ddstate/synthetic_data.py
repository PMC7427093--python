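"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of its parameters and a seed: the same
call produces byte-identical output, and the noiseless output round-trips
through the matching estimator to the generating parameters at numerical
precision.  Defaults mirror the study conditions the analyses target: TRACT
decays of a small death domain at 600 MHz, a pulsed-gradient ramp to
0.5 T/m, deamidation sampled over ~19 days, membrane dimerization over
70 h at lipid-relative concentrations, and two-component amide projections.

Noise models
------------
``"none"``                no noise;
``"gaussian_relative"``   multiplicative, value * (1 + N(0, sd));
``"gaussian_absolute"``   additive, value + N(0, sd).

Typical instrument noise is 2% relative for spectral intensities and 3%
for gel densitometry, the defaults used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chemshift import Peak, PeakList, Projection1D
from .constants import DEFAULT_SPIN_PARAMS, SpinParams
from .diffusion import DilutionSeries, GradientSeries
from .hydro import Conditions
from .kinetics import TimeCourse, second_order_monomer
from .relaxation import DecayCurve, eta_xy_forward

__all__ = [
    "NoiseSpec",
    "gen_tract_decays",
    "gen_pgste_series",
    "gen_dilution_series",
    "gen_deamidation_course",
    "gen_deamidation_series",
    "gen_dimerization_course",
    "gen_gel_table",
    "gen_two_state_projection",
]

NOISE_SPECTRAL_SD = 0.02  # relative, NMR peak intensities
NOISE_GEL_SD = 0.03  # relative, gel densitometry

DEAMIDATION_DAYS = (0.0, 2.0, 4.0, 6.0, 9.0, 12.0, 16.0, 19.0)
DIMERIZATION_HOURS = (0.0, 2.0, 5.0, 10.0, 20.0, 30.0, 50.0, 70.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model attached to a generator call."""

    model: str = "none"  # none | gaussian_relative | gaussian_absolute
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian_relative", "gaussian_absolute"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.model == "none" or self.sd == 0.0:
            return np.array(values, dtype=float, copy=True)
        draw = rng.normal(0.0, self.sd, size=np.shape(values))
        if self.model == "gaussian_relative":
            return values * (1.0 + draw)
        return values + draw


def gen_tract_decays(
    tau_c: float,
    residues: range | list[int],
    cond: Conditions,
    noise: NoiseSpec = NoiseSpec("gaussian_relative", 0.03),
    seed: int = 0,
    r2_mean: float = 15.0,
    delays: np.ndarray | None = None,
    params: SpinParams = DEFAULT_SPIN_PARAMS,
    tau_jitter_sd: float = 0.0,
) -> list[DecayCurve]:
    """TROSY/anti-TROSY decay pairs for a rigid domain tumbling at ``tau_c``.

    The two components relax at ``r2_mean -/+ eta_xy(tau_c)`` so their
    difference encodes the cross-correlation rate exactly as the estimator
    assumes.  Optional per-residue jitter draws each residue's true
    ``tau_c`` from N(tau_c, tau_jitter_sd).
    """
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    rng = np.random.default_rng(seed)
    if delays is None:
        delays = np.linspace(0.004, 0.12, 12)
    curves: list[DecayCurve] = []
    for rid in residues:
        tc_i = tau_c + (rng.normal(0.0, tau_jitter_sd) if tau_jitter_sd > 0 else 0.0)
        tc_i = max(tc_i, 0.1)
        eta = eta_xy_forward(tc_i, cond, params)
        for component, R in (("alpha", r2_mean - eta), ("beta", r2_mean + eta)):
            clean = np.exp(-R * delays)
            curves.append(
                DecayCurve(
                    residue_id=rid,
                    residue_name="X",
                    component=component,
                    delays=delays,
                    intensities=noise.apply(clean, rng),
                    noise_sd=noise.sd if noise.model != "none" else None,
                )
            )
    return curves


def gen_pgste_series(
    D: float,
    noise: NoiseSpec = NoiseSpec("none"),
    seed: int = 0,
    n_points: int = 16,
    g_min: float = 0.02,
    g_max: float = 0.5,
    delta: float = 0.004,
    Delta: float = 0.1,
) -> GradientSeries:
    """Stejskal-Tanner attenuation of a species diffusing at ``D`` (m^2/s)."""
    if D <= 0:
        raise ValueError("D must be positive")
    rng = np.random.default_rng(seed)
    g = np.linspace(g_min, g_max, n_points)
    series = GradientSeries(g, np.ones(n_points), delta=delta, Delta=Delta)
    clean = np.exp(-D * series.b_values)
    return GradientSeries(
        g, noise.apply(clean, rng), delta=delta, Delta=Delta,
        gamma=series.gamma, shape_factor=series.shape_factor,
    )


def gen_dilution_series(
    D0: float,
    k_c: float,
    concentrations: np.ndarray,
    noise: NoiseSpec = NoiseSpec("none"),
    seed: int = 0,
    rel_err: float = 0.01,
) -> DilutionSeries:
    """Concentration series ``D(c) = D0 (1 - k_c c)`` with stated errors."""
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, dtype=float)
    clean = D0 * (1.0 - k_c * c)
    return DilutionSeries(c, noise.apply(clean, rng), np.full_like(c, rel_err * D0))


def gen_deamidation_course(
    k_days: float,
    times_days: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec("gaussian_relative", NOISE_SPECTRAL_SD),
    seed: int = 0,
) -> TimeCourse:
    """First-order intensity decay of the unmodified species, unit days."""
    if k_days < 0:
        raise ValueError("k_days must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(times_days if times_days is not None else DEAMIDATION_DAYS, dtype=float)
    clean = np.exp(-k_days * t)
    return TimeCourse(t, noise.apply(clean, rng), unit="days", label="deamidation")


def gen_deamidation_series(
    k_days: float,
    times_days: np.ndarray | None = None,
    probe_residue: int = 352,
    noise: NoiseSpec = NoiseSpec("gaussian_relative", NOISE_SPECTRAL_SD),
    seed: int = 0,
) -> list[PeakList]:
    """Time-stamped peak lists of a two-state deamidation time course.

    The reference-state probe intensity fades as ``exp(-k t)`` while the
    product state grows complementarily, so the summed intensity is
    conserved in the noiseless limit.  Shift values place the two states
    0.3 ppm (1H) / 2.0 ppm (15N) apart, inside the amide window.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times_days if times_days is not None else DEAMIDATION_DAYS, dtype=float)
    lists: list[PeakList] = []
    for ti in t:
        frac = math.exp(-k_days * ti)
        i_ref, i_prod = noise.apply(np.array([frac, 1.0 - frac]), rng)
        peaks = [
            Peak(
                residue_id=probe_residue, residue_name="N", atom="N-H",
                shift_H=8.30, shift_N=118.5, intensity=float(max(i_ref, 0.0)),
                state_label="reference", time_stamp=float(ti),
            ),
            Peak(
                residue_id=probe_residue, residue_name="D", atom="N-H",
                shift_H=8.60, shift_N=120.5, intensity=float(max(i_prod, 0.0)),
                state_label="product", time_stamp=float(ti),
            ),
        ]
        lists.append(PeakList(peaks))
    return lists


def gen_dimerization_course(
    k: float,
    M0: float,
    times_hours: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec("gaussian_relative", NOISE_GEL_SD),
    seed: int = 0,
) -> TimeCourse:
    """Monomer-fraction time course of irreversible membrane dimerization.

    ``k`` in (mole_lipid/mole_protein) s^-1, ``M0`` in mole-protein per
    mole-lipid (1/LPR).  Values are fractions M(t)/M0, clipped to (0, 1]
    after noise.
    """
    if k < 0 or M0 <= 0:
        raise ValueError("require k >= 0 and M0 > 0")
    rng = np.random.default_rng(seed)
    th = np.asarray(times_hours if times_hours is not None else DIMERIZATION_HOURS, dtype=float)
    frac = second_order_monomer(th * 3600.0, M0, k) / M0
    noisy = np.clip(noise.apply(frac, rng), 1e-9, 1.0)
    return TimeCourse(th, noisy, unit="hours", label="dimerization")


def gen_gel_table(
    course: TimeCourse,
    higher_order_fraction: float = 0.0,
    total_mass: float = 100.0,
) -> list[dict[str, float]]:
    """Per-lane band intensities consistent with a monomer-fraction course.

    Each lane carries ``total_mass`` units of protein mass: the monomer
    band gets ``fraction * total_mass`` and the oligomer mass is split
    between dimer and tetramer bands by ``higher_order_fraction``.  Mass is
    conserved per lane by construction.
    """
    if not (0.0 <= higher_order_fraction <= 1.0):
        raise ValueError("higher_order_fraction must be in [0, 1]")
    lanes = []
    for t, f in zip(course.times, course.values):
        oligo = (1.0 - f) * total_mass
        lanes.append(
            {
                "time": float(t),
                "monomer": float(f * total_mass),
                "dimer": float(oligo * (1.0 - higher_order_fraction)),
                "tetramer": float(oligo * higher_order_fraction),
            }
        )
    return lanes


def gen_two_state_projection(
    p1: float,
    centers: tuple[float, float] = (8.2, 8.7),
    widths: tuple[float, float] = (0.06, 0.06),
    noise: NoiseSpec = NoiseSpec("none"),
    seed: int = 0,
    axis: np.ndarray | None = None,
) -> Projection1D:
    """Sum of two Lorentzians with area fractions (p1, 1-p1) on a ppm grid.

    A metadata warning flag is set when the centers are closer than half
    the mean linewidth, where deconvolution becomes ill-conditioned.
    """
    if not (0.0 <= p1 <= 1.0):
        raise ValueError("p1 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if axis is None:
        lo = min(centers) - 10 * max(widths)
        hi = max(centers) + 10 * max(widths)
        axis = np.linspace(lo, hi, 512)
    axis = np.asarray(axis, dtype=float)

    def lor(x, area, c, fwhm):
        hw = fwhm / 2.0
        return area / math.pi * hw / ((x - c) ** 2 + hw**2)

    clean = lor(axis, p1, centers[0], widths[0]) + lor(axis, 1.0 - p1, centers[1], widths[1])
    meta = {"p1": p1, "centers": centers, "widths": widths}
    if abs(centers[1] - centers[0]) < 0.5 * np.mean(widths):
        meta["overlap_warning"] = True
    if noise.model == "gaussian_relative":
        # relative spectral noise is scaled to the maximum amplitude so the
        # baseline is not noise-free
        amp = clean + rng.normal(0.0, noise.sd * clean.max(), size=clean.shape)
    else:
        amp = noise.apply(clean, rng)
    return Projection1D(axis, amp, meta)
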