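"""End-to-end workflows composing the analysis stages.

Three named workflows mirror the experimental logic:

* ``oligostate`` -- rotational correlation time from relaxation decays,
  diffusion coefficient from a gradient ramp, conversion of both to an
  effective molecular weight, and the monomer/dimer call against the
  monomer sequence weight.
* ``deamidation`` -- probe-residue population course out of time-stamped
  peak lists, then the first-order rate constant and half-life.
* ``dimerization`` -- monomer fractions from gel densitometry, the
  second-order rate constant at the stated lipid-to-protein ratio, and the
  LPR bookkeeping.

Every run returns an :class:`AnalysisReport` recording the parameters
used, so identical inputs and configuration always reproduce identical
result tables.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chemshift import population_course_to_kinetics
from .config import RunConfig
from .diffusion import GradientSeries, stejskal_tanner_fit
from .hydro import HydroMeasurement, classify_oligomer
from .kinetics import TimeCourse, fit_first_order, fit_second_order, gel_monomer_fraction
from .relaxation import DecayCurve, ensemble_tau_c, tract_from_decays

__all__ = ["AnalysisReport", "run_workflow", "WORKFLOWS"]


@dataclass
class AnalysisReport:
    """Machine- and human-readable record of one workflow run."""

    stage: str
    inputs_digest: str
    parameters: dict[str, Any]
    results: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    version: str = __version__

    def to_dict(self) -> dict[str, Any]:
        return {
            "stage": self.stage,
            "inputs_digest": self.inputs_digest,
            "parameters": self.parameters,
            "results": self.results.to_dict(orient="records"),
            "warnings": self.warnings,
            "version": self.version,
        }

    def to_text(self) -> str:
        lines = [
            f"ddstate {self.version} :: {self.stage}",
            f"inputs: {self.inputs_digest}",
            "parameters: " + json.dumps(self.parameters, default=str),
        ]
        if self.warnings:
            lines += [f"WARNING: {w}" for w in self.warnings]
        lines.append(self.results.to_string(index=False))
        return "\n".join(lines)


def _digest(inputs: Mapping[str, Any]) -> str:
    h = hashlib.sha256()
    for key in sorted(inputs):
        h.update(key.encode())
        h.update(repr(inputs[key]).encode())
    return h.hexdigest()[:16]


def _workflow_oligostate(config: RunConfig, inputs: Mapping[str, Any]) -> pd.DataFrame:
    decays: Sequence[DecayCurve] | None = inputs.get("decays")
    gradient: GradientSeries | None = inputs.get("gradient_series")
    mw_monomer: float = inputs["mw_monomer"]
    if decays is None and gradient is None:
        raise ValueError("oligostate workflow needs decays and/or a gradient series")
    cond = config.conditions()
    tau_c = D = None
    if decays is not None:
        results = tract_from_decays(decays, cond, config.spin_params())
        tau_c, _ = ensemble_tau_c(results, inputs.get("residue_range"))
    if gradient is not None:
        D, _, _ = stejskal_tanner_fit(gradient)
    call = classify_oligomer(
        HydroMeasurement(inputs.get("construct", "sample"), tau_c=tau_c, D=D),
        cond,
        mw_monomer,
        A=config.mw_A,
        b=config.mw_b,
    )
    return pd.DataFrame(
        [
            {
                "construct": call.construct_name,
                "tau_c_ns": tau_c,
                "D_m2s": D,
                "rh_rot_nm": call.rh_rot,
                "rh_trans_nm": call.rh_trans,
                "mw_rot_kda": call.mw_rot,
                "mw_trans_kda": call.mw_trans,
                "mw_monomer_kda": mw_monomer,
                "n_oligomer": call.n_oligomer,
                "label": call.label,
                "disagreement": call.disagreement,
            }
        ]
    )


def _workflow_deamidation(config: RunConfig, inputs: Mapping[str, Any]) -> pd.DataFrame:
    course: TimeCourse
    if "course" in inputs:
        course = inputs["course"]
    else:
        course = population_course_to_kinetics(
            inputs["peaklists"],
            inputs.get("probe_residue", 352),
            state_label=inputs.get("state_label", "reference"),
        )
    fit = fit_first_order(course)
    return pd.DataFrame(
        [
            {
                "label": course.label,
                "n_points": course.times.size,
                "k_per_day": fit.k,
                "k_err": fit.k_err,
                "t_half_days": fit.t_half,
            }
        ]
    )


def _workflow_dimerization(config: RunConfig, inputs: Mapping[str, Any]) -> pd.DataFrame:
    lpr: float = inputs["lpr"]
    if "course" in inputs:
        course: TimeCourse = inputs["course"]
    else:
        lanes = inputs["gel_lanes"]  # dicts with 'time' plus band intensities
        times, fracs = [], []
        for lane in lanes:
            bands = {k: v for k, v in lane.items() if k not in ("time", "lane")}
            times.append(float(lane["time"]))
            fracs.append(gel_monomer_fraction(bands))
        order = np.argsort(times)
        course = TimeCourse(
            np.asarray(times)[order],
            np.asarray(fracs)[order],
            unit=inputs.get("unit", "hours"),
            label="gel monomer fraction",
        )
    fit = fit_second_order(course, M0=1.0 / lpr)
    return pd.DataFrame(
        [
            {
                "label": course.label,
                "lpr": lpr,
                "M0_mole_per_mole": 1.0 / lpr,
                "k_mole_lipid_per_mole_protein_per_s": fit.k,
                "k_err": fit.k_err,
            }
        ]
    )


WORKFLOWS = {
    "oligostate": _workflow_oligostate,
    "deamidation": _workflow_deamidation,
    "dimerization": _workflow_dimerization,
}


def run_workflow(
    name: str, config: RunConfig, inputs: Mapping[str, Any]
) -> AnalysisReport:
    """Execute a named workflow and wrap the result in a report.

    Raises ``ValueError`` for an unknown name or empty inputs; stage errors
    propagate with the stage name prepended.
    """
    if name not in WORKFLOWS:
        raise ValueError(f"unknown workflow {name!r}; choose from {sorted(WORKFLOWS)}")
    if not inputs:
        raise ValueError(f"workflow {name!r}: empty input set")
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        try:
            results = WORKFLOWS[name](config, inputs)
        except Exception as exc:
            raise type(exc)(f"workflow {name!r}: {exc}") from exc
        caught = [str(w.message) for w in wrec]
    return AnalysisReport(
        stage=name,
        inputs_digest=_digest(inputs),
        parameters={
            "temperature": config.temperature,
            "viscosity": config.viscosity,
            "field_MHz": config.field_MHz,
            "mw_A": config.mw_A,
            "mw_b": config.mw_b,
            "seed": config.seed,
        },
        results=results,
        warnings=caught,
    )
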