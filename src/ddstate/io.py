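"""Readers and writers for the CSV/TSV dialects and peak-list formats.

All tabular inputs are plain UTF-8 CSV (or TSV) with a header row; lines
starting with ``#`` before the header are parsed as ``key=value`` metadata
(e.g. acquisition parameters of a gradient series).  Numbers use the dot
decimal separator regardless of locale.  A Sparky-style ``.list`` reader
covers assigned amide peak lists with the ``G353N-H`` assignment
convention.
"""

from __future__ import annotations

import io as _io
import math
import re
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .chemshift import Peak, PeakList, Projection1D
from .diffusion import DilutionSeries, GradientSeries
from .hydro import HydroMeasurement
from .kinetics import TimeCourse
from .relaxation import DecayCurve

__all__ = [
    "SchemaError",
    "read_metadata",
    "read_table",
    "read_hydro_table",
    "read_decay_table",
    "read_gradient_series",
    "read_dilution_table",
    "read_timecourse",
    "read_gel_table",
    "read_peaklist_csv",
    "read_sparky_list",
    "read_projection",
    "read_fasta",
    "write_table",
]


class SchemaError(ValueError):
    """A table is missing mandatory columns or contains unparseable cells."""


def read_metadata(path: str | Path) -> dict[str, str]:
    """Parse leading ``# key=value`` comment lines into a dict."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_table(
    path: str | Path,
    required: Iterable[str],
    optional: Iterable[str] = (),
) -> pd.DataFrame:
    """Read a CSV/TSV with schema validation.

    ``required`` columns must all be present (a missing one raises
    :class:`SchemaError` naming it); unparseable numeric cells raise with
    the offending row number.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), comment="#", skip_blank_lines=True)
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot read table {path}: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    return df


def _float_or_none(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_hydro_table(path: str | Path) -> list[HydroMeasurement]:
    """Hydrodynamic-parameters table -> measurements.

    Columns: ``construct, tau_c_ns, tau_c_err, D_m2s, D_err, conc_M``
    (missing observable cells left empty).
    """
    df = read_table(path, required=["construct"])
    if "tau_c_ns" not in df.columns and "D_m2s" not in df.columns:
        raise SchemaError(f"{path}: need at least one of columns tau_c_ns, D_m2s")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                HydroMeasurement(
                    construct_name=str(row["construct"]),
                    tau_c=_float_or_none(row.get("tau_c_ns")),
                    tau_c_err=_float_or_none(row.get("tau_c_err")),
                    D=_float_or_none(row.get("D_m2s")),
                    D_err=_float_or_none(row.get("D_err")),
                    concentration=_float_or_none(row.get("conc_M")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {idx + 1}: {exc}") from exc
    return out


def read_decay_table(path: str | Path) -> list[DecayCurve]:
    """Long-format relaxation decays -> per-residue/component curves.

    Columns: ``residue, resname, component, delay_s, intensity``.
    """
    df = read_table(path, required=["residue", "component", "delay_s", "intensity"])
    curves = []
    for (rid, comp), grp in df.groupby(["residue", "component"], sort=True):
        grp = grp.sort_values("delay_s")
        resname = str(grp["resname"].iloc[0]) if "resname" in grp.columns else "X"
        curves.append(
            DecayCurve(
                residue_id=int(rid),
                residue_name=resname,
                component=str(comp),
                delays=grp["delay_s"].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float),
            )
        )
    return curves


def read_gradient_series(path: str | Path) -> GradientSeries:
    """Gradient ramp with ``# delta_s=.. # Delta_s=.. # gamma=..`` metadata."""
    meta = read_metadata(path)
    for key in ("delta_s", "Delta_s"):
        if key not in meta:
            raise SchemaError(f"{path}: missing metadata line '# {key}=...'")
    df = read_table(path, required=["gradient_Tm", "intensity"])
    kwargs = {}
    if "gamma" in meta:
        kwargs["gamma"] = float(meta["gamma"])
    if "shape_factor" in meta:
        kwargs["shape_factor"] = float(meta["shape_factor"])
    return GradientSeries(
        df["gradient_Tm"].to_numpy(dtype=float),
        df["intensity"].to_numpy(dtype=float),
        delta=float(meta["delta_s"]),
        Delta=float(meta["Delta_s"]),
        **kwargs,
    )


def read_dilution_table(path: str | Path) -> DilutionSeries:
    """Columns: ``conc_M, D_m2s`` and optional ``D_err``."""
    df = read_table(path, required=["conc_M", "D_m2s"])
    errs = df["D_err"].to_numpy(dtype=float) if "D_err" in df.columns else None
    return DilutionSeries(
        df["conc_M"].to_numpy(dtype=float), df["D_m2s"].to_numpy(dtype=float), errs
    )


def read_timecourse(path: str | Path) -> TimeCourse:
    """Columns: ``time, value`` and optional ``error``; ``# unit=`` metadata."""
    meta = read_metadata(path)
    df = read_table(path, required=["time", "value"])
    errs = df["error"].to_numpy(dtype=float) if "error" in df.columns else None
    return TimeCourse(
        df["time"].to_numpy(dtype=float),
        df["value"].to_numpy(dtype=float),
        errs,
        unit=meta.get("unit", "days"),
        label=meta.get("label", ""),
    )


def read_gel_table(path: str | Path) -> list[dict]:
    """Gel densitometry, columns ``lane, band, intensity`` (long format).

    Returns one dict per lane: ``{"lane": ..., bands...}``, lanes in file
    order of first appearance.
    """
    df = read_table(path, required=["lane", "band", "intensity"])
    lanes = []
    for lane, grp in df.groupby("lane", sort=False):
        entry: dict = {"lane": lane}
        for _, row in grp.iterrows():
            entry[str(row["band"]).strip().lower()] = float(row["intensity"])
        lanes.append(entry)
    return lanes


def read_peaklist_csv(path: str | Path) -> PeakList:
    """Assigned peak list, columns
    ``residue, resname, atom, w_N_ppm, w_H_ppm, intensity, state, time``.
    """
    df = read_table(path, required=["residue", "w_N_ppm", "w_H_ppm"])
    peaks = []
    for idx, row in df.iterrows():
        try:
            peaks.append(
                Peak(
                    residue_id=int(row["residue"]),
                    residue_name=str(row.get("resname", "X")),
                    atom=str(row.get("atom", "N-H")),
                    shift_H=float(row["w_H_ppm"]),
                    shift_N=float(row["w_N_ppm"]),
                    intensity=float(row["intensity"]) if "intensity" in df.columns else 1.0,
                    state_label=(
                        str(row["state"])
                        if "state" in df.columns and not pd.isna(row["state"])
                        else None
                    ),
                    time_stamp=(
                        float(row["time"])
                        if "time" in df.columns and not pd.isna(row["time"])
                        else None
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {idx + 1}: {exc}") from exc
    return PeakList(peaks)


_SPARKY_ASSIGNMENT = re.compile(r"^([A-Z])(\d+)([A-Z]+)-([A-Z]+)$")


def read_sparky_list(path: str | Path) -> PeakList:
    """Sparky-style ``.list`` peak list.

    Expected lines like ``G353N-H   118.53    8.31   [height]`` after an
    optional ``Assignment w1 w2`` header; w1 is 15N, w2 is 1H.
    """
    peaks = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            parts = line.split()
            m = _SPARKY_ASSIGNMENT.match(parts[0])
            if m is None:
                raise SchemaError(
                    f"{path}: line {lineno}: cannot parse assignment {parts[0]!r}"
                )
            resname, rid, atom1, atom2 = m.groups()
            if len(parts) < 3:
                raise SchemaError(f"{path}: line {lineno}: expected two shift columns")
            w1, w2 = float(parts[1]), float(parts[2])
            height = float(parts[3]) if len(parts) > 3 else 1.0
            peaks.append(
                Peak(
                    residue_id=int(rid),
                    residue_name=resname,
                    atom=f"{atom1}-{atom2}",
                    shift_H=w2,
                    shift_N=w1,
                    intensity=height,
                )
            )
    return PeakList(peaks)


def read_projection(path: str | Path) -> Projection1D:
    """Two-column projection, ``ppm, amplitude``."""
    df = read_table(path, required=["ppm", "amplitude"])
    return Projection1D(
        df["ppm"].to_numpy(dtype=float), df["amplitude"].to_numpy(dtype=float)
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records -> {description: sequence} (order preserved)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.description] = str(rec.seq)
    return records


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a DataFrame as CSV with optional ``# key=value`` header lines."""
    buf = _io.StringIO()
    if meta:
        for key, val in meta.items():
            buf.write(f"# {key}={val}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
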