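"""Run configuration: every tunable default in one serializable place.

Precedence is command-line flags > config file > the defaults below.  The
defaults encode the package's standing assumptions: 303.15 K with
pure-water viscosity, a 600 MHz spectrometer, the calibrated radius-to-mass
power law, conventional amide spin constants, and the 0.2 nitrogen weight
for generalized chemical-shift perturbations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .chemshift import GCS_N_WEIGHT_DEFAULT, GCS_THRESHOLD_DEFAULT
from .constants import SpinParams
from .hydro import MW_A_DEFAULT, MW_B_DEFAULT, Conditions

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unreadable configuration."""


@dataclass
class RunConfig:
    # sample conditions
    temperature: float = 303.15  # K
    viscosity: float | None = None  # Pa s; None -> pure water at temperature
    field_MHz: float = 600.0  # proton Larmor frequency
    # radius -> molecular-weight calibration, MW[kDa] = mw_A * (r_h/nm)**mw_b
    mw_A: float = MW_A_DEFAULT
    mw_b: float = MW_B_DEFAULT
    # amide spin constants for cross-correlated relaxation
    r_nh: float = 1.02e-10  # m
    delta_sigma_n: float = -160e-6  # 15N CSA (dimensionless)
    theta_deg: float = 17.0  # CSA axis / N-H bond angle
    # chemical-shift perturbation analysis
    gcs_weight: float = GCS_N_WEIGHT_DEFAULT
    gcs_threshold: float = GCS_THRESHOLD_DEFAULT  # ppm
    # randomness
    seed: int = 0

    def conditions(self) -> Conditions:
        return Conditions(
            temperature=self.temperature,
            viscosity=self.viscosity,
            field_MHz=self.field_MHz,
        )

    def spin_params(self) -> SpinParams:
        return SpinParams(
            r_nh=self.r_nh, delta_sigma_n=self.delta_sigma_n, theta_deg=self.theta_deg
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), "utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)
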