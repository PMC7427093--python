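"""Physical constants (CODATA 2018) and NMR spin-interaction defaults.

The spin constants parameterize the amide ``15N-1H`` dipole-dipole /
``15N`` CSA cross-correlation rate used for rotational-diffusion analysis:
the effective N-H bond length, the ``15N`` chemical-shift anisotropy, and
the angle between the CSA principal axis and the N-H bond.
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA 2018 exact/recommended values
K_B = 1.380649e-23  # J K^-1
N_A = 6.02214076e23  # mol^-1
H_PLANCK = 6.62607015e-34  # J s
MU_0 = 1.25663706212e-6  # N A^-2
GAMMA_H1 = 2.6752218744e8  # rad s^-1 T^-1
GAMMA_N15 = -2.7126189e7  # rad s^-1 T^-1 (negative gyromagnetic ratio)

#: average mass of one water molecule, Da (added once per peptide chain)
WATER_MASS_DA = 18.0153


@dataclass(frozen=True)
class SpinParams:
    """Constants of the amide dipole-CSA interference interaction.

    Attributes
    ----------
    r_nh:
        Effective N-H internuclear distance, metres.
    delta_sigma_n:
        ``15N`` chemical-shift anisotropy, dimensionless (ppm * 1e-6).
    theta_deg:
        Angle between the CSA unique axis and the N-H bond, degrees.
    """

    r_nh: float = 1.02e-10
    delta_sigma_n: float = -160e-6
    theta_deg: float = 17.0


DEFAULT_SPIN_PARAMS = SpinParams()
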