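"""Physical constants used throughout the package.

All internal computations use SI units: seconds, rad/s, rad^2/s^2, Tesla,
metres where relevant.  Magnetic susceptibility is dimensionless (SI
volume susceptibility); the ``ppm`` suffix in public signatures means the
value is expressed in parts per million of that dimensionless quantity.
Unit conversions happen only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Proton gyromagnetic ratio, rad / s / T.
GAMMA = 2.675e8

#: Default main magnetic field strength, T.
B0_DEFAULT = 3.0

#: Static dephasing regime prefactor, 2*pi / (9*sqrt(3)).
LAMBDA_SDR = 2.0 * math.pi / (9.0 * math.sqrt(3.0))

#: Diffusion narrowing regime prefactor, 16/75.
LAMBDA_DNR = 16.0 / 75.0

#: Water diffusion coefficient in tissue, um^2 / ms (== 1e-9 m^2/s).
D_WATER_UM2_PER_MS = 1.0

#: Brain tissue mass density, g / cm^3.
RHO_TISSUE = 1.05

#: Effective mass susceptibility of iron bound to neuromelanin, ppm * m^3 / kg.
CHI_EFF_NM = 2.98

#: Effective susceptibility slopes used for iron-map conversion,
#: ppm of volume susceptibility per (mg iron / g tissue).
CHI_SLOPE_NEUROMELANIN = 3.3e-3 * 1e3 / 1.0  # 3.3 ppb/(ug/g) == 3.3 ppm/(mg/g)
CHI_SLOPE_FERRITIN = 1.3e-3 * 1e3 / 1.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of physical constants, overridable via configuration.

    Attributes
    ----------
    gamma : float
        Gyromagnetic ratio, rad/s/T.
    B0 : float
        Main magnetic field, T.
    D : float
        Water diffusion coefficient, um^2/ms.
    lambda_sdr, lambda_dnr : float
        Regime prefactors linking the microscopic relaxation rate to the
        inclusion properties in the static-dephasing and
        diffusion-narrowing regimes.
    rho : float
        Tissue density, g/cm^3.
    chi_eff_nm : float
        Effective mass susceptibility of neuromelanin-bound iron,
        ppm * m^3 / kg.
    """

    gamma: float = GAMMA
    B0: float = B0_DEFAULT
    D: float = D_WATER_UM2_PER_MS
    lambda_sdr: float = LAMBDA_SDR
    lambda_dnr: float = LAMBDA_DNR
    rho: float = RHO_TISSUE
    chi_eff_nm: float = CHI_EFF_NM

    @property
    def gamma_b0(self) -> float:
        """gamma * B0, rad/s per unit (dimensionless) susceptibility."""
        return self.gamma * self.B0


DEFAULT_CONSTANTS = PhysicalConstants()
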