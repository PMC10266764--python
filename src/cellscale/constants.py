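"""Physical constants and unit conversions.

The package works in the unit system of cell biophysics tables:
concentrations in mM (= mol/m^3), volumes in um^3 (= fL), particle
amounts as dimensionless counts, pressures in Pa, potentials in kBT/e
(with a mV helper), temperatures in K, masses in Da or kg.
"""

import numpy as np

#: Boltzmann constant, J/K.
KB = 1.380649e-23

#: Avogadro constant, 1/mol.
NA = 6.02214076e23

#: Molar gas constant, J/(mol K); kB*NA.
RGAS = KB * NA

#: Elementary charge, C.
E_CHARGE = 1.602176634e-19

#: Unified atomic mass unit, kg.
DA = 1.66053906660e-27

#: Conversion count -> (mM * um^3): a single particle in 1 um^3 is
#: 1/(NA * 1e-18 m^3) mol/m^3 = 1e18/NA mM.
CONC_UM3_PER_COUNT = 1e18 / NA

DEFAULT_T = 300.0


def thermal_voltage_mV(T: float = DEFAULT_T) -> float:
    """kBT/e in millivolts at temperature ``T`` (25.85 mV at 300 K)."""
    return KB * T / E_CHARGE * 1e3


def pressure_from_mM(c_mM: float, T: float = DEFAULT_T) -> float:
    """Van 't Hoff pressure (Pa) of an ideal osmolyte concentration in mM.

    1 mM is 1 mol/m^3, so the prefactor is the molar gas constant.
    """
    return RGAS * T * np.asarray(c_mM)


def mM_from_pressure(p_Pa: float, T: float = DEFAULT_T) -> float:
    """Concentration (mM) osmotically equivalent to a pressure in Pa."""
    return np.asarray(p_Pa) / (RGAS * T)


def counts_to_mM(n: float, volume_um3: float) -> float:
    """Concentration (mM) of ``n`` particles in ``volume_um3`` um^3."""
    return n * CONC_UM3_PER_COUNT / volume_um3


def mM_to_counts(c_mM: float, volume_um3: float) -> float:
    """Particle count at concentration ``c_mM`` in ``volume_um3`` um^3."""
    return c_mM * volume_um3 / CONC_UM3_PER_COUNT


def amol_to_counts(amount_amol: float) -> float:
    """Convert an amount in attomol (1e-18 mol) to a particle count."""
    return amount_amol * 1e-18 * NA
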