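"""Steady state of the two-ion Pump-Leak model for a single compartment.

The model fixes the volume of a compartment containing ``X`` impermeant
particles of mean (negative) valence magnitude ``z`` immersed in a bath of
monovalent salt at concentration ``n0`` by three constraints:

* electroneutrality          ``n+ - n- - z*x = 0``
* osmotic (water) balance    ``dP = kBT * (n+ + n- + x - 2*n0)``
* ion flux balance           ``n+ * n- = alpha0 * n0**2``

where ``x = X/(V - R)`` is the impermeant concentration in the wet volume,
``alpha0 = exp(-p/(kBT*g+))`` measures active cation pumping against passive
leak (0 = infinite pumping, 1 = none), and ``dP`` is the hydrostatic
pressure difference sustained by a wall (zero for mammalian cells).

Units follow :mod:`cellscale.constants`: mM, um^3, Pa, K, counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import (
    CONC_UM3_PER_COUNT,
    DEFAULT_T,
    mM_from_pressure,
    pressure_from_mM,
    thermal_voltage_mV,
)

__all__ = [
    "PumpLeakParams",
    "PumpLeakState",
    "VolumeDivergenceError",
    "InfeasibleError",
    "alpha0_from_pumping",
    "alpha0_from_concentrations",
    "solve_steady_state",
    "volume_infinite_pumping",
    "donnan_potential",
    "donnan_potential_mV",
    "impermeant_concentration_from_balance",
    "mean_charge_from_electroneutrality",
    "dry_mass_density",
    "osmotic_pressure",
]


class VolumeDivergenceError(ValueError):
    """No pumping and no wall: the Pump-Leak model predicts a diverging volume."""


class InfeasibleError(ValueError):
    """The steady-state system has no physical root with V > R."""


@dataclass(frozen=True)
class PumpLeakParams:
    """Inputs of the single-compartment Pump-Leak model.

    Parameters
    ----------
    n0 : float
        External cation (= anion) concentration, mM.
    alpha0 : float
        Pumping efficiency in [0, 1]; 0 means infinite pumping.
    z : float
        Mean negative-valence magnitude of the impermeant species
        (the signed charge is ``-z``).
    X : float
        Impermeant particle count (dimensionless; use
        :func:`cellscale.constants.amol_to_counts` for molar amounts).
    R : float
        Excluded (dry) volume, um^3.
    dP : float
        Hydrostatic pressure difference across the membrane/wall, Pa.
    T : float
        Temperature, K.
    """

    n0: float
    alpha0: float
    z: float
    X: float
    R: float = 0.0
    dP: float = 0.0
    T: float = DEFAULT_T

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be > 0")
        if not 0.0 <= self.alpha0 <= 1.0:
            raise ValueError("alpha0 must lie in [0, 1]")
        if self.z < 0:
            raise ValueError("z is a magnitude and must be >= 0")
        if self.X < 0:
            raise ValueError("X must be >= 0")
        if self.R < 0:
            raise ValueError("R must be >= 0")
        if self.dP < 0:
            raise ValueError("dP must be >= 0")


@dataclass(frozen=True)
class PumpLeakState:
    """Solved steady state: volume, ion concentrations and potential."""

    V: float
    nplus: float
    nminus: float
    x: float
    Uc: float
    Pi_in: float
    params: PumpLeakParams = field(repr=False)

    @property
    def Uc_mV(self) -> float:
        return self.Uc * thermal_voltage_mV(self.params.T)

    @property
    def wet_volume(self) -> float:
        return self.V - self.params.R

    def residuals(self) -> tuple[float, float]:
        """(electroneutrality, osmotic) residuals, relative to n0."""
        p = self.params
        elec = (self.nplus - self.nminus - p.z * self.x) / p.n0
        osm = (
            pressure_from_mM(self.nplus + self.nminus + self.x - 2 * p.n0, p.T) - p.dP
        ) / pressure_from_mM(p.n0, p.T)
        return elec, osm


def alpha0_from_pumping(arg: float) -> float:
    """Pumping efficiency ``exp(-p/(kBT g+))`` from the flux/conductance ratio."""
    if arg < 0:
        raise ValueError("pumping argument must be >= 0")
    return math.exp(-arg)


def alpha0_from_concentrations(nplus: float, nminus: float, n0: float) -> float:
    """Pumping efficiency from the ion-product law ``n+ n- = alpha0 n0^2``."""
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if nplus <= 0 or nminus <= 0:
        raise ValueError("ion concentrations must be > 0")
    return nplus * nminus / n0**2


def donnan_potential(nminus: float, n0: float) -> float:
    """Donnan potential ``Uc = ln(n-/n0)`` in kBT/e units.

    The anion Boltzmann factor is used; the cation relation is shifted by
    pumping and would not reproduce the membrane potential.
    """
    if nminus <= 0 or n0 <= 0:
        raise ValueError("concentrations must be > 0")
    return math.log(nminus / n0)


def donnan_potential_mV(nminus: float, n0: float, T: float = DEFAULT_T) -> float:
    """Donnan potential in millivolts at temperature ``T``."""
    return donnan_potential(nminus, n0) * thermal_voltage_mV(T)


def impermeant_concentration_from_balance(
    nplus: float, nminus: float, n0: float, dP: float = 0.0, T: float = DEFAULT_T
) -> float:
    """Impermeant concentration x (mM) from the osmotic balance.

    ``x = 2 n0 - n+ - n- + dP/kBT`` with ``dP`` converted to mM equivalents.
    """
    if min(nplus, nminus, n0) < 0 or dP < 0:
        raise ValueError("inputs must be >= 0")
    x = 2 * n0 - nplus - nminus + float(mM_from_pressure(dP, T))
    if x < 0:
        raise ValueError(
            "inconsistent inputs: osmotic balance implies negative impermeant "
            f"concentration ({x:.3g} mM)"
        )
    return x


def mean_charge_from_electroneutrality(nplus: float, nminus: float, x: float) -> float:
    """Mean valence magnitude ``z = (n+ - n-)/x`` from electroneutrality."""
    if x <= 0:
        raise ValueError("x must be > 0")
    return (nplus - nminus) / x


def osmotic_pressure(concentration_sum: float, T: float = DEFAULT_T) -> float:
    """Van 't Hoff pressure (Pa) of a total osmolyte concentration (mM)."""
    if np.any(np.asarray(concentration_sum) < 0):
        raise ValueError("concentration must be >= 0")
    return float(pressure_from_mM(concentration_sum, T))


def volume_infinite_pumping(X: float, z: float, n0: float, R: float = 0.0) -> float:
    """Volume (um^3) in the infinite-pumping limit: ``V = R + (z+1) X / (2 n0)``.

    The wet volume holds the impermeant particles and their ``z`` counterions
    at total concentration ``2 n0``.
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    return R + (z + 1) * X * CONC_UM3_PER_COUNT / (2 * n0)


def _ion_concentrations(x: float, z: float, alpha0: float, n0: float) -> tuple[float, float]:
    """Closed-form n+/n- satisfying electroneutrality and the ion product."""
    s = math.sqrt((z * x) ** 2 + 4 * alpha0 * n0**2)
    # round-off can leave a tiny negative anion concentration at alpha0 ~ 0
    return (z * x + s) / 2, max((-z * x + s) / 2, 0.0)


def solve_steady_state(params: PumpLeakParams) -> PumpLeakState:
    """Solve the Pump-Leak steady state for the volume and ion concentrations.

    Electroneutrality and the ion-product law give ``n+ + n- =
    sqrt(z^2 x^2 + 4 alpha0 n0^2)``, leaving a scalar osmotic residual that
    is strictly decreasing in V; it is bracketed and solved with Brent's
    method, then all invariants are checked.
    """
    p = params
    dP_mM = float(mM_from_pressure(p.dP, p.T))
    target = 2 * p.n0 + dP_mM  # required internal osmolarity, mM

    if p.X == 0:
        # no impermeants: osmolarity is 2 n0 sqrt(alpha0), volume indeterminate
        raise InfeasibleError(
            "X = 0: internal osmolarity is fixed at 2*n0*sqrt(alpha0) and "
            "cannot match the external value; the volume is indeterminate"
        )
    if p.alpha0 >= 1.0 and p.dP == 0:
        raise VolumeDivergenceError(
            "alpha0 = 1 with dP = 0: the Pump-Leak model predicts a diverging volume"
        )
    if 2 * p.n0 * math.sqrt(p.alpha0) >= target:
        raise VolumeDivergenceError(
            "pumping too weak for the imposed pressure: ion osmolarity alone "
            "exceeds the osmotic balance target, the volume diverges"
        )

    def residual(V: float) -> float:
        x = p.X * CONC_UM3_PER_COUNT / (V - p.R)
        np_, nm = _ion_concentrations(x, p.z, p.alpha0, p.n0)
        return np_ + nm + x - target

    # The infinite-pumping volume is a lower bound (alpha0 adds ions, which
    # swell the cell); expand upward until the residual changes sign.
    v_lo_wet = (p.z + 1) * p.X * CONC_UM3_PER_COUNT / target
    v_lo = p.R + v_lo_wet
    v_hi = p.R + 2 * v_lo_wet
    while residual(v_hi) > 0:
        v_hi = p.R + (v_hi - p.R) * 2
        if v_hi - p.R > 1e18:
            raise InfeasibleError("no root with V > R found")
    while residual(v_lo) < 0:
        v_lo = p.R + (v_lo - p.R) / 2

    V = brentq(residual, v_lo, v_hi, xtol=1e-14, rtol=1e-15)
    x = p.X * CONC_UM3_PER_COUNT / (V - p.R)
    nplus, nminus = _ion_concentrations(x, p.z, p.alpha0, p.n0)
    if nminus <= 0:  # alpha0 = 0 exactly: no free anions
        Uc = -math.inf
    else:
        Uc = donnan_potential(nminus, p.n0)
    state = PumpLeakState(
        V=V,
        nplus=nplus,
        nminus=nminus,
        x=x,
        Uc=Uc,
        Pi_in=osmotic_pressure(nplus + nminus + x, p.T),
        params=p,
    )
    elec, osm = state.residuals()
    if abs(elec) > 1e-10 or abs(osm) > 1e-8:
        raise InfeasibleError(f"solver residuals too large: elec={elec:g}, osm={osm:g}")
    return state


def dry_mass_density(
    Ptot: float,
    Af: float,
    Ma: float = 110.0,
    lp: float = 400.0,
    vp: float = 4.0e-8,
    zAf: float = 1.0,
    n0: float = 150.0,
) -> float:
    """Dry mass density (kg/L) of a cell of proteins plus free amino acids.

    ``rho = Ma lp Ptot / (vp Ptot + (zAf+1) Af / (2 n0))``: the numerator is
    the protein mass, the denominator the protein excluded volume plus the
    wet volume tied to the amino-acid pool and its counterions.

    Parameters use package units: ``Ma`` in Da (mean amino-acid mass),
    ``lp`` residues per protein, ``vp`` protein excluded volume in um^3
    (default 4e-8 um^3 = 4e-26 m^3, i.e. ~0.1 nm^3 per residue), ``n0``
    in mM.  Scale-invariant in (Ptot, Af): doubling both leaves rho fixed.
    """
    if Ptot < 0 or Af < 0:
        raise ValueError("counts must be >= 0")
    if Ptot == 0 and Af == 0:
        raise ValueError("Ptot and Af cannot both be zero")
    from .constants import DA

    mass_kg = Ma * DA * lp * Ptot
    vol_um3 = vp * Ptot + (zAf + 1) * Af * CONC_UM3_PER_COUNT / (2 * n0)
    if vol_um3 <= 0:
        raise ValueError("volume must be > 0")
    vol_L = vol_um3 * 1e-15
    return mass_kg / vol_L
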