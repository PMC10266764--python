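"""Nested Pump-Leak model: nucleus plus cytoplasm.

The Pump-Leak constraints (electroneutrality, osmotic balance, ion flux
balance) are written in both compartments.  Four osmolyte classes play
asymmetric roles:

* chromatin — a polyelectrolyte gel with effective charge ``Qeff``; it has
  no translational entropy and enters only through its free counterions;
* proteins — trapped in their compartment by nucleo-cytoplasmic transport
  (counts ``Pn``, ``Pc``, valence magnitude ``zp``);
* metabolites — permeant across the nuclear envelope but not the plasma
  membrane (total count ``Af_tot``, valence magnitude ``za``), partitioned
  across the envelope by the Boltzmann factor of the envelope potential;
* ions — permeant everywhere, pumped at the plasma membrane
  (efficiency ``alpha0``) and Boltzmann-partitioned at the envelope.

Electroneutrality in the nucleus forces a Donnan-type nuclear envelope
potential ``Un`` tied to the chromatin counterion concentration.  Envelope
mechanics are fold-buffered: membrane stored in folds (area fraction
``s``) keeps the envelope tension at zero until the area reservoir is
exhausted, after which tension grows linearly with stretching modulus
``K`` and the Laplace pressure opposes further swelling.

Units: mM, um^3, counts, mN/m for tension, Pa for pressures, kBT/e for
potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .constants import CONC_UM3_PER_COUNT, DEFAULT_T, KB, mM_from_pressure, thermal_voltage_mV

__all__ = [
    "NestedParams",
    "NestedState",
    "default_nested_params",
    "solve_nested",
    "nuclear_potential",
    "nc_limits",
    "linear_scaling",
    "metabolite_partition",
    "nuclear_volume_pressure_regime",
    "envelope_tension",
    "max_swelling",
    "osmotic_shock_sweep",
    "simulate_growth_nc",
]

_GAMMA = CONC_UM3_PER_COUNT  # mM * um^3 per particle


@dataclass(frozen=True)
class NestedParams:
    """Composition and mechanics of the two-compartment model.

    ``Vn_iso`` (um^3) is the nuclear volume at the isotonic external
    concentration that defines the envelope's unfolded reference area; if
    None it is computed self-consistently from a tension-free solve.
    """

    Pn: float
    Pc: float
    Af_tot: float
    Qeff: float
    zp: float = 1.0
    za: float = 1.0
    alpha0: float = 0.0
    n0: float = 150.0
    Rn: float = 0.0
    Rc: float = 0.0
    K: float = 0.0
    s: float = 0.0
    Vn_iso: float | None = None
    T: float = DEFAULT_T

    def __post_init__(self) -> None:
        if min(self.Pn, self.Pc, self.Af_tot, self.Qeff) < 0:
            raise ValueError("counts must be >= 0")
        if self.Pc <= 0:
            raise ValueError("cytoplasmic protein count must be > 0")
        if not 0.0 <= self.alpha0 < 1.0:
            raise ValueError("alpha0 must lie in [0, 1) (alpha0 -> 1 diverges)")
        if self.n0 <= 0:
            raise ValueError("n0 must be > 0")
        if self.zp < 0 or self.za < 0:
            raise ValueError("valences are magnitudes and must be >= 0")
        if self.K < 0 or self.s < 0:
            raise ValueError("K and s must be >= 0")


@dataclass(frozen=True)
class NestedState:
    """Solved state of the nested model."""

    Vn: float
    Vc: float
    pn: float
    pc: float
    anf: float
    acf: float
    nn_plus: float
    nn_minus: float
    nc_plus: float
    nc_minus: float
    qeff: float
    Un: float
    gamma_n: float
    dPn: float
    params: NestedParams = field(repr=False)

    @property
    def NC(self) -> float:
        return self.Vn / self.Vc

    @property
    def Un_mV(self) -> float:
        return self.Un * thermal_voltage_mV(self.params.T)

    @property
    def Nn_tot(self) -> float:
        """Total free osmolyte count in the nucleus."""
        wn = self.Vn - self.params.Rn
        return (self.pn + self.anf + self.nn_plus + self.nn_minus) * wn / _GAMMA

    @property
    def Nc_tot(self) -> float:
        """Total free osmolyte count in the cytoplasm."""
        wc = self.Vc - self.params.Rc
        return (self.pc + self.acf + self.nc_plus + self.nc_minus) * wc / _GAMMA

    def residuals(self) -> np.ndarray:
        """Scaled residuals of the five structural relations (should be ~0)."""
        p = self.params
        wn, wc = self.Vn - p.Rn, self.Vc - p.Rc
        sc_c = self.nc_plus + self.nc_minus + p.zp * self.pc + p.za * self.acf + p.n0
        sc_n = (
            self.nn_plus + self.nn_minus + p.zp * self.pn + p.za * self.anf + self.qeff + p.n0
        )
        sum_c = self.nc_plus + self.nc_minus + self.pc + self.acf
        sum_n = self.nn_plus + self.nn_minus + self.pn + self.anf
        dpn_mM = float(mM_from_pressure(self.dPn, p.T))
        elec_c = (self.nc_plus - self.nc_minus - p.zp * self.pc - p.za * self.acf) / sc_c
        elec_n = (
            self.nn_plus - self.nn_minus - p.zp * self.pn - p.za * self.anf - self.qeff
        ) / sc_n
        osm_c = (sum_c - 2 * p.n0) / (2 * p.n0)
        osm_n = (sum_n - sum_c - dpn_mM) / (sum_n + sum_c + dpn_mM)
        metab = (self.acf * wc + self.anf * wn - p.Af_tot * _GAMMA) / max(
            p.Af_tot * _GAMMA, p.n0 * wc
        )
        return np.array([elec_c, elec_n, osm_c, osm_n, metab])


def nuclear_potential(qeff: float, n0: float) -> float:
    """Envelope potential ``Un = -ln(1 + qeff/(2 n0))`` (kBT/e units).

    Valid in the monovalent high-pumping regime (zp = za = 1, alpha0 = 0);
    0 for diluted chromatin, saturating to ``-ln 2`` at high charge.
    """
    if qeff < 0 or n0 <= 0:
        raise ValueError("qeff must be >= 0 and n0 > 0")
    return -math.log1p(qeff / (2 * n0))


def nc_limits(Pn: float, Pc: float, Qeff: float) -> tuple[float, float]:
    """Limiting NC ratios: metabolite-dominated ``NC1 = Pn/Pc`` and
    metabolite-free ``NC2 = (Pn + Qeff/2)/Pc``."""
    if Pc <= 0:
        raise ValueError("Pc must be > 0")
    return Pn / Pc, (Pn + Qeff / 2.0) / Pc


def metabolite_partition(Af_tot: float, NC: float) -> float:
    """Nuclear metabolite count for neutral metabolites: ``Af/(1 + 1/NC)``."""
    if NC <= 0:
        raise ValueError("NC must be > 0")
    return Af_tot / (1.0 + 1.0 / NC)


def nuclear_volume_pressure_regime(
    Pn: float, dPn: float, pc: float, T: float = DEFAULT_T
) -> float:
    """Nuclear volume (um^3) when only trapped proteins and the envelope
    pressure matter: ``Vn = Pn/(dPn/kBT + pc)`` with dPn in Pa, pc in mM."""
    if dPn < 0 or pc <= 0:
        raise ValueError("dPn must be >= 0 and pc > 0")
    return Pn * _GAMMA / (float(mM_from_pressure(dPn, T)) + pc)


def _sphere_area(V: float) -> float:
    """Surface area (um^2) of a sphere of volume V (um^3)."""
    return (36.0 * math.pi) ** (1.0 / 3.0) * V ** (2.0 / 3.0)


def _sphere_radius(V: float) -> float:
    return (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)


def envelope_tension(
    Vn: float, Vn_iso: float | None, s: float, K: float
) -> tuple[float, float]:
    """Fold-buffered envelope tension (mN/m) and Laplace pressure (Pa).

    The unfolded reference area is ``A0*(1+s)`` with ``A0`` the sphere area
    at ``Vn_iso``; tension is zero while folds remain, then grows linearly
    with areal strain at modulus ``K``.  ``dPn = 2*gamma/r``.
    """
    if Vn <= 0:
        raise ValueError("Vn must be > 0")
    if K == 0 or Vn_iso is None or s is None:
        return 0.0, 0.0
    a0 = _sphere_area(Vn_iso) * (1.0 + s)
    a = _sphere_area(Vn)
    if a <= a0:
        return 0.0, 0.0
    gamma = K * (a - a0) / a0  # mN/m
    dpn = 2.0 * gamma * 1e-3 / (_sphere_radius(Vn) * 1e-6)  # Pa
    return gamma, dpn


def max_swelling(params: NestedParams, Nn_tot: float | None = None) -> float:
    """Saturated nuclear swelling ``Vn_max/Vn_iso`` under strong hypo-osmotic
    shock, from the fold-buffered mechanics closed form.

    ``Vmax/Viso = (1+s)^(3/2)/(2 sqrt 2) * (1 + sqrt(1 + 1/((1+s) Keff)))^(3/2)``
    with ``Keff = K / (kBT * (Nn/Viso) * (6 Viso/pi)^(1/3))``.  By default
    ``Nn = (zp+1) Pn + Qeff``: at saturation no metabolites remain in the
    nucleus.  Tends to the area-limited bound ``(1+s)^(3/2)`` as K -> inf.
    """
    p = params
    if p.K <= 0 or p.Vn_iso is None or p.Vn_iso <= 0:
        raise ValueError("max_swelling needs K > 0 and Vn_iso")
    n = Nn_tot if Nn_tot is not None else (p.zp + 1) * p.Pn + p.Qeff
    if n <= 0:
        raise ValueError("nuclear osmolyte count must be > 0")
    viso_m3 = p.Vn_iso * 1e-18
    keff = (p.K * 1e-3) / (KB * p.T * (n / viso_m3) * (6.0 * viso_m3 / math.pi) ** (1.0 / 3.0))
    return (
        (1.0 + p.s) ** 1.5
        / (2.0 * math.sqrt(2.0))
        * (1.0 + math.sqrt(1.0 + 1.0 / ((1.0 + p.s) * keff))) ** 1.5
    )


# ---------------------------------------------------------------------------
# full solver


def _unpack(u: np.ndarray, p: NestedParams, has_metab: bool):
    # clip log variables so wild solver steps cannot overflow exp
    if has_metab:
        lwn, lwc, lacf, lncp, un = np.clip(u, -500.0, 500.0)
        acf = math.exp(lacf)
    else:
        lwn, lwc, lncp, un = np.clip(u, -500.0, 500.0)
        acf = 0.0
    wn, wc, ncp = math.exp(lwn), math.exp(lwc), math.exp(lncp)
    return wn, wc, acf, ncp, un


def _residual_vec(u: np.ndarray, p: NestedParams, has_metab: bool, mechanics: bool):
    wn, wc, acf, ncp, un = _unpack(u, p, has_metab)
    pn = p.Pn * _GAMMA / wn
    pc = p.Pc * _GAMMA / wc
    qeff = p.Qeff * _GAMMA / wn
    anf = acf * math.exp(p.za * un)
    ncm = p.alpha0 * p.n0**2 / ncp
    nnp = ncp * math.exp(-un)
    nnm = ncm * math.exp(un)
    # each residual is scaled by the magnitude of its own equation so the
    # relative tolerance stays meaningful across extreme osmolarity sweeps
    sc_c = ncp + ncm + p.zp * pc + p.za * acf + p.n0
    sc_n = nnp + nnm + p.zp * pn + p.za * anf + qeff + p.n0
    sum_c = ncp + ncm + pc + acf
    sum_n = nnp + nnm + pn + anf
    res = [
        (ncp - ncm - p.zp * pc - p.za * acf) / sc_c,
        (nnp - nnm - p.zp * pn - p.za * anf - qeff) / sc_n,
        (sum_c - 2 * p.n0) / (2 * p.n0),
    ]
    if mechanics:
        _, dpn = envelope_tension(wn + p.Rn, p.Vn_iso, p.s, p.K)
    else:
        dpn = 0.0
    dpn_mM = float(mM_from_pressure(dpn, p.T))
    res.append((sum_n - sum_c - dpn_mM) / (sum_n + sum_c + dpn_mM))
    if has_metab:
        res.append((acf * wc + anf * wn - p.Af_tot * _GAMMA) / (p.Af_tot * _GAMMA))
    return np.array(res)


def _initial_guess(p: NestedParams, has_metab: bool) -> np.ndarray:
    """Fixed-point guess: osmolarity 2 n0 in each compartment, metabolites
    distributed proportionally to wet volume, no envelope potential bias."""
    inflation = 1.0 / max(1.0 - math.sqrt(p.alpha0), 0.05)
    trap_n = (p.zp + 1) * p.Pn + p.Qeff
    trap_c = (p.zp + 1) * p.Pc
    fn = trap_n / (trap_n + trap_c)
    for _ in range(50):
        xn = trap_n + (p.za + 1) * p.Af_tot * fn
        xc = trap_c + (p.za + 1) * p.Af_tot * (1 - fn)
        fn_new = xn / (xn + xc)
        if abs(fn_new - fn) < 1e-12:
            fn = fn_new
            break
        fn = fn_new
    wn = max(xn * _GAMMA / (2 * p.n0) * inflation, 1e-12)
    wc = max(xc * _GAMMA / (2 * p.n0) * inflation, 1e-12)
    acf = p.Af_tot * _GAMMA / (wn + wc) if has_metab else 0.0
    b = p.zp * p.Pc * _GAMMA / wc + p.za * acf
    ncp = (b + math.sqrt(b**2 + 4 * p.alpha0 * p.n0**2)) / 2
    ncp = max(ncp, 1e-9 * p.n0)
    un = nuclear_potential(p.Qeff * _GAMMA / wn, p.n0)
    if has_metab:
        return np.array([math.log(wn), math.log(wc), math.log(acf), math.log(ncp), un])
    return np.array([math.log(wn), math.log(wc), math.log(ncp), un])


def solve_nested(
    params: NestedParams,
    mechanics: bool = True,
    guess: np.ndarray | None = None,
) -> NestedState:
    """Solve the nested Pump-Leak system for both volumes, concentrations,
    envelope potential and tension.

    The system couples both electroneutralities, the plasma osmotic balance
    (no hydrostatic pressure at the plasma membrane), the envelope osmotic
    balance with the fold-buffered Laplace pressure, the plasma ion-product
    law, Boltzmann partitioning of ions and metabolites across the envelope
    and metabolite conservation.  Solved in log variables with a
    volume-proportional fixed point as the initial guess.
    """
    p = params
    has_metab = p.Af_tot > 0
    n_unknowns = 5 if has_metab else 4
    guesses = []
    if guess is not None and len(guess) == n_unknowns:
        guesses.append(np.asarray(guess, dtype=float))
    g0 = _initial_guess(p, has_metab)
    guesses.append(g0)
    g1 = g0.copy()
    g1[-1] = 0.0
    guesses.append(g1)

    best = None
    for u0 in guesses:
        sol = root(
            _residual_vec,
            u0,
            args=(p, has_metab, mechanics),
            method="hybr",
            options={"xtol": 1e-13, "maxfev": 4000},
        )
        res = _residual_vec(sol.x, p, has_metab, mechanics)
        if best is None or np.max(np.abs(res)) < best[1]:
            best = (sol.x, float(np.max(np.abs(res))))
        if best[1] < 1e-9:
            break
    if best is None or best[1] > 1e-9:
        raise RuntimeError(
            f"nested Pump-Leak solver did not converge (max residual {best[1]:.2e})"
        )
    u = best[0]
    wn, wc, acf, ncp, un = _unpack(u, p, has_metab)
    pn = p.Pn * _GAMMA / wn
    pc = p.Pc * _GAMMA / wc
    qeff = p.Qeff * _GAMMA / wn
    anf = acf * math.exp(p.za * un)
    ncm = p.alpha0 * p.n0**2 / ncp
    nnp = ncp * math.exp(-un)
    nnm = ncm * math.exp(un)
    if mechanics:
        gamma_n, dpn = envelope_tension(wn + p.Rn, p.Vn_iso, p.s, p.K)
    else:
        gamma_n, dpn = 0.0, 0.0
    return NestedState(
        Vn=wn + p.Rn,
        Vc=wc + p.Rc,
        pn=pn,
        pc=pc,
        anf=anf,
        acf=acf,
        nn_plus=nnp,
        nn_minus=nnm,
        nc_plus=ncp,
        nc_minus=ncm,
        qeff=qeff,
        Un=un,
        gamma_n=gamma_n,
        dPn=dpn,
        params=p,
    )


def linear_scaling(params: NestedParams, state: NestedState) -> tuple[float, float]:
    """Slope and intercept of the tension-free nuclear scaling law
    ``Vn = (Nn/Nc) Vc + (Rn - (Nn/Nc) Rc)``."""
    if state.gamma_n > 1e-9:
        raise ValueError("linear scaling holds only in the tension-free regime")
    slope = state.Nn_tot / state.Nc_tot
    return slope, params.Rn - slope * params.Rc


def osmotic_shock_sweep(
    params: NestedParams, n0_grid: np.ndarray, mechanics: bool = True
) -> pd.DataFrame:
    """Quasi-static nuclear response to a sweep of external concentrations.

    ``n0_grid`` must be decreasing (hypo-osmotic shock).  The isotonic
    reference state is solved tension-free at ``params.n0`` to fix
    ``Vn_iso`` (the fold reservoir is defined in the isotonic state), then
    the full system is solved per grid value with continuation.  The
    constant-content counterfactual (nuclear osmolyte number frozen at its
    isotonic value) is reported alongside.
    """
    n0_grid = np.asarray(n0_grid, dtype=float)
    if np.any(np.diff(n0_grid) >= 0):
        raise ValueError("n0_grid must be strictly decreasing")
    p = params
    iso = solve_nested(p, mechanics=False)
    viso = iso.Vn
    nn_iso = iso.Nn_tot
    p = replace(p, Vn_iso=viso)

    has_metab = p.Af_tot > 0
    guess = None
    rows = []
    for n0 in n0_grid:
        pi = replace(p, n0=float(n0))
        st = solve_nested(pi, mechanics=mechanics, guess=guess)
        wn = st.Vn - pi.Rn
        guess = (
            np.array([math.log(wn), math.log(st.Vc - pi.Rc), math.log(st.acf), math.log(st.nc_plus), st.Un])
            if has_metab
            else np.array([math.log(wn), math.log(st.Vc - pi.Rc), math.log(st.nc_plus), st.Un])
        )
        vn_cf = _constant_content_volume(pi, nn_iso, mechanics=mechanics)
        rows.append(
            {
                "n0": n0,
                "n0_rel": n0 / params.n0,
                "Vn": st.Vn,
                "Vn_norm": st.Vn / viso,
                "Vn_norm_counterfactual": vn_cf / viso,
                "Un": st.Un,
                "gamma_n": st.gamma_n,
                "dPn": st.dPn,
                "NC": st.NC,
            }
        )
    return pd.DataFrame(rows)


def _constant_content_volume(p: NestedParams, nn_tot: float, mechanics: bool = True) -> float:
    """Nuclear volume if the nuclear osmolyte count were frozen.

    Solves ``kBT (Nn/(Vn-Rn) - 2 n0) = dPn(Vn)`` for Vn; the cytoplasmic
    osmolarity stays at 2 n0 by plasma osmotic balance.
    """

    def f(vn: float) -> float:
        cn = nn_tot * _GAMMA / (vn - p.Rn)
        if mechanics:
            _, dpn = envelope_tension(vn, p.Vn_iso, p.s, p.K)
        else:
            dpn = 0.0
        return cn - 2 * p.n0 - float(mM_from_pressure(dpn, p.T))

    lo = p.Rn + nn_tot * _GAMMA / (2 * p.n0) / 1e3
    hi = p.Rn + nn_tot * _GAMMA / (2 * p.n0) * 1e6
    while f(lo) < 0:
        lo = p.Rn + (lo - p.Rn) / 10
    while f(hi) > 0:
        hi = p.Rn + (hi - p.Rn) * 10
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)


def simulate_growth_nc(
    params: NestedParams,
    growth_df: pd.DataFrame,
    fn: float = 0.25,
) -> pd.DataFrame:
    """Quasi-static NC ratio and envelope potential along a growth trajectory.

    The trajectory (from :func:`cellscale.growth.simulate_growth`) supplies
    total protein and free-metabolite counts; proteins are split between
    nucleus and cytoplasm at the fixed transport ratio ``fn`` and the
    chromatin charge is constant through G1.  Solved tension-free.
    """
    if not 0 < fn < 1:
        raise ValueError("fn must be in (0, 1)")
    guess = None
    rows = []
    has_metab = None
    for _, r in growth_df.iterrows():
        ptot, af = float(r["Ptot"]), float(r["Af"])
        pi = replace(params, Pn=fn * ptot, Pc=(1 - fn) * ptot, Af_tot=af)
        if has_metab is None:
            has_metab = pi.Af_tot > 0
        st = solve_nested(pi, mechanics=False, guess=guess)
        wn, wc = st.Vn - pi.Rn, st.Vc - pi.Rc
        guess = (
            np.array([math.log(wn), math.log(wc), math.log(st.acf), math.log(st.nc_plus), st.Un])
            if has_metab
            else np.array([math.log(wn), math.log(wc), math.log(st.nc_plus), st.Un])
        )
        rows.append({"t_h": float(r["t_h"]), "NC": st.NC, "Un": st.Un, "Vn": st.Vn, "Vc": st.Vc})
    df = pd.DataFrame(rows)
    df["NC_norm"] = df["NC"] / df["NC"].iloc[0]
    df["Un_norm"] = df["Un"] / df["Un"].iloc[0] if df["Un"].iloc[0] != 0 else np.nan
    return df


def default_nested_params() -> NestedParams:
    """Composition of a typical mammalian cell in the monovalent
    high-pumping regime: chromatin counterions comparable to trapped
    nuclear proteins, metabolites ~60x the chromatin counterions, folded
    envelope with K = 50 mN/m and 4% area reserve."""
    return NestedParams(
        Pn=1.0e9,
        Pc=3.3e9,
        Af_tot=1.2e11,
        Qeff=2.0e9,
        zp=1.0,
        za=1.0,
        alpha0=0.0,
        n0=150.0,
        K=50.0,
        s=0.04,
    )
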