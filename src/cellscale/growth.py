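"""Regime-switching model of transcription, translation and amino-acid
biosynthesis coupled to the Pump-Leak volume.

Four protein classes are tracked: ribosomes (``r``), RNA polymerases
(``p``), amino-acid biosynthesis enzymes (``e``) and everything else
(``o``).  While neither DNA nor mRNA is saturated, mRNA production is
proportional to the RNAP count and protein production to the ribosome
count, so every class grows exponentially at the ribosome-formation rate
``kr = kt*phi_r - 1/tau_p``.  When the RNAP count exceeds the number of
available gene-binding sites (``Pp* = Npmax * sum(g)``) mRNA numbers
plateau, and when the ribosome count exceeds the available mRNA sites
(``Pr* = Nrmax * Npmax * k0 * tau_m * sum(g)``) protein numbers relax to a
plateau with timescale ``tau_p``.  Free amino acids then keep accumulating
linearly, so the volume grows linearly while the dry mass is constant:
the dry-mass density is diluted.

Counts are continuous (deterministic mean-field model); the transitions
NONSAT -> DNA_SAT -> MRNA_SAT are sharp and irreversible.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import CONC_UM3_PER_COUNT, DA
from .pumpleak import dry_mass_density

__all__ = [
    "Regime",
    "GrowthParams",
    "default_growth_params",
    "CLASSES",
    "mrna_quasistatic",
    "production_rates",
    "amino_acid_rate",
    "saturation_thresholds",
    "saturation_time",
    "growth_rate",
    "pool_ratio",
    "homeostatic_density",
    "linear_regime_density",
    "simulate_growth",
    "ploidy_report",
]

CLASSES = ("r", "p", "e", "o")


class Regime(enum.Enum):
    NONSAT = "NONSAT"
    DNA_SAT = "DNA_SAT"
    MRNA_SAT = "MRNA_SAT"


@dataclass(frozen=True)
class GrowthParams:
    """Rates, gene fractions and composition constants of the growth model.

    Rates are per hour, times in hours, counts dimensionless, ``vp`` in
    um^3, ``Ma`` in Da, ``n0`` in mM.  ``phi`` are gene fractions summing
    to 1, ``g`` gene copy numbers per class, ``P0`` initial protein counts.
    ``rho_w`` is the effective water density in kg/L, renormalized upward
    because the model books all dry mass as protein.
    """

    k0: float
    kt: float
    tau_m: float
    tau_p: float
    phi: dict[str, float]
    g: dict[str, float]
    Npmax: float
    Nrmax: float
    kcat: float
    lp: float
    vp: float
    Ma: float
    zAf: float
    n0: float
    P0: dict[str, float]
    rho_w: float = 1.04

    def __post_init__(self) -> None:
        if min(self.k0, self.kt, self.tau_m, self.tau_p, self.kcat) <= 0:
            raise ValueError("rates and lifetimes must be > 0")
        if set(self.phi) != set(CLASSES) or set(self.g) != set(CLASSES) or set(self.P0) != set(CLASSES):
            raise ValueError(f"phi, g and P0 must have keys {CLASSES}")
        if abs(sum(self.phi.values()) - 1.0) > 1e-9:
            raise ValueError("gene fractions phi must sum to 1")
        if self.kt * self.phi["r"] <= 1.0 / self.tau_p:
            raise ValueError("kt*phi_r must exceed 1/tau_p for positive growth")

    @property
    def g_tot(self) -> float:
        return sum(self.g.values())

    @property
    def phi_vec(self) -> np.ndarray:
        return np.array([self.phi[c] for c in CLASSES])

    @property
    def g_vec(self) -> np.ndarray:
        return np.array([self.g[c] for c in CLASSES])

    @property
    def P0_vec(self) -> np.ndarray:
        return np.array([self.P0[c] for c in CLASSES])


def growth_rate(params: GrowthParams) -> float:
    """Effective ribosome-formation rate ``kr = kt*phi_r - 1/tau_p`` (1/h)."""
    return params.kt * params.phi["r"] - 1.0 / params.tau_p


def pool_ratio(params: GrowthParams) -> float:
    """Flux ratio ``lambda = phi_e*kcat/(lp*kr)`` of amino-acid production
    to consumption in the exponential regime.

    The steady amino-acid/protein-residue pool ratio is ``lambda - 1``;
    the homeostatic-density formula assumes ``lambda >> 1``.
    """
    return params.phi["e"] * params.kcat / (params.lp * growth_rate(params))


def mrna_quasistatic(Pp: float, params: GrowthParams) -> np.ndarray:
    """Quasistatic mRNA counts ``Mj = k0*tau_m*phi_j*Pp`` (nonsaturated DNA).

    mRNA lifetimes are much shorter than protein lifetimes, so mRNA counts
    track the RNAP count adiabatically.
    """
    pstar, _ = saturation_thresholds(params)
    if Pp > pstar * (1 + 1e-12):
        raise ValueError("DNA is saturated: the quasistatic nonsaturated form does not apply")
    return params.k0 * params.tau_m * params.phi_vec * Pp


def saturation_thresholds(params: GrowthParams) -> tuple[float, float]:
    """RNAP and ribosome counts at which DNA, then mRNA, saturate.

    ``Pp* = Npmax * sum(g)`` (all gene sites occupied) and
    ``Pr* = Nrmax * Npmax * k0 * tau_m * sum(g)`` (all sites of the
    plateaued mRNA pool occupied).
    """
    pp_star = params.Npmax * params.g_tot
    pr_star = params.Nrmax * params.Npmax * params.k0 * params.tau_m * params.g_tot
    return pp_star, pr_star


def saturation_time(params: GrowthParams) -> float:
    """Time t** (h) at which ribosomes saturate the mRNA pool.

    ``t** = ln(Pr*/Pr0) / kr``; returns 0 if the pool is saturated already.
    """
    pr0 = params.P0["r"]
    if pr0 <= 0:
        raise ValueError("initial ribosome count must be > 0")
    _, pr_star = saturation_thresholds(params)
    if pr_star <= pr0:
        return 0.0
    return math.log(pr_star / pr0) / growth_rate(params)


def production_rates(
    M: np.ndarray, P: np.ndarray, regime: Regime, params: GrowthParams
) -> tuple[np.ndarray, np.ndarray]:
    """Regime-appropriate (dM/dt, dP/dt) per class.

    The mRNA source is ``k0*phi_j*Pp`` below DNA saturation and
    ``k0*gj*Npmax`` above; the protein source is ``kt*(Mj/sum M)*Pr`` below
    mRNA saturation and ``kt*Mj*Nrmax`` above.  Degradation ``-Mj/tau_m``
    and ``-Pj/tau_p`` is always present.
    """
    M = np.asarray(M, dtype=float)
    P = np.asarray(P, dtype=float)
    Pp = P[CLASSES.index("p")]
    Pr = P[CLASSES.index("r")]
    if regime is Regime.NONSAT:
        m_src = params.k0 * params.phi_vec * Pp
    else:
        m_src = params.k0 * params.g_vec * params.Npmax
    if regime is Regime.MRNA_SAT:
        p_src = params.kt * M * params.Nrmax
    else:
        msum = M.sum()
        p_src = params.kt * (M / msum) * Pr if msum > 0 else np.zeros_like(M)
    dM = m_src - M / params.tau_m
    dP = p_src - P / params.tau_p
    return dM, dP


def amino_acid_rate(Pe: float, dPtot_dt: float, params: GrowthParams) -> float:
    """Free amino-acid rate ``dAf/dt = kcat*Pe - lp*dPtot/dt`` (1/h)."""
    return params.kcat * Pe - params.lp * dPtot_dt


def homeostatic_density(params: GrowthParams) -> float:
    """Homeostatic dry-mass density (kg/L) of the exponential regime.

    In exponential growth the free amino-acid pool locks to
    ``Af = lp*(lambda-1)*Ptot``, making the density independent of time
    and of the initial protein content.
    """
    lam = pool_ratio(params)
    if lam <= 1:
        raise ValueError(
            "phi_e*kcat/(lp*kr) must exceed 1: amino-acid production cannot "
            "sustain the protein pool (density singularity)"
        )
    return dry_mass_density(
        1.0,
        params.lp * (lam - 1.0),
        Ma=params.Ma,
        lp=params.lp,
        vp=params.vp,
        zAf=params.zAf,
        n0=params.n0,
    )


def linear_regime_density(t: float | np.ndarray, params: GrowthParams) -> float | np.ndarray:
    """Dry-mass density (kg/L) in the linear (saturated) regime.

    ``t`` is measured from the saturation time t**.  The protein pool is
    constant while amino acids accumulate at rate ``kcat*phi_e`` per
    protein, so the density decays as 1/t.
    """
    t = np.asarray(t, dtype=float)
    kr = growth_rate(params)
    ratio = (
        params.phi["e"] * params.kcat / (params.phi["r"] * kr * params.kt * params.lp * params.tau_p)
        - 1.0
        + params.kcat * params.phi["e"] * t / params.lp
    )
    out = np.array(
        [
            dry_mass_density(
                1.0, params.lp * r, Ma=params.Ma, lp=params.lp, vp=params.vp,
                zAf=params.zAf, n0=params.n0,
            )
            for r in np.atleast_1d(ratio)
        ]
    )
    return out if t.ndim else float(out[0])


def _volume(P: np.ndarray, Af: float, params: GrowthParams) -> float:
    """Cell volume (um^3): protein dry volume plus amino-acid wet volume."""
    ptot = P.sum()
    wet = (params.zAf + 1) * Af * CONC_UM3_PER_COUNT / (2 * params.n0)
    return params.vp * ptot + wet


def simulate_growth(params: GrowthParams, t_grid: np.ndarray) -> pd.DataFrame:
    """Integrate the class ODEs with sharp regime switching.

    Returns a DataFrame with one row per grid time: mRNA and protein counts
    per class, free amino acids, volume (fL), dry mass (pg), dry and total
    mass densities (kg/L) and the regime label.  Switch times are located
    by event detection, keeping trajectories continuous.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    pp_star, _ = saturation_thresholds(params)
    nr_max = params.Nrmax

    def rhs(regime: Regime):
        def f(t, y):
            M, P, _ = y[:4], y[4:8], y[8]
            dM, dP = production_rates(M, P, regime, params)
            dAf = amino_acid_rate(P[CLASSES.index("e")], dP.sum(), params)
            return np.concatenate([dM, dP, [dAf]])
        return f

    def ev_dna(t, y):
        return y[4 + CLASSES.index("p")] - pp_star

    def ev_mrna(t, y):
        return y[4 + CLASSES.index("r")] - nr_max * y[:4].sum()

    for ev in (ev_dna, ev_mrna):
        ev.terminal = True
        ev.direction = 1

    P0 = params.P0_vec.astype(float)
    M0 = mrna_quasistatic(min(P0[CLASSES.index("p")], pp_star), params)
    y0 = np.concatenate([M0, P0, [params.lp * (pool_ratio(params) - 1.0) * P0.sum()]])

    events_by_regime = {
        Regime.NONSAT: [ev_dna, ev_mrna],
        Regime.DNA_SAT: [ev_mrna],
        Regime.MRNA_SAT: [],
    }
    order = [Regime.NONSAT, Regime.DNA_SAT, Regime.MRNA_SAT]

    # skip regimes already saturated at t=0
    regime_idx = 0
    if P0[CLASSES.index("p")] >= pp_star:
        regime_idx = 1
    if P0[CLASSES.index("r")] >= nr_max * M0.sum():
        regime_idx = 2

    rows_t: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    rows_regime: list[str] = []
    t0, t_end = t_grid[0], t_grid[-1]
    y = y0
    while t0 < t_end:
        regime = order[regime_idx]
        seg_mask = (t_grid >= t0) & (t_grid <= t_end)
        sol = solve_ivp(
            rhs(regime),
            (t0, t_end),
            y,
            method="LSODA",
            rtol=1e-8,
            atol=1.0,
            events=events_by_regime[regime],
            t_eval=t_grid[seg_mask] if seg_mask.any() else None,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"growth integration failed in {regime.value}: {sol.message}")
        stop = t_end
        if sol.status == 1:  # event hit
            stop = min(te[0] for te in sol.t_events if len(te))
        t_seg = np.asarray(sol.t, dtype=float)  # may be an empty list
        y_seg = np.asarray(sol.y, dtype=float).reshape(len(y), -1)
        keep = t_seg < stop if sol.status == 1 else np.ones_like(t_seg, dtype=bool)
        rows_t.append(t_seg[keep])
        rows_y.append(y_seg[:, keep])
        rows_regime.extend([regime.value] * int(keep.sum()))
        if sol.status == 1:
            y = sol.sol(stop)
            t0 = stop
            regime_idx += 1
        else:
            break

    t_all = np.concatenate(rows_t)
    y_all = np.concatenate(rows_y, axis=1)
    regimes = np.array(rows_regime)
    on_grid = np.isin(t_all, t_grid)
    t_all, y_all, regimes = t_all[on_grid], y_all[:, on_grid], regimes[on_grid]
    rows_regime = list(regimes)
    M, P, Af = y_all[:4], y_all[4:8], y_all[8]
    ptot = P.sum(axis=0)
    V = np.array([_volume(P[:, i], Af[i], params) for i in range(len(t_all))])
    dry_kg = params.Ma * DA * params.lp * ptot
    V_L = V * 1e-15
    rho = dry_kg / V_L
    water_L = (V - params.vp * ptot) * 1e-15
    rho_tot = (dry_kg + params.rho_w * water_L) / V_L

    df = pd.DataFrame(
        {
            "t_h": t_all,
            "V_fL": V,
            "dry_mass_pg": dry_kg * 1e15,
            "rho": rho,
            "rho_tot": rho_tot,
            "Af": Af,
            "Ptot": ptot,
            "regime": rows_regime,
        }
    )
    for i, c in enumerate(CLASSES):
        df[f"P_{c}"] = P[i]
        df[f"M_{c}"] = M[i]
    return df


def ploidy_report(params: GrowthParams, ploidy_factor: float) -> dict:
    """Effect of multiplying every gene copy number by ``ploidy_factor``.

    Reports, for the base and scaled genomes: the saturation volume
    ``V* = V(t**)``, the saturation time t**, the exponential rate kr and
    the asymptotic linear-regime volume slope.  V* and the slope scale with
    ploidy; kr does not; t** shifts by ``ln(factor)/kr``.
    """
    if ploidy_factor <= 0:
        raise ValueError("ploidy_factor must be > 0")

    def metrics(p: GrowthParams) -> dict:
        kr = growth_rate(p)
        tss = saturation_time(p)
        lam = pool_ratio(p)
        v1 = _volume(p.P0_vec.astype(float), p.lp * (lam - 1.0) * p.P0_vec.sum(), p)
        v_star = v1 * math.exp(kr * tss)
        eps = 1.0 / (lam - 1.0)
        slope = (1.0 + eps) * kr * (1.0 + kr * p.tau_p) * v_star
        return {"kr": kr, "t_star2": tss, "V_star": v_star, "linear_slope": slope}

    scaled = replace(params, g={c: params.g[c] * ploidy_factor for c in CLASSES})
    base_m, scaled_m = metrics(params), metrics(scaled)
    return {
        "base": base_m,
        "scaled": scaled_m,
        "factor": ploidy_factor,
        "V_star_ratio": scaled_m["V_star"] / base_m["V_star"],
        "slope_ratio": scaled_m["linear_slope"] / base_m["linear_slope"],
        "t_star2_shift": scaled_m["t_star2"] - base_m["t_star2"],
        "kr_ratio": scaled_m["kr"] / base_m["kr"],
    }


def default_growth_params(
    kr: float = 0.5,
    t_star2: float = 164.0 / 60.0,
    tau_p: float = 69.0 / 60.0,
    v1: float = 30.0,
    lam: float = 3.5,
) -> GrowthParams:
    """Growth parameters calibrated to a non-dividing budding-yeast cell.

    The four observable targets (exponential rate ``kr``, mRNA-saturation
    time ``t_star2``, protein lifetime ``tau_p``, initial volume ``v1`` in
    fL) and the amino-acid flux ratio ``lam`` are hit by back-solving the
    translation rate, the catalytic rate, the initial protein counts and
    the ribosome packing density; the remaining microscopic constants are
    held at coarse literature-scale values.
    """
    phi = {"r": 0.3, "p": 0.05, "e": 0.2, "o": 0.45}
    g_tot, Npmax, k0, tau_m = 5000.0, 40.0, 6.0, 0.33
    lp, vp, Ma, zAf, n0 = 400.0, 4.0e-8, 110.0, 1.0, 150.0
    g = {c: phi[c] * g_tot for c in CLASSES}
    kt = (kr + 1.0 / tau_p) / phi["r"]
    kcat = lam * lp * kr / phi["e"]
    # initial counts from the volume composition V = vp*P + (zAf+1)*Af/(2 n0)
    vol_per_protein = vp + (zAf + 1) * lp * (lam - 1.0) * CONC_UM3_PER_COUNT / (2 * n0)
    ptot0 = v1 / vol_per_protein
    P0 = {c: phi[c] * ptot0 for c in CLASSES}
    # ribosome packing set so that mRNA saturation happens at t_star2
    pr_star = P0["r"] * math.exp(kr * t_star2)
    Nrmax = pr_star / (Npmax * k0 * tau_m * g_tot)
    return GrowthParams(
        k0=k0, kt=kt, tau_m=tau_m, tau_p=tau_p, phi=phi, g=g,
        Npmax=Npmax, Nrmax=Nrmax, kcat=kcat, lp=lp, vp=vp, Ma=Ma,
        zAf=zAf, n0=n0, P0=P0,
    )
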