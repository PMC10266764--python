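"""Seeded generators of synthetic observations.

These emulate the statistical structure of the published measurements the
analyses consume — single-cell volume / total-density / normalized-protein
time series of non-dividing yeast cells, and normalized nuclear-swelling
curves under hypo-osmotic shock — so every pipeline stage is testable
offline.  Noiseless output is bit-identical to the forward models; noise
is multiplicative lognormal (or additive Gaussian) with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import (
    DEFAULT_POOL_EPS,
    GrowthFitResult,
    TimeSeries,
    model_volume,
    predict_density,
    predict_protein_norm,
)
from .nucleus import NestedParams, osmotic_shock_sweep

__all__ = [
    "NoiseModel",
    "DEFAULT_CHANNEL_CV",
    "default_true_params",
    "gen_growth_timeseries",
    "gen_shock_curve",
    "gen_population",
]

#: Measurement scatter per channel: volume (microscopy), total density
#: (suspended microchannel resonator), protein (fluorescence intensity).
DEFAULT_CHANNEL_CV = {"volume": 0.02, "rho_tot": 0.005, "protein_norm": 0.05}


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: multiplicative lognormal or additive Gaussian."""

    kind: str = "multiplicative_lognormal"
    cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def apply(self, y: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.cv == 0:
            return y.copy()
        if rng is None:
            rng = np.random.default_rng(self.seed)
        if self.kind == "multiplicative_lognormal":
            sigma = np.sqrt(np.log1p(self.cv**2))
            return y * rng.lognormal(-0.5 * sigma**2, sigma, size=y.shape)
        return y + rng.normal(0.0, self.cv * np.abs(y), size=y.shape)


def default_true_params() -> GrowthFitResult:
    """Ground-truth growth parameters of the synthetic yeast experiment.

    Protein lifetime 69 min, mRNA-saturation time 164 min, exponential
    rate 0.5/h and initial volume 30 fL — the last two chosen so the
    asymptotic linear slope is ~130 fL/h, the haploid value.
    """
    return GrowthFitResult(tau_p=69.0 / 60.0, t_star2=164.0 / 60.0, kr=0.5, v1=30.0)


def gen_growth_timeseries(
    true_params=None,
    t_grid: np.ndarray | None = None,
    noise: NoiseModel | dict | None = None,
    seed: int = 0,
) -> dict[str, TimeSeries]:
    """Volume, total-density and normalized-protein series from one latent
    growth trajectory, with channel-appropriate multiplicative noise.

    ``true_params`` is a GrowthFitResult or (tau_p, t**, kr, v1) tuple;
    ``noise`` may be a single NoiseModel for all channels or a dict per
    channel label; by default each channel gets its own cv
    (:data:`DEFAULT_CHANNEL_CV`) and all draws derive from ``seed``.
    """
    if true_params is None:
        true_params = default_true_params()
    if t_grid is None:
        t_grid = np.linspace(0.0, 8.0, 60)
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)

    clean = {
        "volume": np.asarray(model_volume(t_grid, true_params)),
        "rho_tot": predict_density(true_params, t_grid).y,
        "protein_norm": predict_protein_norm(true_params, t_grid).y,
    }
    out = {}
    for label, y in clean.items():
        if isinstance(noise, NoiseModel):
            nm = noise
        elif isinstance(noise, dict) and label in noise:
            nm = noise[label]
        else:
            nm = NoiseModel(cv=DEFAULT_CHANNEL_CV[label])
        sigma = nm.cv * np.abs(y) if nm.cv > 0 else None
        out[label] = TimeSeries(t=t_grid, y=nm.apply(y, rng), sigma=sigma, label=label)
    return out


def gen_shock_curve(
    params: NestedParams,
    n0_grid: np.ndarray,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[TimeSeries, pd.DataFrame]:
    """Noisy normalized nuclear-volume shock curve plus the clean sweep.

    The "time" axis of the returned series is the relative external
    osmolarity grid (decreasing).
    """
    sweep = osmotic_shock_sweep(params, n0_grid)
    rng = np.random.default_rng(seed)
    nm = noise if noise is not None else NoiseModel(cv=0.03)
    # store against increasing -n0_rel so TimeSeries monotonicity holds
    ts = TimeSeries(
        t=-sweep["n0_rel"].to_numpy(),
        y=nm.apply(sweep["Vn_norm"].to_numpy(), rng),
        label="volume",
    )
    return ts, sweep


def gen_population(
    n_cells: int,
    param_dispersion: float,
    base_params=None,
    t_grid: np.ndarray | None = None,
    seed: int = 0,
    noise: NoiseModel | None = None,
) -> dict:
    """Population of single-cell volume trajectories with lognormally
    dispersed parameters around the base values.

    Returns the per-cell parameter table, the stacked trajectories and the
    population mean trajectory.  With dispersion the mean of exponentials
    grows faster than the exponential of the mean parameters.  If a
    ``noise`` model is given, per-cell measurement noise is applied before
    averaging, emulating a population-mean growth curve: this is the input
    the four-parameter fit is designed for, since averaging M cells leaves
    cv/sqrt(M) scatter on the mean.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if param_dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if base_params is None:
        base_params = default_true_params()
    if t_grid is None:
        t_grid = np.linspace(0.0, 8.0, 60)
    t_grid = np.asarray(t_grid, dtype=float)
    base = (
        base_params.as_tuple() if isinstance(base_params, GrowthFitResult) else tuple(base_params)[:4]
    )
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(param_dispersion**2)) if param_dispersion > 0 else 0.0
    cells = []
    trajs = np.empty((n_cells, len(t_grid)))
    for i in range(n_cells):
        factors = (
            rng.lognormal(-0.5 * sigma**2, sigma, size=4) if sigma > 0 else np.ones(4)
        )
        pars = tuple(b * f for b, f in zip(base, factors))
        cells.append(dict(zip(("tau_p", "t_star2", "kr", "v1"), pars)))
        traj = model_volume(t_grid, (*pars, DEFAULT_POOL_EPS))
        trajs[i] = noise.apply(traj, rng) if noise is not None else traj
    return {
        "t": t_grid,
        "params": pd.DataFrame(cells),
        "trajectories": trajs,
        "mean": trajs.mean(axis=0),
    }
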