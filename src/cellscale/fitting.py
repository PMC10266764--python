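"""Four-parameter piecewise fit of single-cell growth curves.

Non-dividing cells grow exponentially until ribosomes saturate the mRNA
pool at time ``t**``, after which protein numbers relax to a plateau with
the protein lifetime ``tau_p`` while free amino acids keep accumulating,
so the volume crosses over to linear growth.  The observable volume curve
is fully determined by four parameters: the protein lifetime ``tau_p``,
the saturation time ``t**``, the exponential rate ``kr`` and the initial
volume ``v1``.  Once fitted on the volume channel, the total-density and
normalized-protein channels are predicted with no further adjustable
parameters.

The post-saturation branch integrates the amino-acid balance
``dAf/dt = kcat*Pe - lp*dPtot/dt`` with every protein class relaxing as
``exp(-(t-t**)/tau_p)`` to its plateau; continuity of value and slope at
``t**`` fixes the composite constants.  One dimensionless structural
constant remains, ``eps = (lp - vp/beta) * Ptot/ (V/beta)`` evaluated in
the exponential regime, the ratio of the protein-bound residue pool to
the free amino-acid pool; it equals ``1/(lambda - 1)`` for the growth
model with flux ratio ``lambda`` and defaults to 0.4, the value implied
by the default growth parameters.  It is a model constant, not a fitted
parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TimeSeries",
    "GrowthFitResult",
    "DEFAULT_POOL_EPS",
    "model_volume",
    "fit_volume",
    "predict_density",
    "predict_protein_norm",
    "half_life",
]

#: Default residue-pool/amino-acid-pool ratio 1/(lambda-1) at lambda = 3.5.
DEFAULT_POOL_EPS = 0.4


@dataclass(frozen=True)
class TimeSeries:
    """A measured channel: time (h), values, optional 1-sigma errors."""

    t: np.ndarray
    y: np.ndarray
    sigma: np.ndarray | None = None
    label: str = "volume"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if self.sigma is not None:
            object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("measurements must be finite")
        if self.label not in ("volume", "rho_tot", "protein_norm"):
            raise ValueError(f"unknown channel label {self.label!r}")


@dataclass(frozen=True)
class GrowthFitResult:
    """The four fitted growth parameters and goodness-of-fit."""

    tau_p: float
    t_star2: float
    kr: float
    v1: float
    residual_norm: float = math.nan
    covariance: np.ndarray | None = field(default=None, repr=False)
    eps: float = DEFAULT_POOL_EPS
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.tau_p, self.kr, self.v1) <= 0 or self.t_star2 < 0:
            raise ValueError("fitted parameters must be positive")

    @property
    def tau_half(self) -> float:
        """Protein half-life, ``tau_p * ln 2`` (h)."""
        return half_life(self.tau_p)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.tau_p, self.t_star2, self.kr, self.v1)


def half_life(tau_p: float) -> float:
    """Half-life (h) of an exponentially degraded pool with lifetime ``tau_p``."""
    if tau_p <= 0:
        raise ValueError("tau_p must be > 0")
    return tau_p * math.log(2.0)


def _coerce(params) -> tuple[float, float, float, float, float]:
    if isinstance(params, GrowthFitResult):
        return (*params.as_tuple(), params.eps)
    if len(params) == 5:
        return tuple(params)
    tau_p, t_star2, kr, v1 = params
    return tau_p, t_star2, kr, v1, DEFAULT_POOL_EPS


def model_volume(t: np.ndarray, params) -> np.ndarray:
    """Piecewise volume model (fL): exponential, then relaxation to linear.

    ``params`` is a GrowthFitResult or a (tau_p, t**, kr, v1) tuple.  For
    ``t >= t**`` the curve is
    ``V**[1 + (1+eps)kr(1+kr tau_p)u - ((1+eps)(kr tau_p)^2 + eps kr tau_p)(1-e^(-u/tau_p))]``
    with ``u = t - t**``; value and slope are continuous at t** (and the
    curvature too in the eps = 0 limit).
    """
    tau_p, t_star2, kr, v1, eps = _coerce(params)
    t = np.asarray(t, dtype=float)
    v_star = v1 * np.exp(kr * t_star2)
    u = t - t_star2
    relax = 1.0 - np.exp(-np.clip(u, 0, None) / tau_p)
    linear = (
        1.0
        + (1.0 + eps) * kr * (1.0 + kr * tau_p) * u
        - ((1.0 + eps) * (kr * tau_p) ** 2 + eps * kr * tau_p) * relax
    )
    out = np.where(t < t_star2, v1 * np.exp(kr * t), v_star * linear)
    return out if t.ndim else float(out)


def predict_protein_norm(fit, t_grid: np.ndarray) -> TimeSeries:
    """Normalized protein content ``Ptot(t)/Ptot(0)``: exponential, then
    relaxation to the plateau ``e^(kr t**) (1 + kr tau_p)``.  Parameter-free
    once the volume channel is fitted.
    """
    tau_p, t_star2, kr, _, _ = _coerce(fit)
    t = np.asarray(t_grid, dtype=float)
    u = np.clip(t - t_star2, 0, None)
    plateau_branch = math.exp(kr * t_star2) * (1.0 + kr * tau_p * (1.0 - np.exp(-u / tau_p)))
    y = np.where(t < t_star2, np.exp(kr * t), plateau_branch)
    return TimeSeries(t=t, y=y, label="protein_norm")


def predict_density(
    fit, t_grid: np.ndarray, rho_w: float = 1.04, rho_tot0: float = 1.10
) -> TimeSeries:
    """Total mass density (kg/L): water plus protein dry mass.

    ``rho_tot(t) = rho_w + (rho_tot0 - rho_w) * Pnorm(t)/Vnorm(t)``, where
    the normalized protein and volume curves come from the fitted
    parameters alone.  ``rho_w`` is the renormalized water density
    (1.04 kg/L: the model books all dry mass as protein, which is absorbed
    into the water density) and ``rho_tot0`` anchors the initial density.
    Constant before t**, strictly decreasing towards ``rho_w`` afterwards.
    """
    t = np.asarray(t_grid, dtype=float)
    tau_p, t_star2, kr, v1, eps = _coerce(fit)
    vnorm = model_volume(t, (tau_p, t_star2, kr, 1.0, eps))
    pnorm = predict_protein_norm(fit, t).y
    y = rho_w + (rho_tot0 - rho_w) * pnorm / vnorm
    return TimeSeries(t=t, y=y, label="rho_tot")


def fit_volume(
    ts: TimeSeries,
    n_starts: int = 16,
    eps: float = DEFAULT_POOL_EPS,
    rng: np.random.Generator | None = None,
) -> GrowthFitResult:
    """Least-squares fit of (tau_p, t**, kr, v1) to a volume time series.

    Multi-start over log-spaced kr and tau_p and t** spread across the
    observation window, to avoid local minima of the piecewise objective.
    Residuals are unweighted unless per-point sigmas are supplied.  If the
    best t** lands at the end of the window, it is flagged unidentifiable.
    """
    if ts.label != "volume":
        raise ValueError("fit_volume expects the volume channel")
    t, y = ts.t, ts.y
    if len(t) < 8:
        raise ValueError("need at least 8 points spanning both growth regimes")
    # normalize by the data scale so convergence thresholds are unit-free
    scale = np.median(np.abs(y))
    w = scale / ts.sigma if ts.sigma is not None else np.ones_like(y)
    w = w / scale

    def residuals(theta: np.ndarray) -> np.ndarray:
        tau_p, kr, v1 = np.exp(theta[[0, 2, 3]])
        t_star2 = theta[1]
        return w * (model_volume(t, (tau_p, t_star2, kr, v1, eps)) - y)

    # data-driven scales
    span = t[-1] - t[0]
    kr0 = max(np.log(max(y[min(5, len(y) - 1)], 1e-12) / y[0]) / max(t[min(5, len(t) - 1)] - t[0], 1e-9), 0.05)
    kr_grid = np.geomspace(max(kr0 / 4, 0.01), kr0 * 4, 4)
    tau_grid = np.geomspace(0.2, 4.0, 2)
    tss_grid = t[0] + np.array([0.3, 0.7]) * span

    starts = []
    for kr_s in kr_grid:
        for tau_s in tau_grid:
            for tss_s in tss_grid:
                starts.append((tau_s, tss_s, kr_s, max(y[0], 1e-12)))
    if rng is not None:
        jitter = rng.lognormal(0.0, 0.2, size=(len(starts), 4))
    else:
        jitter = np.ones((len(starts), 4))
    starts = starts[:n_starts] if len(starts) > n_starts else starts

    best = None
    for (tau_s, tss_s, kr_s, v1_s), j in zip(starts, jitter):
        theta0 = np.array(
            [np.log(tau_s * j[0]), tss_s, np.log(kr_s * j[2]), np.log(v1_s * j[3])]
        )
        try:
            sol = least_squares(
                residuals,
                theta0,
                bounds=([np.log(1e-3), t[0] - span, np.log(1e-4), -np.inf],
                        [np.log(1e3), t[-1] + span, np.log(1e3), np.inf]),
                method="trf",
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("volume fit failed from every start")

    tau_p, kr, v1 = np.exp(best.x[[0, 2, 3]])
    t_star2 = float(best.x[1])
    warnings: list[str] = []
    if t_star2 >= t[-1] - 0.02 * span:
        warnings.append("t_star2 at or beyond the observation window: unidentifiable")
    if t_star2 <= t[0] + 0.02 * span:
        warnings.append("t_star2 at the start of the window: exponential regime not observed")
    t_star2 = max(t_star2, 0.0)

    # Gauss-Markov covariance estimate in the internal coordinates
    try:
        jtj = best.jac.T @ best.jac
        dof = max(len(t) - 4, 1)
        cov = np.linalg.pinv(jtj) * 2 * best.cost / dof
    except Exception:
        cov = None
    return GrowthFitResult(
        tau_p=float(tau_p),
        t_star2=t_star2,
        kr=float(kr),
        v1=float(v1),
        residual_norm=float(np.sqrt(2 * best.cost)),
        covariance=cov,
        eps=eps,
        warnings=tuple(warnings),
    )
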