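"""Latent-understanding dynamics: a bistable scalar SDE and its bifurcation structure.

The latent state ``U`` (understanding) lives on [0, 1] and evolves under two
opposing pressures: an *innovation* drive that pushes understanding upward and
is strongest far from the solution, and *functional fixedness*, a restoring
pull back toward the initial misconception.  The deterministic drift is

    dU/dt = gamma * (1-U)^2 / (h^2 + (1-U)^2)  -  U * (1-U)

where ``gamma`` is the control parameter weighting innovation and ``h^2`` the
squared half-saturation constant of the innovation term (default 0.01).  For
intermediate gamma the drift is bistable — a low-U "confused" attractor
coexists with a high-U "enlightened" one — and the confused attractor is
destroyed in a saddle-node (fold) bifurcation as gamma grows.  Stochastic
trajectories are integrated with the Euler–Maruyama scheme under a linear
gamma ramp, producing "sessions" in which understanding tips abruptly from
confusion to enlightenment once gamma passes the fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "DriftParams",
    "SimConfig",
    "LatentTrajectory",
    "FixedPoint",
    "FixedPointSet",
    "FoldSearchResult",
    "drift",
    "fixed_points",
    "critical_gamma",
    "simulate_latent",
    "insight_time",
]


@dataclass(frozen=True)
class DriftParams:
    """Parameters of the deterministic drift field.

    Attributes
    ----------
    gamma : float
        Control parameter weighting the innovation term; must be > 0.
    half_sat_sq : float
        Squared half-saturation constant h^2 of the innovation term; must
        be > 0.  Default 0.01 (= 0.1^2).
    """

    gamma: float
    half_sat_sq: float = 0.01

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not self.half_sat_sq > 0:
            raise ValueError(f"half_sat_sq must be > 0, got {self.half_sat_sq}")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one Euler–Maruyama session simulation.

    gamma ramps linearly from ``gamma_start`` to ``gamma_end`` over
    ``n_steps`` steps of size ``dt``.  ``noise_sigma`` is the noise
    amplitude per sqrt(time); increments are ``noise_sigma*sqrt(dt)*z`` with
    ``z`` standard normal.
    """

    gamma_start: float = 0.1
    gamma_end: float = 0.3
    n_steps: int = 2000
    dt: float = 1.0
    noise_sigma: float = 0.02
    u0: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.u0 <= 1.0:
            raise ValueError("u0 must lie in [0, 1]")


@dataclass(frozen=True)
class LatentTrajectory:
    """A simulated latent-understanding trajectory with its gamma ramp."""

    times: np.ndarray
    u: np.ndarray
    gamma: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.u) == len(self.gamma)):
            raise ValueError("times, u and gamma must have equal length")
        if np.any(self.u < 0) or np.any(self.u > 1):
            raise ValueError("u values must lie in [0, 1]")


Stability = Literal["stable", "unstable"]


@dataclass(frozen=True)
class FixedPoint:
    u_star: float
    stability: Stability


@dataclass(frozen=True)
class FixedPointSet:
    """All roots of the drift on [0, 1] at one gamma, sorted by location."""

    gamma: float
    points: tuple[FixedPoint, ...]

    @property
    def interior(self) -> tuple[FixedPoint, ...]:
        """Fixed points strictly inside (0, 1)."""
        return tuple(p for p in self.points if 0.0 < p.u_star < 1.0)

    @property
    def interior_stable(self) -> tuple[FixedPoint, ...]:
        return tuple(p for p in self.interior if p.stability == "stable")


@dataclass(frozen=True)
class FoldSearchResult:
    """Outcome of a fold (saddle-node) search along a gamma sweep.

    ``gamma_star`` is None when no fold was found in the sweep range; this is
    a regular result, not an error (e.g. a monotone drift has no fold).
    """

    branch: str
    gamma_star: Optional[float]
    found: bool


def drift(u: float, params: DriftParams) -> tuple[float, float, float]:
    """Evaluate the drift at ``u``, decomposed into its two pressures.

    Returns ``(total_rate, innovation_term, fixedness_term)`` with
    ``total_rate = innovation_term - fixedness_term``.

    Raises
    ------
    ValueError
        If ``u`` lies outside [0, 1].
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u must lie in [0, 1], got {u}")
    x = 1.0 - u
    innovation = params.gamma * x * x / (params.half_sat_sq + x * x)
    fixedness = u * x
    return innovation - fixedness, innovation, fixedness


def _drift_total(u: np.ndarray | float, gamma: float, h2: float):
    """Vectorised total drift, no domain checks (internal)."""
    x = 1.0 - np.asarray(u, dtype=float)
    return gamma * x * x / (h2 + x * x) - (1.0 - x) * x


_DERIV_STEP = 1e-6
_DERIV_TIE_TOL = 1e-10


def fixed_points(
    params: DriftParams,
    tolerance: float = 1e-9,
    grid_size: int = 4001,
) -> FixedPointSet:
    """Find all roots of the drift on [0, 1] with linear-stability labels.

    Roots are bracketed by sign changes on a uniform grid and refined with
    Brent's method; u = 1 is always a root (both drift terms vanish there).
    Stability is the sign of a central-difference derivative of the drift
    (step 1e-6; derivatives within 1e-10 of zero are labelled unstable).
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0")
    g, h2 = params.gamma, params.half_sat_sq
    grid = np.linspace(0.0, 1.0, grid_size)
    f = _drift_total(grid, g, h2)

    roots: list[float] = []
    for i in range(grid_size - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = f[i], f[i + 1]
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(lambda u: _drift_total(u, g, h2), a, b,
                                      xtol=tolerance)))
    roots.append(1.0)  # always a root; grid sign test misses tangency at 1
    # dedupe near-coincident roots
    roots = sorted(roots)
    deduped: list[float] = []
    for r in roots:
        if not deduped or r - deduped[-1] > 1e-7:
            deduped.append(r)

    points = []
    for r in deduped:
        lo = max(r - _DERIV_STEP, 0.0)
        hi = min(r + _DERIV_STEP, 1.0)
        deriv = (_drift_total(hi, g, h2) - _drift_total(lo, g, h2)) / (hi - lo)
        stability: Stability = "stable" if deriv < -_DERIV_TIE_TOL else "unstable"
        points.append(FixedPoint(u_star=r, stability=stability))
    return FixedPointSet(gamma=g, points=tuple(points))


def critical_gamma(
    params_template: DriftParams,
    branch: Literal["confused", "enlightened"] = "confused",
    grid_resolution: float = 1e-3,
    gamma_range: tuple[float, float] = (0.05, 0.35),
) -> FoldSearchResult:
    """Locate the saddle-node fold where a stable branch is created/destroyed.

    Sweeps gamma over ``gamma_range`` at step ``grid_resolution``, counting
    interior fixed points of the drift.  The *confused* branch (low-u stable
    point) disappears where the interior count drops from 3 to 1 as gamma
    increases; the *enlightened* branch (high-u stable point) appears where
    it rises from 1 to 3.  The transition is refined by bisection to ~1e-6.

    Returns a FoldSearchResult; ``gamma_star`` is None (``found`` False) when
    no fold exists in the range, e.g. when the drift is monotone in gamma.
    """
    if branch not in ("confused", "enlightened"):
        raise ValueError(f"unknown branch {branch!r}")
    if grid_resolution > 1e-3:
        raise ValueError("grid_resolution must be <= 1e-3 to separate the folds")
    h2 = params_template.half_sat_sq

    def n_interior(g: float) -> int:
        return len(fixed_points(DriftParams(gamma=g, half_sat_sq=h2),
                                grid_size=2001).interior)

    lo, hi = gamma_range
    gammas = np.arange(lo, hi + grid_resolution / 2, grid_resolution)
    counts = [n_interior(float(g)) for g in gammas]

    for i in range(len(gammas) - 1):
        c0, c1 = counts[i], counts[i + 1]
        if branch == "confused" and c0 == 3 and c1 < 3:
            pass
        elif branch == "enlightened" and c0 == 1 and c1 > 1:
            pass
        else:
            continue
        # bisect the bracketing interval on the fixed-point count
        a, b = float(gammas[i]), float(gammas[i + 1])
        for _ in range(40):
            mid = 0.5 * (a + b)
            if n_interior(mid) == c0:
                a = mid
            else:
                b = mid
            if b - a < 1e-7:
                break
        return FoldSearchResult(branch=branch, gamma_star=0.5 * (a + b), found=True)

    return FoldSearchResult(branch=branch, gamma_star=None, found=False)


def simulate_latent(config: SimConfig, params_template: DriftParams | None = None) -> LatentTrajectory:
    """Integrate the latent SDE with the Euler–Maruyama scheme.

    u_{t+1} = u_t + f(u_t; gamma_t) dt + noise_sigma sqrt(dt) z_t, with z_t
    i.i.d. standard normal and gamma ramped linearly from ``gamma_start`` to
    ``gamma_end``.  u is clamped to [0, 1] after every step (clamp events are
    logged at DEBUG).  Fully reproducible from ``config.seed``.
    """
    h2 = params_template.half_sat_sq if params_template is not None else 0.01
    n = config.n_steps
    gamma = np.linspace(config.gamma_start, config.gamma_end, n)
    times = np.arange(n, dtype=float) * config.dt
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal(n - 1)
    sqrt_dt = np.sqrt(config.dt)

    u = np.empty(n)
    u[0] = config.u0
    n_clamped = 0
    for t in range(n - 1):
        step = (
            u[t]
            + _drift_total(u[t], gamma[t], h2) * config.dt
            + config.noise_sigma * sqrt_dt * z[t]
        )
        if step < 0.0 or step > 1.0:
            n_clamped += 1
            step = min(max(step, 0.0), 1.0)
        u[t + 1] = step
    if n_clamped:
        logger.debug("simulate_latent: clamped %d/%d steps to [0,1]", n_clamped, n - 1)
    return LatentTrajectory(times=times, u=u, gamma=gamma, seed=config.seed)


def insight_time(traj: LatentTrajectory, threshold: float = 0.5) -> Optional[float]:
    """First time at which u crosses ``threshold`` from below (None if never).

    The confusion/enlightenment boundary defaults to U = 0.5; a trajectory
    starting at or above the threshold is credited at its first time point.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    u = traj.u
    if u[0] >= threshold:
        return float(traj.times[0])
    above = u >= threshold
    idx = np.nonzero(above & ~np.roll(above, 1))[0]
    idx = idx[idx > 0]
    if idx.size == 0:
        return None
    return float(traj.times[idx[0]])
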