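"""Brownian-dynamics simulators for the bundled toy systems.

Overdamped Langevin (Brownian) dynamics in a potential U(x) integrated
with the forward Euler-Maruyama scheme,

    x_{t+dt} = x_t - dt * grad U(x_t) / kT + sqrt(2 dt D) w_t,

with w_t standard normal per dimension.  Dimensionless units with D = 1
and kT = 1 are the default.  Two potentials are registered: a
one-dimensional asymmetric double well U(x) = x^4 - 6x^2 + 2x, and a
five-dimensional "protein-folding" model whose energy depends only on the
radius r = |x| — a deep enthalpic minimum near the origin (folded) and a
shallow entropy-stabilised basin at large r (unfolded), separated by a
barrier at r = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Potential",
    "SimulationConfig",
    "brownian_trajectory",
    "double_well",
    "folding_model",
    "DOUBLE_WELL",
    "FOLDING_5D",
    "get_potential",
]


def double_well(x):
    """Energy and derivative of the asymmetric double well.

    U(x) = x^4 - 6 x^2 + 2 x;  U'(x) = 4 x^3 - 12 x + 2.  Minima near
    x = -1.810 (deep) and x = 1.644 (shallow), saddle near x = 0.168.
    Accepts scalars or arrays elementwise.
    """
    x = np.asarray(x, dtype=np.float64)
    u = x**4 - 6.0 * x**2 + 2.0 * x
    du = 4.0 * x**3 - 12.0 * x + 2.0
    return u, du


def folding_model(x):
    """Energy and gradient of the 5D folding model.

    The energy depends only on r = |x|:

        U(r) = -2.5 (r-3)^2                   for r < 3
        U(r) = 0.5 (r-3)^3 - (r-3)^2          for r >= 3

    Both branches meet with value 0 and slope 0 at r = 3.  The gradient is
    dU/dr * x / r, defined as zero at the origin.
    """
    x = np.asarray(x, dtype=np.float64)
    r = float(np.linalg.norm(x))
    s = r - 3.0
    if r < 3.0:
        u = -2.5 * s * s
        du = -5.0 * s
    else:
        u = 0.5 * s**3 - s * s
        du = 1.5 * s * s - 2.0 * s
    if r < 1e-12:
        grad = np.zeros_like(x)
    else:
        grad = du * x / r
    return u, grad


@dataclass(frozen=True)
class Potential:
    """A named potential with energy and gradient callables.

    ``func`` maps a position of shape (dim,) — or a scalar for dim 1 — to
    ``(energy, gradient)``.  ``x0`` is the conventional starting point.
    """

    name: str
    dim: int
    func: Callable
    x0: np.ndarray

    def energy(self, x) -> float:
        return float(np.squeeze(np.asarray(self.func(x)[0])))

    def gradient(self, x) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.func(x)[1], dtype=np.float64))


#: Shallow-well minimum of the double well; starting there lets a modest
#: trajectory visit both basins.
DOUBLE_WELL = Potential("double-well", 1, double_well, np.array([1.644]))
FOLDING_5D = Potential("folding-5d", 5, folding_model, np.zeros(5))

_REGISTRY = {p.name: p for p in (DOUBLE_WELL, FOLDING_5D)}


def get_potential(name: str) -> Potential:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown potential {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


@dataclass
class SimulationConfig:
    """Parameters of one Brownian-dynamics run.

    ``dt`` defaults to 0.05, which keeps the Euler scheme stable over the
    visited range of both toy potentials while letting trajectories of the
    standard lengths (50k / 100k steps) cross the barrier many times.
    ``x0`` defaults to the potential's conventional start.
    """

    potential: Potential | str
    n_steps: int
    seed: int
    dt: float = 0.05
    D: float = 1.0
    kT: float = 1.0
    x0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if isinstance(self.potential, str):
            self.potential = get_potential(self.potential)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.D <= 0 or self.kT <= 0:
            raise ValueError("D and kT must be > 0")
        if self.x0 is None:
            self.x0 = np.array(self.potential.x0, dtype=np.float64)
        else:
            self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=np.float64))
        if self.x0.shape != (self.potential.dim,):
            raise ValueError("x0 does not match the potential dimension")


def brownian_trajectory(config: SimulationConfig) -> np.ndarray:
    """Integrate the overdamped Langevin equation; returns (n_steps, dim).

    The first frame is ``x0``; each subsequent frame is one Euler-Maruyama
    step.  The run is fully determined by ``config.seed``.  A non-finite
    position aborts with the offending step index (the usual cause is a
    time step too large for the local force).
    """
    pot = config.potential
    dt, kT = config.dt, config.kT
    noise_scale = np.sqrt(2.0 * dt * config.D)
    rng = np.random.default_rng(config.seed)
    noise = rng.standard_normal((config.n_steps - 1, pot.dim)) * noise_scale
    traj = np.empty((config.n_steps, pot.dim))
    x = config.x0.copy()
    traj[0] = x
    for t in range(config.n_steps - 1):
        x = x - dt * pot.gradient(x) / kT + noise[t]
        if not np.all(np.isfinite(x)):
            raise RuntimeError(
                f"trajectory diverged at step {t + 1}: non-finite position "
                "(reduce dt)"
            )
        traj[t + 1] = x
    return traj
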