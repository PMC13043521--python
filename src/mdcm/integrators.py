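"""Fixed-step integrators: forward Euler and Euler-Maruyama.

Both operate on fields ``f(t, x) -> dx`` and support batched states (any
leading axes), which the inversion machinery uses to propagate an
ensemble of perturbed parameter vectors in one pass.  The default step of
1 ms matches the generative simulations throughout the package.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["IntegrationError", "integrate_euler", "integrate_euler_maruyama"]


class IntegrationError(RuntimeError):
    """Raised when a trajectory blows up (non-finite state)."""

    def __init__(self, message: str, step: int | None = None,
                 time: float | None = None):
        super().__init__(message)
        self.step = step
        self.time = time


def _check_finite(x: np.ndarray, step: int, t: float) -> None:
    if not np.all(np.isfinite(x)):
        raise IntegrationError(
            f"numerical blow-up: non-finite state at step {step} (t={t:.4f} s)",
            step=step, time=t)


def integrate_euler(field: Callable, state0, dt: float, n_steps: int,
                    t0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler trajectory.

    Returns ``(times, traj)`` with ``times`` of length ``n_steps + 1`` and
    ``traj[k]`` the state at ``times[k]`` (``traj[0] = state0``).  Aborts
    with :class:`IntegrationError` on numerical blow-up.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.array(state0, dtype=float)
    traj = np.empty((n_steps + 1,) + x.shape)
    traj[0] = x
    t = t0
    try:
        for k in range(n_steps):
            x = x + dt * field(t, x)
            traj[k + 1] = x
            t = t0 + (k + 1) * dt
        _check_finite(x, n_steps, t)
    except FloatingPointError as err:
        raise IntegrationError(
            f"numerical blow-up at step {k} (t={t:.4f} s): {err}",
            step=k, time=t) from err
    times = t0 + dt * np.arange(n_steps + 1)
    return times, traj


def integrate_euler_maruyama(field: Callable, diffusion, state0, dt: float,
                             n_steps: int, seed: int | None = None,
                             rng: np.random.Generator | None = None,
                             t0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama trajectory with additive noise.

    ``diffusion`` is broadcast against the state and multiplies
    independent standard-normal increments scaled by ``sqrt(dt)`` (Ito
    convention).  A zero diffusion reduces *exactly* to
    :func:`integrate_euler`; a fixed ``seed`` makes the path bit-identical
    across runs.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.array(state0, dtype=float)
    diffusion = np.broadcast_to(np.asarray(diffusion, dtype=float), x.shape)
    if not np.any(diffusion):
        return integrate_euler(field, state0, dt, n_steps, t0=t0)
    if rng is None:
        rng = np.random.default_rng(seed)
    sqdt = np.sqrt(dt)
    traj = np.empty((n_steps + 1,) + x.shape)
    traj[0] = x
    t = t0
    try:
        for k in range(n_steps):
            shock = rng.standard_normal(x.shape)
            x = x + dt * field(t, x) + sqdt * diffusion * shock
            traj[k + 1] = x
            t = t0 + (k + 1) * dt
        _check_finite(x, n_steps, t)
    except FloatingPointError as err:
        raise IntegrationError(
            f"numerical blow-up at step {k} (t={t:.4f} s): {err}",
            step=k, time=t) from err
    times = t0 + dt * np.arange(n_steps + 1)
    return times, traj
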