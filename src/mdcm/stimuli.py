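"""Stimuli and input noise for the decision regime.

The stimulus to each column is a brief Gaussian bump of current; the
column-1 bump is larger by a bias ``delta``, and the normalised input
difference defines the *evidence quality* ``epsilon`` (the analogue of
motion coherence in a random-dot task).  Input noise is white Gaussian
noise low-pass filtered by fast AMPA-receptor kinetics, i.e. an
Ornstein-Uhlenbeck (OU) process ``dI = -I/tau dt + (sd/sqrt(tau)) dW``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "StimulusSpec",
    "NoiseProcessSpec",
    "gaussian_bump",
    "evidence_quality",
    "delta_for_epsilon",
    "simulate_ou",
    "total_input",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Gaussian-bump stimulus: amplitude ``a`` (+ bias ``delta`` on column 1).

    ``t0`` is the bump centre/onset (s), ``width`` the Gaussian width
    parameter (s), ``offset`` the stimulus end after which the input is
    identically zero.  ``epsilon`` is derived, not stored.
    """

    a: float = 1.0
    delta: float = 0.0
    t0: float = 0.0
    offset: float = 2.0
    width: float = 0.007

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("base amplitude a must be positive")
        if self.delta < 0:
            raise ValueError("bias delta must be non-negative")
        if self.width <= 0:
            raise ValueError("bump width must be positive")

    @property
    def epsilon(self) -> float:
        """Evidence quality (u1 - u2)/(u1 + u2) at the bump peak."""
        return evidence_quality(self.a + self.delta, self.a)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epsilon"] = self.epsilon
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(**{k: d[k] for k in ("a", "delta", "t0", "offset", "width")})


@dataclass(frozen=True)
class NoiseProcessSpec:
    """AMPA-filtered white-noise input: OU time constant, SD and seed."""

    tau: float = 0.005
    sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def gaussian_bump(t, spec: StimulusSpec, column: int):
    """Stimulus current (nA) at time(s) ``t`` for the given column.

    ``(a + delta) * exp(-(t-t0)^2 / width^2)`` for column 1, amplitude
    ``a`` for column 2; zero once ``t`` passes the stimulus offset.
    """
    amp = spec.a + spec.delta if column == 1 else spec.a
    t = np.asarray(t, dtype=float)
    u = amp * np.exp(-((t - spec.t0) ** 2) / spec.width ** 2)
    u = np.where(t > spec.offset, 0.0, u)
    return u if u.shape else float(u)


def evidence_quality(u1_0: float, u2_0: float) -> float:
    """Normalised input difference ``(u1 - u2)/(u1 + u2)`` at onset."""
    s = u1_0 + u2_0
    if s <= 0:
        raise ValueError("evidence quality undefined for non-positive "
                         "total input")
    return (u1_0 - u2_0) / s


def delta_for_epsilon(a: float, epsilon: float) -> float:
    """Amplitude bias producing a requested evidence quality.

    Inverse of :func:`evidence_quality` for the bump parameterisation:
    ``delta = 2 a epsilon / (1 - epsilon)``; round-trips exactly.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    return 2.0 * a * epsilon / (1.0 - epsilon)


def simulate_ou(spec: NoiseProcessSpec, dt: float, n_steps: int,
                rng: np.random.Generator | None = None,
                i0: float = 0.0) -> np.ndarray:
    """Euler-Maruyama path of the AMPA-filtered noise current.

    Returns ``n_steps + 1`` values starting at ``i0``.  The white-noise
    increment is ``sd * sqrt(dt)`` per step (Ito convention), scaled by
    ``1/sqrt(tau)``; the stationary SD is therefore ``sd / sqrt(2)``.
    Reproducible: a fresh generator is seeded from ``spec.seed`` unless an
    explicit ``rng`` is passed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    out = np.empty(n_steps + 1)
    out[0] = i0
    decay = 1.0 - dt / spec.tau
    amp = spec.sd * np.sqrt(dt) / np.sqrt(spec.tau)
    shocks = rng.standard_normal(n_steps)
    x = i0
    for k in range(n_steps):
        x = x * decay + amp * shocks[k]
        out[k + 1] = x
    return out


def total_input(t, spec: StimulusSpec, noise_value, column: int = 1):
    """Total input current ``u(t) + I_eta(t)`` to one column (nA)."""
    return gaussian_bump(t, spec, column) + noise_value
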