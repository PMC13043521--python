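"""Dynamical-systems diagnostics.

Largest-Lyapunov-exponent estimation (Benettin two-trajectory method),
phase portraits, peak-amplitude periodicity detection and parameter-grid
regime scans.  These serve two roles: calibrating the unprinted knobs of
the generative presets (drive amplitudes, firing threshold, decision
threshold) and scoring how well a reconstructed model reproduces the
ground-truth dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .integrators import integrate_euler
from .models import (DecisionModelParams, ExtrinsicWeights, LATERAL,
                     RateModelParams, apply_architecture, decision_e1_psp,
                     decision_field, decision_state_size, lfp_rate, rate_field)

__all__ = [
    "LyapunovEstimate", "DynamicsSummary",
    "largest_lyapunov", "phase_portrait", "count_period_classes",
    "summarize_rate_dynamics", "regime_scan",
    "decision_equilibria", "decision_threshold",
    "RATE_COORDS", "DECISION_COORDS",
]

RATE_COORDS = {"Ve1_1": 0, "Ve2_1": 1, "Vi_1": 2,
               "Ve1_2": 3, "Ve2_2": 4, "Vi_2": 5}
DECISION_COORDS = {f"{var}{i}_{col}": 14 * (col - 1) + (0 if var == "v" else 7) + i - 1
                   for col in (1, 2) for var in ("v", "y") for i in range(1, 8)}


@dataclass
class LyapunovEstimate:
    """Largest Lyapunov exponent (1/s) with a convergence diagnostic.

    ``se`` is the standard error of per-renormalisation-block expansion
    rates — large values flag a horizon too short for convergence.
    """

    value: float
    se: float
    n_blocks: int
    horizon: float

    def __float__(self) -> float:
        return self.value


def largest_lyapunov(field: Callable, state0, dt: float = 1e-3,
                     horizon: float = 30.0, renorm_interval: float = 1e-3,
                     transient_fraction: float = 0.2,
                     d0: float = 1e-8) -> LyapunovEstimate:
    """Benettin two-trajectory estimate of the largest Lyapunov exponent.

    A reference trajectory and a clone offset by ``d0`` are integrated
    together; every ``renorm_interval`` the log separation growth is
    accumulated and the clone is pulled back to distance ``d0`` along the
    current separation direction.  The first ``transient_fraction`` of the
    horizon is integrated but not scored.  Units: 1/s.
    """
    x = np.array(state0, dtype=float)
    n_total = int(round(horizon / dt))
    n_transient = int(round(transient_fraction * n_total))
    k_renorm = max(1, int(round(renorm_interval / dt)))
    # settle onto the attractor before scoring
    if n_transient:
        _, warm = integrate_euler(field, x, dt, n_transient)
        x = warm[-1]
    pert = np.zeros_like(x)
    pert[0] = d0
    pair = np.stack([x, x + pert])
    logs = []
    t = n_transient * dt
    n_blocks = (n_total - n_transient) // k_renorm
    for _ in range(n_blocks):
        for _ in range(k_renorm):
            pair = pair + dt * field(t, pair)
            t += dt
        delta = pair[1] - pair[0]
        dist = float(np.linalg.norm(delta))
        if dist == 0.0 or not np.isfinite(dist):
            raise RuntimeError("degenerate separation in Benettin iteration")
        logs.append(np.log(dist / d0))
        pair[1] = pair[0] + delta * (d0 / dist)
    logs = np.asarray(logs)
    block_t = k_renorm * dt
    rates = logs / block_t
    value = float(rates.mean())
    se = float(rates.std(ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else np.inf
    return LyapunovEstimate(value=value, se=se, n_blocks=len(rates),
                            horizon=horizon)


def phase_portrait(traj: np.ndarray, coords: Sequence,
                   names: dict[str, int] | None = None,
                   transient_fraction: float = 0.2) -> np.ndarray:
    """Project a trajectory onto a coordinate pair after transient removal.

    ``coords`` may be state indices or coordinate names (resolved through
    ``names``, defaulting to the rate-model or decision-model naming by
    state dimension).  Returns an ordered ``(n, 2)`` point sequence.
    """
    traj = np.asarray(traj, dtype=float)
    if names is None:
        names = RATE_COORDS if traj.shape[-1] == 6 else DECISION_COORDS
    idx = []
    for c in coords:
        if isinstance(c, str):
            if c not in names:
                raise KeyError(f"unknown coordinate name {c!r}")
            idx.append(names[c])
        else:
            idx.append(int(c))
    start = int(transient_fraction * traj.shape[0])
    return traj[start:, idx]


def count_period_classes(series: np.ndarray, transient_fraction: float = 0.2,
                         rel_tol: float = 0.02,
                         max_classes: int = 6) -> int | None:
    """Count distinct oscillation-peak amplitude classes per cycle.

    Local maxima after the transient are clustered by a one-dimensional
    gap rule (amplitude gaps larger than ``rel_tol`` times the peak range
    split clusters).  Returns 1 for a simple limit cycle, 2 for a
    period-doubled cycle, ...; ``None`` flags an aperiodic signal (cluster
    count above ``max_classes`` or unstable between the two halves of the
    window).  Raises ``ValueError`` when no peaks are found.
    """
    series = np.asarray(series, dtype=float)
    start = int(transient_fraction * series.size)
    s = series[start:]
    peaks, _ = find_peaks(s)
    if peaks.size == 0:
        raise ValueError("no oscillation peaks found after transient")
    amps = s[peaks]

    def n_clusters(a: np.ndarray) -> int:
        if a.size == 1:
            return 1
        a = np.sort(a)
        span = max(a[-1] - a[0], 1e-12)
        scale = max(np.ptp(s), 1e-12)
        gaps = np.diff(a)
        return int(np.sum(gaps > rel_tol * scale)) + 1 if span > rel_tol * scale else 1

    total = n_clusters(amps)
    half = amps.size // 2
    stable = (half >= 1 and n_clusters(amps[:half]) == n_clusters(amps[half:])
              == total)
    if total > max_classes or not stable:
        return None
    return total


def dominant_frequency(series: np.ndarray, fs: float,
                       transient_fraction: float = 0.2) -> float:
    """Frequency (Hz) of the largest non-DC spectral peak."""
    series = np.asarray(series, dtype=float)
    s = series[int(transient_fraction * series.size):]
    s = s - s.mean()
    spec = np.abs(np.fft.rfft(s))
    freqs = np.fft.rfftfreq(s.size, d=1.0 / fs)
    if spec.size < 2:
        return 0.0
    return float(freqs[1 + int(np.argmax(spec[1:]))])


@dataclass
class DynamicsSummary:
    """Summary of one deterministic epoch's dynamical character."""

    lyapunov: float
    lyapunov_se: float
    period_classes: int | None         # None = aperiodic
    dominant_freq_hz: float
    portrait: np.ndarray | None = None

    @property
    def aperiodic(self) -> bool:
        return self.period_classes is None

    def to_dict(self) -> dict:
        return {"lyapunov": self.lyapunov, "lyapunov_se": self.lyapunov_se,
                "period_classes": self.period_classes,
                "aperiodic": self.aperiodic,
                "dominant_freq_hz": self.dominant_freq_hz}


def summarize_rate_dynamics(params: RateModelParams, drive: float,
                            weights: ExtrinsicWeights | None = None,
                            dt: float = 1e-3, horizon: float = 30.0,
                            epoch: float = 3.0,
                            keep_portrait: bool = False) -> DynamicsSummary:
    """Lyapunov exponent, periodicity and spectrum of a rate-model regime.

    The exponent uses a long horizon (the short data epochs are too brief
    for a stable estimate); periodicity and spectrum are read from a
    post-transient epoch of the column-1 LFP.
    """
    if weights is None:
        weights = apply_architecture(params, LATERAL)
    f = rate_field(params, weights, lambda t: (drive, drive))
    x0 = np.array([0.0, 1.0, 0.0, 0.0, 1.001, 0.0])
    lyap = largest_lyapunov(f, x0, dt=dt, horizon=horizon)
    n_tr = int(round(5.0 / dt))
    _, warm = integrate_euler(f, x0, dt, n_tr)
    _, traj = integrate_euler(f, warm[-1], dt, int(round(epoch / dt)))
    series = lfp_rate(traj, 1)
    try:
        classes = count_period_classes(series, transient_fraction=0.0)
    except ValueError:
        classes = 1 if np.ptp(series) < 1e-9 else None
    portrait = phase_portrait(traj, ["Ve2_1", "Vi_1"],
                              transient_fraction=0.0) if keep_portrait else None
    return DynamicsSummary(lyapunov=lyap.value, lyapunov_se=lyap.se,
                           period_classes=classes,
                           dominant_freq_hz=dominant_frequency(
                               series, 1.0 / dt, transient_fraction=0.0),
                           portrait=portrait)


def regime_scan(params: RateModelParams, scan_param: str,
                values: Sequence[float], drive: float = 0.0,
                **kwargs) -> list[tuple[float, DynamicsSummary]]:
    """Summarise rate-model dynamics along a parameter grid.

    ``scan_param`` is either ``"drive"`` (the constant input) or the name
    of a :class:`RateModelParams` field; other settings are forwarded to
    :func:`summarize_rate_dynamics`.  Results come back in grid order.
    """
    from dataclasses import replace
    out = []
    for val in values:
        if scan_param == "drive":
            p, d = params, float(val)
        else:
            p, d = replace(params, **{scan_param: float(val)}), drive
        out.append((float(val), summarize_rate_dynamics(p, d, **kwargs)))
    return out


# ---------------------------------------------------------------------------
# decision-model bistability scan
# ---------------------------------------------------------------------------

def decision_equilibria(params: DecisionModelParams,
                        weights: ExtrinsicWeights | None = None,
                        input_current: float = 0.0,
                        settle: float = 20.0, dt: float = 1e-3,
                        kick: float = 2.0, kick_duration: float = 0.3,
                        tol: float = 1e-3) -> list[np.ndarray]:
    """Stable equilibria of the noise-free decision model (multistart).

    Three starts are used: a transient extra current to column 1 only, to
    column 2 only, and no kick, each followed by a long relaxation under
    the baseline ``input_current``.  Final states whose drift is
    negligible are clustered by their (column-1, column-2) e1 PSPs and
    returned one representative per cluster.
    """
    if weights is None:
        weights = apply_architecture(params, LATERAL)
    finals = []
    for bias in ((kick, 0.0), (0.0, kick), (0.0, 0.0)):
        def u(t, b=bias):
            base = np.array([input_current, input_current])
            return base + (np.array(b) if t < kick_duration else 0.0)
        f = decision_field(params, weights, u)
        _, traj = integrate_euler(f, np.zeros(decision_state_size()), dt,
                                  int(round(settle / dt)))
        x = traj[-1]
        drift = np.linalg.norm(decision_field(params, weights,
                                              lambda t: (input_current,
                                                         input_current))(0.0, x))
        if drift < 1.0:          # mV/s scale; transiently oscillating runs excluded
            finals.append(x)
    reps: list[np.ndarray] = []
    for x in finals:
        key = (decision_e1_psp(x, 1), decision_e1_psp(x, 2))
        if not any(abs(key[0] - decision_e1_psp(r, 1)) < tol
                   and abs(key[1] - decision_e1_psp(r, 2)) < tol for r in reps):
            reps.append(x)
    return reps


_THRESHOLD_CACHE: dict = {}


def decision_threshold(params: DecisionModelParams,
                       weights: ExtrinsicWeights | None = None,
                       **kwargs) -> float:
    """Default decision threshold: midpoint of the bistable e1 PSP levels.

    The noise-free balanced model is pushed into each choice attractor in
    turn; the threshold is halfway between the winning (high) and losing
    (low) e1 PSP equilibrium values, making classification regime-relative
    and reproducible.  Results are memoised per parameter set.
    """
    key = (params, None if weights is None
           else (tuple(weights.wee), tuple(weights.wei)),
           tuple(sorted(kwargs.items())))
    if key in _THRESHOLD_CACHE:
        return _THRESHOLD_CACHE[key]
    eq = decision_equilibria(params, weights, **kwargs)
    v1 = sorted({round(decision_e1_psp(x, col), 6)
                 for x in eq for col in (1, 2)})
    if len(v1) < 2:
        raise RuntimeError(
            "decision model is not bistable under these parameters; "
            "cannot derive a threshold")
    out = 0.5 * (v1[0] + v1[-1])
    _THRESHOLD_CACHE[key] = out
    return out
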