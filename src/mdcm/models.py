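"""Two-column cortical neural-mass model families.

Two generative families are defined, both built from a pair of mutually
coupled cortical columns with two excitatory populations (``e1``, ``e2``)
and one inhibitory population (``i``) each:

* a *decision* model — second-order synaptic-kernel dynamics (Jansen-Rit
  style post-synaptic potentials) whose lateral inter-column wiring
  produces two stable choice attractors, driven by brief Gaussian-bump
  stimuli plus Ornstein-Uhlenbeck input noise;
* a *rate* model — first-order membrane-potential equations with sigmoidal
  firing rates whose inter-column coupling produces period-doubled or
  chaotic oscillations depending on the parameter preset.

Both families expose pure vector fields (state in, derivative out), firing
rate nonlinearities, local-field-potential (LFP) observation functions,
and a shared :class:`Architecture` abstraction describing which extrinsic
(between-column) connections exist in a candidate model.  Only extrinsic
connections are ever re-parameterised during inversion; intrinsic
parameters are part of the (known) ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "DecisionModelParams",
    "RateModelParams",
    "Architecture",
    "Connection",
    "ExtrinsicWeights",
    "LATERAL",
    "FORWARD_BACKWARD",
    "FULL",
    "LATERAL_TIED_EI",
    "ARCHITECTURES",
    "sigmoid_decision",
    "rate_sigmoid",
    "decision_vector_field",
    "decision_field",
    "rate_vector_field",
    "rate_field",
    "lfp_decision",
    "lfp_rate",
    "apply_architecture",
    "decision_state_size",
    "DECISION_NOISE_CHANNELS",
]

# state layout for the decision model:
#   x[0:7]    column-1 PSPs        v1..v7   (mV)
#   x[7:14]   column-1 derivatives y1..y7   (mV/s)
#   x[14:21]  column-2 PSPs        v1..v7
#   x[21:28]  column-2 derivatives y1..y7
#   x[28:32]  filtered noise currents I_eta: (e1 col1, i col1, e1 col2, i col2)
DECISION_NOISE_CHANNELS = 4


def decision_state_size() -> int:
    """Length of the decision-model state vector (28 kernel states + noise)."""
    return 28 + DECISION_NOISE_CHANNELS


@dataclass(frozen=True)
class DecisionModelParams:
    """Parameters of the bistable decision (choice-attractor) model.

    Defaults are the ground-truth/prior values of the bistable fixed-point
    regime.  ``He``/``Hi`` are synaptic magnitudes (mV), ``Ke``/``Ki``
    lumped rate constants (1/s), ``C1..C7`` intrinsic couplings, and
    ``Cee_1, Cei_1, Cee_2, Cei_2`` the extrinsic lateral couplings (the
    superscript is the *source* column).  ``r1`` (1/mV) and ``r2`` (mV)
    shape the firing-rate sigmoid; ``tau_ampa`` (s) and ``noise_sd`` (nA)
    define the AMPA-filtered input-noise process.

    The white-noise term of the input-noise equation is interpreted as a
    discrete Gaussian sequence with standard deviation ``noise_sd`` per
    integration step of ``noise_step_ref`` seconds (the generative
    convention of per-step noise draws at the 1-ms simulation step); the
    equivalent Ito diffusion is ``noise_sd / sqrt(noise_step_ref)`` and
    the stationary SD of the filtered current is about
    ``noise_sd * sqrt(tau_ampa / noise_step_ref) / sqrt(2)`` (~0.45 nA at
    the defaults).  docs/methods.md records why the plain Ito reading
    (stationary SD ``noise_sd/sqrt(2)``) is too weak by an order of
    magnitude to ever produce error trials in this regime.
    """

    He: float = 3.25
    Hi: float = 22.0
    Ke: float = 10.0
    Ki: float = 200.0
    C1: float = 0.1
    C2: float = 0.1
    C3: float = 15.0
    C4: float = 3.0
    C5: float = 3.0
    C6: float = 0.1
    C7: float = 30.0
    Cee_1: float = 0.6
    Cei_1: float = 19.0
    Cee_2: float = 0.6
    Cei_2: float = 19.0
    r1: float = 2.0
    r2: float = 1.0
    tau_ampa: float = 0.005
    noise_sd: float = 0.02
    noise_step_ref: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.He > 0 and self.Hi > 0):
            raise ValueError("synaptic magnitudes He, Hi must be positive")
        if not (self.Ke > 0 and self.Ki > 0):
            raise ValueError("rate constants Ke, Ki must be positive")
        if self.tau_ampa <= 0:
            raise ValueError("tau_ampa must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("C1", "C2", "C3", "C4", "C5", "C6", "C7",
                     "Cee_1", "Cei_1", "Cee_2", "Cei_2"):
            if getattr(self, name) < 0:
                raise ValueError(f"coupling {name} must be non-negative")

    @property
    def extrinsic(self) -> dict[str, float]:
        return {"Cee_1": self.Cee_1, "Cei_1": self.Cei_1,
                "Cee_2": self.Cee_2, "Cei_2": self.Cei_2}


@dataclass(frozen=True)
class RateModelParams:
    """Parameters of the first-order rate model (oscillatory regimes).

    Defaults are the period-doubling preset; the chaotic preset differs
    only in the extrinsic coupling ``Cei_2`` (asymmetric inhibitory
    lateral).  ``tau_e``/``tau_i`` are membrane time constants (s),
    ``r1_max`` the maximum firing rate (Hz), ``r0`` a baseline rate (Hz),
    ``V_star`` the firing threshold (mV) and ``ge``/``gi`` the sigmoid
    steepness constants (mV) of the excitatory and inhibitory populations.
    The threshold is not part of the printed parameter set; the default
    here comes from the regime-scan calibration (see docs/methods.md).
    """

    tau_e: float = 0.020
    tau_i: float = 0.010
    C1: float = 14.96
    C2: float = 14.96
    C3: float = 560.0
    C4: float = 760.0
    C5: float = 200.0
    C6: float = 14.96
    C7: float = 561.02
    Cee_1: float = 74.80
    Cei_1: float = 144.0
    Cee_2: float = 74.80
    Cei_2: float = 144.0
    r1_max: float = 70.0
    r0: float = 0.0
    V_star: float = 25.0
    ge: float = 5.0
    gi: float = 2.0

    def __post_init__(self) -> None:
        if not (self.tau_e > 0 and self.tau_i > 0):
            raise ValueError("membrane time constants must be positive")
        if not (self.ge > self.gi > 0):
            raise ValueError("sigmoid steepness must satisfy ge > gi > 0")
        if self.r1_max <= 0:
            raise ValueError("r1_max must be positive")

    @property
    def extrinsic(self) -> dict[str, float]:
        return {"Cee_1": self.Cee_1, "Cei_1": self.Cei_1,
                "Cee_2": self.Cee_2, "Cei_2": self.Cei_2}


# ---------------------------------------------------------------------------
# firing-rate nonlinearities
# ---------------------------------------------------------------------------

def _expit(z):
    # logistic with argument clipping: exact to double precision for
    # |z| < 60 and saturating (no overflow) beyond
    z = np.asarray(z, dtype=float)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def sigmoid_decision(v, r1: float, r2: float):
    """Zero-anchored firing-rate sigmoid of the decision model.

    ``S(v) = 1/(1+exp(-r1 (v - r2))) - 1/(1+exp(r1 r2))``, so that
    ``S(0) = 0`` exactly and the resting state is an equilibrium.
    Strictly increasing in ``v``; saturates without overflow.
    """
    v = np.asarray(v, dtype=float)
    base = 1.0 / (1.0 + np.exp(r1 * r2))
    out = _expit(r1 * (v - r2)) - base
    return out if out.shape else float(out)


def rate_sigmoid(Vm, params: RateModelParams,
                 population: Literal["e", "i"] = "e"):
    """Sigmoidal firing rate of the rate model, bounded in (r0, r0 + r1_max).

    The inhibitory population uses the steeper slope constant ``gi``
    (fast-spiking cells respond more sharply to depolarisation).
    """
    gm = params.ge if population == "e" else params.gi
    Vm = np.asarray(Vm, dtype=float)
    out = params.r1_max * _expit((Vm - params.V_star) / gm) + params.r0
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# architectures (extrinsic wiring of candidate models)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Connection:
    """One extrinsic (between-column) connection of a candidate model.

    ``source``/``target`` are column indices (1 or 2); ``enters`` names the
    target population drive the connection feeds (``"e1"`` for the
    excitatory drive, ``"i"`` for the inhibitory drive); ``prior_key``
    names the parameter-set field supplying the prior-mean strength.
    Connections sharing a ``group`` label are driven by one common
    log-scaling parameter (a ratio-preserving tie: their strength *ratio*
    stays at the prior ratio while the common scale is estimated);
    ``group`` defaults to the connection name, i.e. untied.
    """

    name: str
    source: int
    target: int
    enters: Literal["e1", "i"]
    prior_key: str
    group: str | None = None

    @property
    def group_name(self) -> str:
        return self.group or self.name


_LAT = (
    Connection("lat_ee_1", 1, 2, "e1", "Cee_1"),
    Connection("lat_ei_1", 1, 2, "i", "Cei_1"),
    Connection("lat_ee_2", 2, 1, "e1", "Cee_2"),
    Connection("lat_ei_2", 2, 1, "i", "Cei_2"),
)
# forward connection: into the target column's excitatory drive only;
# backward connection: into both the excitatory and inhibitory drives
# (classic forward/backward laminar convention).
_FB = (
    Connection("fwd_e", 1, 2, "e1", "Cee_1"),
    Connection("bwd_e", 2, 1, "e1", "Cee_2"),
    Connection("bwd_i", 2, 1, "i", "Cei_2"),
)


@dataclass(frozen=True)
class Architecture:
    """A candidate extrinsic wiring: a named set of connections."""

    name: str
    connections: tuple[Connection, ...]

    def __post_init__(self) -> None:
        if not self.connections:
            raise ValueError("an architecture needs at least one "
                             "inter-column connection")
        for c in self.connections:
            if c.source == c.target:
                raise ValueError("extrinsic connections are between columns")

    @property
    def param_names(self) -> tuple[str, ...]:
        """One log-scaling parameter per tie group (first-appearance order)."""
        seen: list[str] = []
        for c in self.connections:
            if c.group_name not in seen:
                seen.append(c.group_name)
        return tuple(seen)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


LATERAL = Architecture("lateral", _LAT)
FORWARD_BACKWARD = Architecture("forward_backward", _FB)
FULL = Architecture("full", _LAT + _FB)
# ratio-preserving variant: both inhibitory laterals share one scale, so
# their asymmetric prior ratio (e.g. 144 vs 32 in the chaotic preset) is
# preserved during estimation — the faithfulness workaround used when a
# toolbox cannot scale the two inhibitory laterals independently
LATERAL_TIED_EI = Architecture("lateral_tied_ei", (
    Connection("lat_ee_1", 1, 2, "e1", "Cee_1"),
    Connection("lat_ei_1", 1, 2, "i", "Cei_1", group="lat_ei"),
    Connection("lat_ee_2", 2, 1, "e1", "Cee_2"),
    Connection("lat_ei_2", 2, 1, "i", "Cei_2", group="lat_ei"),
))
ARCHITECTURES = {a.name: a for a in (LATERAL, FORWARD_BACKWARD, FULL,
                                     LATERAL_TIED_EI)}


@dataclass(frozen=True)
class ExtrinsicWeights:
    """Effective extrinsic drive weights per target column.

    ``wee[j]`` multiplies the source-column firing in the excitatory
    (``e1``) drive of column ``j+1``; ``wei[j]`` the inhibitory drive.
    In a two-column network every extrinsic connection originates in the
    opposite column, so two weights per column fully describe the wiring.
    """

    wee: np.ndarray  # shape (2,)
    wei: np.ndarray  # shape (2,)


def apply_architecture(params, arch: Architecture,
                       theta: Sequence[float] | None = None) -> ExtrinsicWeights:
    """Effective extrinsic weights = prior mean x exp(theta), masked by ``arch``.

    ``theta`` holds one log-scaling per connection present in ``arch``
    (order = ``arch.connections``); ``theta=None`` means all zeros, i.e.
    strengths at their prior means.  Connections absent from ``arch``
    contribute exactly zero; intrinsic parameters are untouched.
    """
    if theta is None:
        theta = np.zeros(arch.n_params)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (arch.n_params,):
        raise ValueError(
            f"theta has length {theta.size}, architecture "
            f"'{arch.name}' has {arch.n_params} parameters")
    names = arch.param_names
    index = {g: i for i, g in enumerate(names)}
    wee = np.zeros(2)
    wei = np.zeros(2)
    for c in arch.connections:
        th = theta[index[c.group_name]]
        w = getattr(params, c.prior_key) * float(np.exp(th))
        j = c.target - 1
        if c.enters == "e1":
            wee[j] += w
        else:
            wei[j] += w
    return ExtrinsicWeights(wee=wee, wei=wei)


# ---------------------------------------------------------------------------
# decision-model vector field and observation
# ---------------------------------------------------------------------------

def decision_vector_field(x: np.ndarray, params: DecisionModelParams,
                          weights: ExtrinsicWeights,
                          inputs) -> np.ndarray:
    """Deterministic part of the decision-model dynamics.

    ``x`` is the 32-dimensional state (see module header for the layout),
    ``inputs`` the per-column stimulus currents (nA), shape ``(2,)``.
    The filtered-noise states decay as ``-I_eta / tau_ampa``; their
    stochastic increments are supplied by the Euler-Maruyama integrator.
    Each synaptic kernel obeys ``ydot = H*K*(drive) - 2*K*y - K^2*v``.

    Vectorised over leading batch axes of ``x`` (and, broadcast-compatibly,
    of ``weights``), so an ensemble of perturbed parameter vectors can be
    integrated in one pass.  Raises ``FloatingPointError`` on a non-finite
    state (numerical blow-up), so integrators can abort with a diagnostic.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite decision-model state")
    p = params
    blocks = x[..., :28].reshape(x.shape[:-1] + (2, 14))   # view, no copy
    V = blocks[..., :7]                                    # (..., 2, 7)
    Y = blocks[..., 7:]
    eta = x[..., 28:32]
    eta_e1 = eta[..., 0::2]                                # (..., 2)
    eta_i = eta[..., 1::2]

    S = lambda u: sigmoid_decision(u, p.r1, p.r2)
    m = V[..., 1] - V[..., 2] + V[..., 6]                  # (..., 2)
    Sm = np.asarray(S(m))
    Smk = Sm[..., ::-1]                                    # opposite column
    I = np.asarray(inputs, dtype=float)

    drive_e1 = p.C1 * Sm + weights.wee * Smk + I + eta_e1
    drive_i = p.C4 * Sm + weights.wei * Smk + I + eta_i
    S_ff = np.asarray(S(V[..., 3] - V[..., 4]))            # i-population drive

    He_Ke, Hi_Ki = p.He * p.Ke, p.Hi * p.Ki
    Ke2, Ki2 = p.Ke ** 2, p.Ki ** 2
    dY = np.empty_like(Y)
    dY[..., 0] = He_Ke * drive_e1 - 2 * p.Ke * Y[..., 0] - Ke2 * V[..., 0]
    dY[..., 1] = (He_Ke * p.C2 * S(V[..., 1] + V[..., 5])
                  - 2 * p.Ke * Y[..., 1] - Ke2 * V[..., 1])
    dY[..., 2] = Hi_Ki * p.C3 * S_ff - 2 * p.Ki * Y[..., 2] - Ki2 * V[..., 2]
    dY[..., 3] = He_Ke * drive_i - 2 * p.Ke * Y[..., 3] - Ke2 * V[..., 3]
    dY[..., 4] = Hi_Ki * p.C5 * S_ff - 2 * p.Ki * Y[..., 4] - Ki2 * V[..., 4]
    dY[..., 5] = (He_Ke * p.C6 * S(V[..., 0] + V[..., 5])
                  - 2 * p.Ke * Y[..., 5] - Ke2 * V[..., 5])
    dY[..., 6] = He_Ke * p.C7 * Sm - 2 * p.Ke * Y[..., 6] - Ke2 * V[..., 6]

    dx = np.empty_like(x)
    dblocks = dx[..., :28].reshape(x.shape[:-1] + (2, 14))
    dblocks[..., :7] = Y
    dblocks[..., 7:] = dY
    dx[..., 28:32] = -eta / p.tau_ampa
    return dx


def decision_field(params: DecisionModelParams, weights: ExtrinsicWeights,
                   input_fn: Callable[[float], Sequence[float]]
                   ) -> Callable[[float, np.ndarray], np.ndarray]:
    """Bind parameters and a time-dependent stimulus into ``f(t, x) -> dx``."""
    def f(t: float, x: np.ndarray) -> np.ndarray:
        return decision_vector_field(x, params, weights, input_fn(t))
    return f


def lfp_decision(x_or_traj: np.ndarray, column: int,
                 form: Literal["y", "v"] = "y") -> np.ndarray | float:
    """LFP observation of the decision model.

    The default ``"y"`` form is the printed definition,
    ``y1+y2-y3+y4-y5+y6+y7`` (signed sum of the kernel derivative
    states); ``"v"`` applies the same sign pattern to the PSPs themselves
    (the components are labelled EPSP/IPSP, so a potential-based sum is a
    plausible intended reading).  Accepts a single state vector or a
    trajectory with states along the last axis.
    """
    signs = np.array([1.0, 1.0, -1.0, 1.0, -1.0, 1.0, 1.0])
    base = 14 * (column - 1) + (7 if form == "y" else 0)
    arr = np.asarray(x_or_traj, dtype=float)
    comp = arr[..., base:base + 7]
    out = comp @ signs
    return out if np.ndim(out) else float(out)


def decision_e1_psp(x_or_traj: np.ndarray, column: int) -> np.ndarray | float:
    """Post-synaptic potential v1 of population e1 — the decision variable."""
    arr = np.asarray(x_or_traj, dtype=float)
    out = arr[..., 14 * (column - 1)]
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# rate-model vector field and observation
# ---------------------------------------------------------------------------

# state layout: [Ve1_1, Ve2_1, Vi_1, Ve1_2, Ve2_2, Vi_2]  (mV)

def rate_vector_field(x: np.ndarray, params: RateModelParams,
                      weights: ExtrinsicWeights,
                      inputs: Sequence[float]) -> np.ndarray:
    """Six coupled membrane-potential equations of the rate model.

    For column j (other column k): Ve1 integrates self-excitation C6 and
    input from e2 (C1) plus drive I_j; Ve2 integrates self-excitation C7,
    the extrinsic excitatory lateral, recurrent C2 from e1 and inhibition
    C3; Vi integrates C4 from e2, the extrinsic inhibitory lateral,
    self-inhibition C5 and the drive I_j.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite rate-model state")
    p = params
    Ve1 = x[..., 0::3]
    Ve2 = x[..., 1::3]
    Vi = x[..., 2::3]
    re1 = np.asarray(rate_sigmoid(Ve1, p, "e"))
    re2 = np.asarray(rate_sigmoid(Ve2, p, "e"))
    ri = np.asarray(rate_sigmoid(Vi, p, "i"))
    re2_k = re2[..., ::-1]          # firing of the opposite column's e2
    I = np.asarray(inputs, dtype=float)

    dVe1 = -Ve1 / p.tau_e + p.C6 * re1 + p.C1 * re2 + I
    dVe2 = (-Ve2 / p.tau_e + p.C7 * re2 + weights.wee * re2_k
            + p.C2 * re1 - p.C3 * ri)
    dVi = (-Vi / p.tau_i + p.C4 * re2 + weights.wei * re2_k
           - p.C5 * ri + I)

    dx = np.empty_like(x)
    dx[..., 0::3] = dVe1
    dx[..., 1::3] = dVe2
    dx[..., 2::3] = dVi
    return dx


def rate_field(params: RateModelParams, weights: ExtrinsicWeights,
               input_fn: Callable[[float], Sequence[float]]
               ) -> Callable[[float, np.ndarray], np.ndarray]:
    """Bind parameters and drive into ``f(t, x) -> dx`` for the rate model."""
    def f(t: float, x: np.ndarray) -> np.ndarray:
        return rate_vector_field(x, params, weights, input_fn(t))
    return f


def lfp_rate(x_or_traj: np.ndarray, column: int) -> np.ndarray | float:
    """Rate-model LFP: minus the e2 membrane potential of the column."""
    arr = np.asarray(x_or_traj, dtype=float)
    out = -arr[..., 3 * (column - 1) + 1]
    return out if np.ndim(out) else float(out)
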