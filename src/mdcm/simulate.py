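"""Trial generation: the synthetic-data side of the evaluation.

A decision *trial* is one 2-s stochastic epoch of the bistable two-column
model: a brief Gaussian-bump stimulus (biased toward column 1 by the
evidence quality epsilon) plus AMPA-filtered input noise, recorded as
per-column LFP and e1 post-synaptic potential series and classified as
``correct`` / ``error`` / ``non_decision`` by a first-threshold-crossing
rule.  Rate-regime (period-doubling, chaos) trials are deterministic
1.5-s epochs recorded after an on-attractor transient.

Trial sets are rejection-sampled to per-label quotas (the full-scale
design is 200 correct + 200 error trials at each of four evidence levels)
and serialised as per-trial CSV plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .integrators import IntegrationError, integrate_euler, integrate_euler_maruyama
from .models import (DECISION_NOISE_CHANNELS, Architecture, DecisionModelParams,
                     ExtrinsicWeights, LATERAL, RateModelParams,
                     apply_architecture, decision_e1_psp, decision_state_size,
                     lfp_decision, lfp_rate, rate_field)
from .stimuli import StimulusSpec, delta_for_epsilon, gaussian_bump

__all__ = [
    "TrialRecord", "TrialSetSpec", "TrialSet", "QuotaError",
    "integrate_euler", "integrate_euler_maruyama",
    "simulate_decision_trial", "simulate_rate_epoch", "generate_rate_trials",
    "classify_trial", "generate_trial_set", "sample_decision_trials",
    "psychophysics",
    "resample_series", "save_trial_set", "load_trial_set",
]

Label = Literal["correct", "error", "non_decision"]

DEFAULT_EPSILONS = (0.032, 0.064, 0.128, 0.256)


@dataclass
class TrialRecord:
    """One simulated epoch with its observation series and classification."""

    regime: str
    t: np.ndarray                      # uniform time base (s)
    lfp: np.ndarray                    # (2, n) per-column LFP
    e1: np.ndarray                     # (2, n) per-column e1 PSP (decision)
    stimulus: StimulusSpec | None
    label: Label | None
    decision_time: float | None
    seed: int | None
    dt: float
    fs: float                          # output sampling rate (Hz)
    drive: float | None = None         # constant drive (rate regimes)
    ic: np.ndarray | None = None       # initial state (rate regimes)

    @property
    def epsilon(self) -> float | None:
        return None if self.stimulus is None else self.stimulus.epsilon


class QuotaError(RuntimeError):
    """A label quota could not be filled within the attempt budget."""

    def __init__(self, message: str, attempts: int, filled: dict):
        super().__init__(message)
        self.attempts = attempts
        self.filled = filled


@dataclass(frozen=True)
class TrialSetSpec:
    """Design of a decision trial set.

    ``epsilons`` are the evidence-quality levels; ``n_correct`` /
    ``n_error`` / ``n_non_decision`` the retained-trial quotas per level.
    ``threshold`` is the decision threshold on the e1 PSP (``None`` =
    derive it from the bistability scan: midpoint of the two stable
    equilibria of the noise-free balanced model).  ``a`` is the
    stimulus base amplitude (nA).
    """

    epsilons: tuple[float, ...] = DEFAULT_EPSILONS
    n_correct: int = 200
    n_error: int = 200
    n_non_decision: int = 0
    epoch: float = 2.0
    threshold: float | None = None
    a: float = 6.0
    stimulus_width: float = 0.007
    stimulus_offset: float = 2.0
    dt: float = 1e-3
    seed: int = 0
    max_attempts_factor: int = 100

    def __post_init__(self) -> None:
        if min(self.n_correct, self.n_error, self.n_non_decision) < 0:
            raise ValueError("quotas must be non-negative")
        if self.epoch < self.stimulus_offset:
            raise ValueError("epoch must cover the stimulus window")


@dataclass
class TrialSet:
    """Retained trials plus the rejection-sampling bookkeeping."""

    spec: TrialSetSpec
    trials: list[TrialRecord]
    attempts: dict[float, int]         # attempts per epsilon level
    threshold: float

    def by_label(self, label: Label) -> list[TrialRecord]:
        return [tr for tr in self.trials if tr.label == label]


# ---------------------------------------------------------------------------
# single-trial simulation and classification
# ---------------------------------------------------------------------------

def _stimulus_fn(stim: StimulusSpec):
    def u(t: float) -> np.ndarray:
        return np.array([gaussian_bump(t, stim, 1), gaussian_bump(t, stim, 2)])
    return u


def _simulate_decision_ensemble(params: DecisionModelParams, stim: StimulusSpec,
                                seeds: Sequence[int | None], dt: float,
                                epoch: float, weights: ExtrinsicWeights
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of a batch of decision epochs.

    All trials share the stimulus; each gets an independent noise path
    generated from its own seed (identical seed => bit-identical trial).
    Returns ``(times, traj)`` with ``traj`` of shape ``(n+1, B, 32)``.
    """
    from ._fast import decision_euler_batch
    n_steps = int(round(epoch / dt))
    B = len(seeds)
    times = dt * np.arange(n_steps + 1)
    u = np.stack([gaussian_bump(times, stim, 1),
                  gaussian_bump(times, stim, 2)], axis=-1)   # (n+1, 2)
    # per-step white-noise convention: Ito diffusion sd/sqrt(tau*step_ref)
    amp = params.noise_sd / np.sqrt(params.tau_ampa * params.noise_step_ref)
    if params.noise_sd > 0:
        if any(s is None for s in seeds):
            raise ValueError("noisy trials need integer seeds")
        shocks = np.stack([np.random.default_rng(int(s)).standard_normal(
            (n_steps, DECISION_NOISE_CHANNELS)) for s in seeds])
    else:
        shocks = np.zeros((B, 0, DECISION_NOISE_CHANNELS))
    p = params
    x0 = np.zeros((B, decision_state_size()))
    wee = np.broadcast_to(weights.wee, (B, 2)).copy()
    wei = np.broadcast_to(weights.wei, (B, 2)).copy()
    traj, ok = decision_euler_batch(
        x0, u, wee, wei, p.He, p.Hi, p.Ke, p.Ki, p.C1, p.C2, p.C3, p.C4,
        p.C5, p.C6, p.C7, p.r1, p.r2, p.tau_ampa, shocks, amp, dt, 1, n_steps)
    if not np.all(ok):
        raise IntegrationError("numerical blow-up in decision ensemble "
                               f"({int((~ok).sum())} of {B} members)")
    return times, traj


def simulate_decision_trial(params: DecisionModelParams, stim: StimulusSpec,
                            seed: int | None, dt: float = 1e-3,
                            epoch: float = 2.0,
                            weights: ExtrinsicWeights | None = None,
                            threshold: float | None = None,
                            window: tuple[float, float] | None = None,
                            ) -> TrialRecord:
    """Integrate one stochastic decision epoch and classify it.

    Noise enters the four filtered-current channels (e1 and i population
    of each column) under the per-step white-noise convention; ``seed=None``
    is allowed only for the noise-free model.
    """
    if weights is None:
        weights = apply_architecture(params, LATERAL)
    t, traj = _simulate_decision_ensemble(params, stim, [seed], dt, epoch,
                                          weights)
    return _record_decision_trial(t, traj[:, 0], stim, seed, dt, threshold,
                                  window)


def _record_decision_trial(t, traj, stim, seed, dt, threshold, window
                           ) -> TrialRecord:
    lfp = np.stack([lfp_decision(traj, 1), lfp_decision(traj, 2)])
    e1 = np.stack([decision_e1_psp(traj, 1), decision_e1_psp(traj, 2)])
    label = decision_time = None
    if threshold is not None:
        if window is None:
            window = (stim.t0, stim.offset)
        label, decision_time = classify_trial(e1[0], e1[1], t, threshold, window)
    return TrialRecord(regime="decision", t=t, lfp=lfp, e1=e1, stimulus=stim,
                       label=label, decision_time=decision_time, seed=seed,
                       dt=dt, fs=1.0 / dt)


def classify_trial(e1_col1: np.ndarray, e1_col2: np.ndarray, t: np.ndarray,
                   threshold: float, window: tuple[float, float]
                   ) -> tuple[Label, float | None]:
    """First-threshold-crossing rule on the two e1 PSP series.

    Column 1 crossing first within the stimulus window makes the trial
    ``correct`` (column 1 receives the stronger input); column 2 first
    makes it an ``error``; neither crossing makes it ``non_decision``.
    Ties (same sample) are broken by the larger excursion at that sample.
    """
    in_win = (t >= window[0]) & (t <= window[1])

    def first_cross(series: np.ndarray) -> int | None:
        hits = np.flatnonzero((series >= threshold) & in_win)
        return int(hits[0]) if hits.size else None

    i1, i2 = first_cross(e1_col1), first_cross(e1_col2)
    if i1 is None and i2 is None:
        return "non_decision", None
    if i2 is None or (i1 is not None and i1 < i2):
        return "correct", float(t[i1])
    if i1 is None or i2 < i1:
        return "error", float(t[i2])
    # same sample: larger excursion wins
    if e1_col1[i1] >= e1_col2[i2]:
        return "correct", float(t[i1])
    return "error", float(t[i2])


def simulate_rate_epoch(params: RateModelParams, drive: float,
                        epoch: float = 1.5, dt: float = 1e-3,
                        weights: ExtrinsicWeights | None = None,
                        transient: float = 5.0,
                        ic: np.ndarray | None = None,
                        regime: str = "rate") -> TrialRecord:
    """One deterministic rate-model epoch, recorded after a transient.

    Both columns receive the same constant ``drive`` (mV/s).  When ``ic``
    is given the transient is skipped and integration starts there (used
    to replay an epoch under candidate connectivity).  The record is
    identical across repeated calls — there is no hidden randomness.
    """
    if weights is None:
        weights = apply_architecture(params, LATERAL)
    f = rate_field(params, weights, lambda t: (drive, drive))
    if ic is None:
        # symmetric ICs never desymmetrise; seed a fixed tiny asymmetry
        x0 = np.array([0.0, 1.0, 0.0, 0.0, 1.001, 0.0])
        n_tr = int(round(transient / dt))
        _, warm = integrate_euler(f, x0, dt, n_tr)
        ic = warm[-1]
    n_steps = int(round(epoch / dt))
    t, traj = integrate_euler(f, ic, dt, n_steps)
    lfp = np.stack([lfp_rate(traj, 1), lfp_rate(traj, 2)])
    e1 = np.stack([traj[:, 0], traj[:, 3]])
    return TrialRecord(regime=regime, t=t, lfp=lfp, e1=e1, stimulus=None,
                       label=None, decision_time=None, seed=None, dt=dt,
                       fs=1.0 / dt, drive=drive, ic=np.array(ic))


def generate_rate_trials(params: RateModelParams, drive: float, n_trials: int,
                         epoch: float = 1.5, dt: float = 1e-3,
                         regime: str = "rate") -> list[TrialRecord]:
    """Replicate one deterministic epoch into an n-trial set."""
    proto = simulate_rate_epoch(params, drive, epoch=epoch, dt=dt, regime=regime)
    return [
        TrialRecord(regime=proto.regime, t=proto.t, lfp=proto.lfp, e1=proto.e1,
                    stimulus=None, label=None, decision_time=None, seed=None,
                    dt=dt, fs=proto.fs, drive=drive, ic=proto.ic)
        for _ in range(n_trials)
    ]


# ---------------------------------------------------------------------------
# trial-set generation with label quotas
# ---------------------------------------------------------------------------

def generate_trial_set(spec: TrialSetSpec, params: DecisionModelParams,
                       arch: Architecture = LATERAL,
                       theta: Sequence[float] | None = None,
                       epsilons: Sequence[float] | None = None) -> TrialSet:
    """Rejection-sample decision trials until each label quota is met.

    Ground truth is the lateral architecture; candidate wirings never
    generate data.  Fresh integer seeds are drawn per attempt from a
    per-level stream derived from ``spec.seed``, so the retained set is a
    pure function of the spec.  Raises :class:`QuotaError` (with attempt
    statistics) if a quota is unreachable within
    ``max_attempts_factor x total quota`` attempts.
    """
    weights = apply_architecture(params, arch, theta)
    threshold = spec.threshold
    if threshold is None:
        from .dynamics import decision_threshold
        threshold = decision_threshold(params, weights)
    levels = tuple(epsilons) if epsilons is not None else spec.epsilons
    quota_total = spec.n_correct + spec.n_error + spec.n_non_decision
    max_attempts = spec.max_attempts_factor * max(quota_total, 1)
    trials: list[TrialRecord] = []
    attempts: dict[float, int] = {}
    for li, eps in enumerate(levels):
        stim = StimulusSpec(a=spec.a, delta=delta_for_epsilon(spec.a, eps),
                            offset=spec.stimulus_offset,
                            width=spec.stimulus_width)
        need = {"correct": spec.n_correct, "error": spec.n_error,
                "non_decision": spec.n_non_decision}
        seed_stream = np.random.default_rng([spec.seed, li])
        n_att = 0
        # trials are integrated in ensembles for speed; attempts are
        # consumed in seed order, so the retained set is independent of
        # the batch size
        while any(v > 0 for v in need.values()):
            if n_att >= max_attempts:
                raise QuotaError(
                    f"quota unreachable at epsilon={eps}: still need {need} "
                    f"after {n_att} attempts", attempts=n_att, filled=need)
            batch = min(max(16, 2 * sum(need.values())), 64,
                        max_attempts - n_att)
            seeds = [int(seed_stream.integers(0, 2 ** 31 - 1))
                     for _ in range(batch)]
            t_arr, traj = _simulate_decision_ensemble(
                params, stim, seeds, spec.dt, spec.epoch, weights)
            for b, s in enumerate(seeds):
                if not any(v > 0 for v in need.values()):
                    break
                tr = _record_decision_trial(t_arr, traj[:, b], stim, s,
                                            spec.dt, threshold, None)
                n_att += 1
                if need.get(tr.label, 0) > 0:
                    need[tr.label] -= 1
                    trials.append(tr)
        attempts[eps] = n_att
    return TrialSet(spec=spec, trials=trials, attempts=attempts,
                    threshold=threshold)


def sample_decision_trials(params: DecisionModelParams,
                           epsilons: Sequence[float], n_per_level: int,
                           seed: int, a: float = 6.0,
                           threshold: float | None = None,
                           arch: Architecture = LATERAL,
                           theta: Sequence[float] | None = None,
                           weights: ExtrinsicWeights | None = None,
                           dt: float = 1e-3, epoch: float = 2.0,
                           stimulus_width: float = 0.007,
                           stimulus_offset: float = 2.0,
                           keep_series: bool = True) -> list[TrialRecord]:
    """A fixed number of *attempts* per evidence level, no rejection.

    This is the sampling scheme behind psychometric/chronometric curves
    (every attempted trial counts, including non-decisions), as opposed to
    the quota-based retained sets of :func:`generate_trial_set`.  With
    ``keep_series=False`` the per-trial series are dropped to save memory.
    """
    if weights is None:
        weights = apply_architecture(params, arch, theta)
    if threshold is None:
        from .dynamics import decision_threshold
        threshold = decision_threshold(params)
    out: list[TrialRecord] = []
    for li, eps in enumerate(epsilons):
        stim = StimulusSpec(a=a, delta=delta_for_epsilon(a, eps),
                            offset=stimulus_offset, width=stimulus_width)
        stream = np.random.default_rng([seed, li])
        done = 0
        while done < n_per_level:
            batch = min(64, n_per_level - done)
            seeds = [int(stream.integers(0, 2 ** 31 - 1)) for _ in range(batch)]
            t_arr, traj = _simulate_decision_ensemble(params, stim, seeds, dt,
                                                      epoch, weights)
            for b, s in enumerate(seeds):
                tr = _record_decision_trial(t_arr, traj[:, b], stim, s, dt,
                                            threshold, None)
                if not keep_series:
                    tr.t = tr.t[:0]
                    tr.lfp = tr.lfp[:, :0]
                    tr.e1 = tr.e1[:, :0]
                out.append(tr)
            done += batch
    return out


# ---------------------------------------------------------------------------
# psychophysics and resampling
# ---------------------------------------------------------------------------

def psychophysics(trials: Sequence[TrialRecord],
                  stimulus_duration: float | None = None) -> pd.DataFrame:
    """Accuracy and normalised decision times per evidence level.

    Accuracy is correct/(correct+error) among decided trials; decision
    times are normalised by the stimulus duration and summarised
    separately for correct and error trials.  Empty cells yield NaN, not
    zero.
    """
    rows = []
    for tr in trials:
        if tr.stimulus is None:
            continue
        dur = (stimulus_duration if stimulus_duration is not None
               else tr.stimulus.offset - tr.stimulus.t0)
        rows.append({"epsilon": tr.epsilon, "label": tr.label,
                     "ndt": (tr.decision_time / dur
                             if tr.decision_time is not None else np.nan)})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["epsilon", "n_correct", "n_error",
                                     "n_non_decision", "accuracy",
                                     "ndt_correct", "ndt_error"])
    out = []
    for eps, grp in df.groupby("epsilon", sort=True):
        n_c = int((grp["label"] == "correct").sum())
        n_e = int((grp["label"] == "error").sum())
        n_nd = int((grp["label"] == "non_decision").sum())
        acc = n_c / (n_c + n_e) if (n_c + n_e) else np.nan
        ndt_c = grp.loc[grp["label"] == "correct", "ndt"].mean()
        ndt_e = grp.loc[grp["label"] == "error", "ndt"].mean()
        out.append({"epsilon": eps, "n_correct": n_c, "n_error": n_e,
                    "n_non_decision": n_nd, "accuracy": acc,
                    "ndt_correct": ndt_c, "ndt_error": ndt_e})
    return pd.DataFrame(out)


def resample_series(series: np.ndarray, source_rate: float,
                    target_rate: float, anti_alias: bool = False) -> np.ndarray:
    """Decimate a uniformly sampled series to a lower rate.

    Plain stride selection by default (mimicking naive downsampling of
    simulated data); with ``anti_alias=True`` an order-8 Chebyshev filter
    is applied first.  The rate ratio must be an integer.
    """
    ratio = source_rate / target_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(f"non-integer decimation factor {ratio:g}")
    if factor == 1:
        return np.asarray(series)
    if anti_alias:
        from scipy.signal import decimate
        return decimate(np.asarray(series, dtype=float), factor, axis=-1)
    return np.asarray(series)[..., ::factor]


# ---------------------------------------------------------------------------
# CSV + JSON persistence
# ---------------------------------------------------------------------------

def save_trial_set(ts: TrialSet, out_dir: str | Path) -> Path:
    """Write one CSV per trial plus a JSON sidecar describing the set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"threshold": ts.threshold,
            "attempts": {str(k): v for k, v in ts.attempts.items()},
            "spec": {**{k: getattr(ts.spec, k) for k in (
                "n_correct", "n_error", "n_non_decision", "epoch",
                "a", "stimulus_width", "stimulus_offset", "dt", "seed",
                "max_attempts_factor")},
                "epsilons": list(ts.spec.epsilons),
                "threshold": ts.spec.threshold},
            "trials": []}
    for i, tr in enumerate(ts.trials):
        name = f"trial_{i:04d}.csv"
        pd.DataFrame({"t": tr.t, "lfp1": tr.lfp[0], "lfp2": tr.lfp[1],
                      "e1_1": tr.e1[0], "e1_2": tr.e1[1]}).to_csv(
            out / name, index=False)
        meta["trials"].append({
            "file": name, "label": tr.label, "decision_time": tr.decision_time,
            "seed": tr.seed, "dt": tr.dt, "fs": tr.fs, "regime": tr.regime,
            "stimulus": tr.stimulus.to_dict() if tr.stimulus else None})
    (out / "trialset.json").write_text(json.dumps(meta, indent=1))
    return out


def load_trial_set(in_dir: str | Path) -> TrialSet:
    """Load a trial set written by :func:`save_trial_set`."""
    src = Path(in_dir)
    meta = json.loads((src / "trialset.json").read_text())
    spec_d = dict(meta["spec"])
    spec = TrialSetSpec(epsilons=tuple(spec_d.pop("epsilons")), **spec_d)
    trials = []
    for td in meta["trials"]:
        df = pd.read_csv(src / td["file"])
        stim = StimulusSpec.from_dict(td["stimulus"]) if td["stimulus"] else None
        trials.append(TrialRecord(
            regime=td["regime"], t=df["t"].to_numpy(),
            lfp=np.stack([df["lfp1"].to_numpy(), df["lfp2"].to_numpy()]),
            e1=np.stack([df["e1_1"].to_numpy(), df["e1_2"].to_numpy()]),
            stimulus=stim, label=td["label"],
            decision_time=td["decision_time"], seed=td["seed"],
            dt=td["dt"], fs=td["fs"]))
    attempts = {float(k): v for k, v in meta["attempts"].items()}
    return TrialSet(spec=spec, trials=trials, attempts=attempts,
                    threshold=meta["threshold"])
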