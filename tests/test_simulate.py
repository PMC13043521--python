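"""Integrators, trial classification, quota sampling and psychophysics."""

import numpy as np
import pytest

from mdcm.integrators import (IntegrationError, integrate_euler,
                              integrate_euler_maruyama)
from mdcm.simulate import (QuotaError, TrialRecord, TrialSetSpec,
                           classify_trial, generate_rate_trials,
                           generate_trial_set, load_trial_set, psychophysics,
                           resample_series, sample_decision_trials,
                           save_trial_set, simulate_decision_trial,
                           simulate_rate_epoch)
from mdcm.stimuli import StimulusSpec


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------

def test_euler_exponential_decay():
    tau = 0.020
    f = lambda t, x: -x / tau
    _, traj = integrate_euler(f, np.array([1.0]), 1e-4, 200)
    assert traj[-1, 0] == pytest.approx(np.exp(-1.0), rel=1e-2)


def test_euler_zero_field_and_blowup_diagnostics():
    _, traj = integrate_euler(lambda t, x: 0.0 * x, np.array([2.0, -1.0]),
                              1e-3, 50)
    np.testing.assert_array_equal(traj[0], traj[-1])
    with np.errstate(over="ignore"), pytest.raises(IntegrationError) as err:
        integrate_euler(lambda t, x: x ** 2, np.array([10.0]), 1.0, 500)
    assert err.value.step is not None


def test_euler_maruyama_zero_noise_reduces_to_euler_exactly():
    f = lambda t, x: -x
    x0 = np.array([1.0, 2.0])
    _, det = integrate_euler(f, x0, 1e-3, 100)
    _, em = integrate_euler_maruyama(f, 0.0, x0, 1e-3, 100, seed=5)
    np.testing.assert_array_equal(det, em)


def test_euler_maruyama_seed_reproducibility():
    f = lambda t, x: -x
    x0 = np.array([0.0])
    _, a = integrate_euler_maruyama(f, 1.0, x0, 1e-3, 200, seed=9)
    _, b = integrate_euler_maruyama(f, 1.0, x0, 1e-3, 200, seed=9)
    _, c = integrate_euler_maruyama(f, 1.0, x0, 1e-3, 200, seed=10)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _ramp(cross_time, t, slope=1.0):
    out = np.zeros_like(t)
    if cross_time is not None:
        out = slope * np.clip(t - cross_time, 0, None) + \
            np.where(t >= cross_time, 1.0, 0.0)
    return out


def test_classify_trial_rules():
    t = np.linspace(0, 2, 201)
    th, win = 0.5, (0.0, 2.0)
    label, dt = classify_trial(_ramp(0.8, t), _ramp(None, t), t, th, win)
    assert (label, dt) == ("correct", pytest.approx(0.8))
    label, dt = classify_trial(_ramp(0.9, t), _ramp(0.6, t), t, th, win)
    assert (label, dt) == ("error", pytest.approx(0.6))
    label, dt = classify_trial(np.zeros_like(t), np.zeros_like(t), t, th, win)
    assert (label, dt) == ("non_decision", None)
    # crossings outside the window do not count
    label, _ = classify_trial(_ramp(1.5, t), _ramp(None, t), t, th, (0.0, 1.0))
    assert label == "non_decision"


def test_classification_invariant_to_lfp_scaling(decision_preset):
    """The label depends only on the e1 traces and threshold, never on the
    LFP amplitude."""
    tr = simulate_decision_trial(decision_preset.params, StimulusSpec(a=6.0),
                                 seed=3, threshold=decision_preset.threshold)
    relabel, rdt = classify_trial(tr.e1[0], tr.e1[1], tr.t,
                                  decision_preset.threshold, (0.0, 2.0))
    tr.lfp = tr.lfp * 1e3      # arbitrary rescaling of the observation
    assert (relabel, rdt) == (tr.label, tr.decision_time)


# ---------------------------------------------------------------------------
# trial sets
# ---------------------------------------------------------------------------

def test_generate_trial_set_quota_and_reproducibility(decision_preset):
    spec = TrialSetSpec(n_correct=1, n_error=1, seed=21,
                        threshold=decision_preset.threshold,
                        epsilons=(0.064,))
    ts1 = generate_trial_set(spec, decision_preset.params)
    ts2 = generate_trial_set(spec, decision_preset.params)
    assert len(ts1.trials) == 2
    assert {tr.label for tr in ts1.trials} == {"correct", "error"}
    assert [tr.seed for tr in ts1.trials] == [tr.seed for tr in ts2.trials]
    for a, b in zip(ts1.trials, ts2.trials):
        np.testing.assert_array_equal(a.e1, b.e1)
    # labels re-derive from the stored series (first-crossing definition)
    for tr in ts1.trials:
        lab, dt = classify_trial(tr.e1[0], tr.e1[1], tr.t, ts1.threshold,
                                 (0.0, 2.0))
        assert (lab, dt) == (tr.label, tr.decision_time)


def test_generate_trial_set_quota_unreachable(decision_preset):
    # at near-certain evidence, error trials are too rare for a 2x budget
    spec = TrialSetSpec(n_correct=0, n_error=3, seed=0,
                        threshold=decision_preset.threshold,
                        epsilons=(0.9,), max_attempts_factor=2)
    with pytest.raises(QuotaError) as err:
        generate_trial_set(spec, decision_preset.params)
    assert err.value.attempts >= 6


def test_balanced_inputs_have_symmetric_outcomes(decision_preset):
    """At epsilon = 0 correct and error are exchangeable labels, so the
    correct fraction over attempts is ~1/2."""
    trials = sample_decision_trials(decision_preset.params, [0.0], 150,
                                    seed=4, a=6.0,
                                    threshold=decision_preset.threshold,
                                    keep_series=False)
    n_c = sum(tr.label == "correct" for tr in trials)
    n_e = sum(tr.label == "error" for tr in trials)
    assert n_c + n_e > 30
    frac = n_c / (n_c + n_e)
    assert 0.35 < frac < 0.65


def test_decision_trial_dt_self_convergence(decision_preset):
    """Halving the integration step leaves the noise-free trajectory
    essentially unchanged (forward-Euler self-convergence).  The 7 ms
    stimulus bump is sampled by only ~7 steps at dt = 1 ms, so a few
    percent of pointwise step error is expected; the classification is
    unaffected."""
    p = decision_preset.params
    from dataclasses import replace
    p0 = replace(p, noise_sd=0.0)
    th = decision_preset.threshold
    tr1 = simulate_decision_trial(p0, StimulusSpec(a=6.0), None, dt=1e-3,
                                  threshold=th)
    tr2 = simulate_decision_trial(p0, StimulusSpec(a=6.0), None, dt=5e-4,
                                  threshold=th)
    scale = np.max(np.abs(tr1.e1))
    diff = np.max(np.abs(tr1.e1 - tr2.e1[:, ::2])) / scale
    assert diff < 0.06
    assert tr1.label == tr2.label


def test_rate_epochs_deterministic(pd_preset):
    a = simulate_rate_epoch(pd_preset.params, pd_preset.drive, epoch=0.5)
    b = simulate_rate_epoch(pd_preset.params, pd_preset.drive, epoch=0.5)
    np.testing.assert_array_equal(a.lfp, b.lfp)
    trials = generate_rate_trials(pd_preset.params, pd_preset.drive, 3,
                                  epoch=0.5, regime="period_doubling")
    assert len(trials) == 3
    np.testing.assert_array_equal(trials[0].lfp, trials[2].lfp)


# ---------------------------------------------------------------------------
# psychophysics and resampling
# ---------------------------------------------------------------------------

def _fake_trial(eps, label, dt):
    stim = StimulusSpec(a=1.0, delta=2 * eps / (1 - eps) if eps else 0.0)
    return TrialRecord(regime="decision", t=np.zeros(1), lfp=np.zeros((2, 1)),
                       e1=np.zeros((2, 1)), stimulus=stim, label=label,
                       decision_time=dt, seed=0, dt=1e-3, fs=1000.0)


def test_psychophysics_accuracy_and_empty_cells():
    trials = [_fake_trial(0.2, "correct", 0.5) for _ in range(4)]
    df = psychophysics(trials)
    assert df.loc[0, "accuracy"] == 1.0
    assert np.isnan(df.loc[0, "ndt_error"])    # empty cell -> NaN, not 0
    trials += [_fake_trial(0.2, "error", 1.0) for _ in range(4)]
    df = psychophysics(trials)
    assert df.loc[0, "accuracy"] == 0.5
    # decision times normalised by the 2 s stimulus duration
    assert df.loc[0, "ndt_correct"] == pytest.approx(0.25)
    assert df.loc[0, "ndt_error"] == pytest.approx(0.5)


def test_resample_series_stride_and_errors():
    x = np.arange(20, dtype=float)
    half = resample_series(x, 1000.0, 500.0)
    np.testing.assert_array_equal(half, x[::2])
    assert half.size == 10
    np.testing.assert_array_equal(resample_series(x, 1000.0, 1000.0), x)
    with pytest.raises(ValueError):
        resample_series(x, 1000.0, 300.0)


def test_trial_set_save_load_roundtrip(tmp_path, decision_preset):
    spec = TrialSetSpec(n_correct=1, n_error=1, seed=21,
                        threshold=decision_preset.threshold,
                        epsilons=(0.064,))
    ts = generate_trial_set(spec, decision_preset.params)
    save_trial_set(ts, tmp_path / "set")
    back = load_trial_set(tmp_path / "set")
    assert len(back.trials) == len(ts.trials)
    assert back.threshold == ts.threshold
    for a, b in zip(ts.trials, back.trials):
        assert a.label == b.label and a.seed == b.seed
        np.testing.assert_allclose(a.lfp, b.lfp, rtol=1e-12)
        assert a.stimulus.epsilon == pytest.approx(b.stimulus.epsilon)
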