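"""Vector fields, observation functions and architecture algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdcm.models import (ARCHITECTURES, Architecture, Connection,
                         DecisionModelParams, FORWARD_BACKWARD, FULL, LATERAL,
                         RateModelParams, apply_architecture,
                         decision_state_size, decision_vector_field,
                         lfp_decision, lfp_rate, rate_sigmoid,
                         rate_vector_field, sigmoid_decision)
from mdcm.integrators import integrate_euler
from mdcm.models import decision_field, rate_field


# ---------------------------------------------------------------------------
# firing-rate nonlinearities
# ---------------------------------------------------------------------------

def test_sigmoid_decision_zero_anchor_and_limit():
    # S(0) = 0 by construction for any shape parameters
    assert sigmoid_decision(0.0, 2.0, 1.0) == pytest.approx(0.0, abs=1e-15)
    assert sigmoid_decision(0.0, 0.7, 3.0) == pytest.approx(0.0, abs=1e-15)
    # saturation: S(v -> inf) = 1 - 1/(1 + e^{r1 r2}); v = 50 is deep enough
    expected = 1.0 - 1.0 / (1.0 + np.exp(2.0 * 1.0))
    assert sigmoid_decision(50.0, 2.0, 1.0) == pytest.approx(expected, rel=1e-12)
    # extreme arguments saturate instead of overflowing
    assert np.isfinite(sigmoid_decision(1e9, 2.0, 1.0))
    assert np.isfinite(sigmoid_decision(-1e9, 2.0, 1.0))


@settings(derandomize=True, max_examples=50)
@given(v1=st.floats(-10, 10), dv=st.floats(1e-3, 5))
def test_sigmoid_decision_strictly_increasing(v1, dv):
    assert sigmoid_decision(v1 + dv, 2.0, 1.0) > sigmoid_decision(v1, 2.0, 1.0)


def test_rate_sigmoid_midpoint_asymptotes_and_quantile():
    p = RateModelParams()
    mid = rate_sigmoid(p.V_star, p, "e")
    assert mid == pytest.approx(p.r0 + p.r1_max / 2)
    assert rate_sigmoid(-1e6, p, "e") == pytest.approx(p.r0, abs=1e-9)
    assert rate_sigmoid(1e6, p, "e") == pytest.approx(p.r0 + p.r1_max)
    # logistic quantile: Vm = V* + g ln 3 sits at 3/4 of the range
    vq = p.V_star + p.ge * np.log(3.0)
    assert rate_sigmoid(vq, p, "e") == pytest.approx(p.r0 + 0.75 * p.r1_max,
                                                     rel=1e-12)
    # the inhibitory curve is steeper at threshold (ge > gi)
    h = 1e-4
    slope_e = (rate_sigmoid(p.V_star + h, p, "e")
               - rate_sigmoid(p.V_star - h, p, "e")) / (2 * h)
    slope_i = (rate_sigmoid(p.V_star + h, p, "i")
               - rate_sigmoid(p.V_star - h, p, "i")) / (2 * h)
    assert slope_i > slope_e


def test_rate_params_validate_steepness_ordering():
    with pytest.raises(ValueError):
        RateModelParams(ge=2.0, gi=5.0)


# ---------------------------------------------------------------------------
# decision vector field
# ---------------------------------------------------------------------------

def test_decision_origin_is_exact_equilibrium():
    p = DecisionModelParams()
    w = apply_architecture(p, LATERAL)
    dx = decision_vector_field(np.zeros(decision_state_size()), p, w, (0.0, 0.0))
    assert np.all(dx == 0.0)


def test_decoupled_kernel_steady_state():
    # all couplings zero: constant drive D into e1 settles at v = He*D/Ke
    p = DecisionModelParams(C1=0, C2=0, C3=0, C4=0, C5=0, C6=0, C7=0,
                            Cee_1=0, Cei_1=0, Cee_2=0, Cei_2=0, noise_sd=0)
    w = apply_architecture(p, LATERAL)
    D = 2.0
    f = decision_field(p, w, lambda t: (D, D))
    _, traj = integrate_euler(f, np.zeros(decision_state_size()), 1e-3, 3000)
    v1, y1 = traj[-1][0], traj[-1][7]
    assert v1 == pytest.approx(p.He * D / p.Ke, rel=1e-3)
    assert abs(y1) < 1e-3


def test_decision_field_batch_matches_single():
    """Central-difference state Jacobians agree between the batched and
    per-sample evaluation paths (the batch axis must be inert)."""
    p = DecisionModelParams()
    w = apply_architecture(p, LATERAL)
    rng = np.random.default_rng(0)
    X = 0.1 * rng.normal(size=(5, decision_state_size()))
    batch = decision_vector_field(X, p, w, (0.3, 0.1))
    single = np.stack([decision_vector_field(x, p, w, (0.3, 0.1)) for x in X])
    np.testing.assert_allclose(batch, single, rtol=1e-12, atol=1e-14)


def test_decision_field_jacobian_matches_fd_oracle():
    """The field linearised by its own batched evaluation agrees with a
    brute-force centred-difference oracle computed element by element."""
    p = DecisionModelParams()
    w = apply_architecture(p, LATERAL)
    rng = np.random.default_rng(3)
    x0 = 0.05 * rng.normal(size=decision_state_size())
    h = 1e-6
    d = x0.size
    pert = np.vstack([x0 + h * np.eye(d), x0 - h * np.eye(d)])
    batch = decision_vector_field(pert, p, w, (0.2, 0.2))
    J_batch = (batch[:d] - batch[d:]).T / (2 * h)
    J_oracle = np.empty((d, d))
    for j in range(d):
        e = np.zeros(d)
        e[j] = h
        J_oracle[:, j] = (decision_vector_field(x0 + e, p, w, (0.2, 0.2))
                          - decision_vector_field(x0 - e, p, w, (0.2, 0.2))
                          ) / (2 * h)
    np.testing.assert_allclose(J_batch, J_oracle, rtol=1e-6, atol=1e-8)


def test_decision_field_raises_on_nonfinite_state():
    p = DecisionModelParams()
    w = apply_architecture(p, LATERAL)
    bad = np.zeros(decision_state_size())
    bad[3] = np.inf
    with pytest.raises(FloatingPointError):
        decision_vector_field(bad, p, w, (0.0, 0.0))


# ---------------------------------------------------------------------------
# rate vector field
# ---------------------------------------------------------------------------

def _uncoupled_rate_params():
    # r0 = 0 and V_star far above any reachable potential makes r(V) ~ 0,
    # so only relaxation and the external drive remain
    return RateModelParams(C1=0, C2=0, C3=0, C4=0, C5=0, C6=0, C7=0,
                           Cee_1=0, Cei_1=0, Cee_2=0, Cei_2=0,
                           V_star=1e4)


def test_rate_field_pure_decay_and_forced_equilibrium():
    p = _uncoupled_rate_params()
    w = apply_architecture(p, LATERAL)
    x0 = np.array([1.0, 2.0, 3.0, -1.0, 0.5, -2.0])
    f = rate_field(p, w, lambda t: (0.0, 0.0))
    dt, T = 2e-5, 0.02
    _, traj = integrate_euler(f, x0, dt, int(T / dt))
    taus = np.array([p.tau_e, p.tau_e, p.tau_i] * 2)
    np.testing.assert_allclose(traj[-1], x0 * np.exp(-T / taus), rtol=1e-2)
    # constant drive I settles excitatory potentials at tau_e*I, Vi at tau_i*I
    I = 100.0
    f2 = rate_field(p, w, lambda t: (I, I))
    _, traj2 = integrate_euler(f2, np.zeros(6), 1e-4, 4000)
    expected = np.array([p.tau_e * I, 0.0, p.tau_i * I] * 2)
    np.testing.assert_allclose(traj2[-1], expected, atol=1e-3)


def test_rate_field_jacobian_matches_fd_oracle():
    p = RateModelParams()
    w = apply_architecture(p, LATERAL)
    x0 = np.array([10.0, 24.0, 18.0, 5.0, 26.0, 30.0])
    h = 1e-6
    pert = np.vstack([x0 + h * np.eye(6), x0 - h * np.eye(6)])
    batch = rate_vector_field(pert, p, w, (10.0, 10.0))
    J_batch = (batch[:6] - batch[6:]).T / (2 * h)
    for j in range(6):
        e = np.zeros(6)
        e[j] = h
        col = (rate_vector_field(x0 + e, p, w, (10.0, 10.0))
               - rate_vector_field(x0 - e, p, w, (10.0, 10.0))) / (2 * h)
        np.testing.assert_allclose(J_batch[:, j], col, rtol=1e-6, atol=1e-8)


# ---------------------------------------------------------------------------
# observation functions
# ---------------------------------------------------------------------------

def test_lfp_decision_sign_pattern_and_v_form():
    x = np.zeros(decision_state_size())
    assert lfp_decision(x, 1) == 0.0
    x[7:14] = 1.0          # column-1 y components
    assert lfp_decision(x, 1) == pytest.approx(3.0)   # + + - + - + +
    assert lfp_decision(x, 2) == 0.0
    x[0:7] = [1, 2, 3, 4, 5, 6, 7]
    assert lfp_decision(x, 1, form="v") == pytest.approx(1 + 2 - 3 + 4 - 5 + 6 + 7)


def test_lfp_rate_sign_flip_involution():
    x = np.zeros(6)
    x[1] = 3.5
    assert lfp_rate(x, 1) == -3.5
    assert lfp_rate(x, 2) == 0.0
    assert lfp_rate(-x, 1) == -lfp_rate(x, 1)       # odd function


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

def test_architecture_catalogue_nesting():
    lat = {(c.source, c.target, c.enters) for c in LATERAL.connections}
    fb = {(c.source, c.target, c.enters) for c in FORWARD_BACKWARD.connections}
    full = {(c.source, c.target, c.enters) for c in FULL.connections}
    assert lat | fb <= full
    assert FULL.n_params == LATERAL.n_params + FORWARD_BACKWARD.n_params
    for arch in ARCHITECTURES.values():
        assert any(c.source != c.target for c in arch.connections)


def test_architecture_rejects_self_connections():
    with pytest.raises(ValueError):
        Architecture("bad", (Connection("x", 1, 1, "e1", "Cee_1"),))


def test_apply_architecture_prior_mask_and_roundtrip():
    p = DecisionModelParams()
    w0 = apply_architecture(p, LATERAL)          # theta = 0 -> prior means
    np.testing.assert_allclose(w0.wee, [p.Cee_2, p.Cee_1])
    np.testing.assert_allclose(w0.wei, [p.Cei_2, p.Cei_1])
    # idempotent for theta = 0
    np.testing.assert_array_equal(w0.wee,
                                  apply_architecture(p, LATERAL, [0] * 4).wee)
    # lateral mask on full params: no forward/backward contribution
    w_lat = apply_architecture(p, LATERAL)
    w_full0 = apply_architecture(p, FULL, [0, 0, 0, 0, -50, -50, -50])
    np.testing.assert_allclose(w_full0.wee, w_lat.wee, atol=1e-18)
    # exp round-trip recovers arbitrary target strengths
    target = {"Cee_1": 1.7, "Cei_1": 5.0, "Cee_2": 0.2, "Cei_2": 40.0}
    theta = [np.log(target[c.prior_key] / getattr(p, c.prior_key))
             for c in LATERAL.connections]
    w = apply_architecture(p, LATERAL, theta)
    np.testing.assert_allclose(w.wee, [target["Cee_2"], target["Cee_1"]],
                               rtol=1e-12)
    with pytest.raises(ValueError):
        apply_architecture(p, LATERAL, [0.0, 0.0])


def test_tied_ei_architecture_preserves_prior_ratio():
    """The ratio-preserving lateral variant estimates one common scale
    for both inhibitory laterals, so an asymmetric prior ratio (144 vs 32
    in the chaotic preset) survives estimation unchanged."""
    from mdcm.models import LATERAL_TIED_EI
    p = RateModelParams(Cei_2=32.0)
    assert LATERAL_TIED_EI.n_params == 3
    w = apply_architecture(p, LATERAL_TIED_EI, [0.0, np.log(2.0), 0.0])
    np.testing.assert_allclose(w.wei, [64.0, 288.0])
    assert w.wei[1] / w.wei[0] == pytest.approx(144.0 / 32.0)
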