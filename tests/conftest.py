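"""Shared fixtures: presets and the (expensive) reduced decision study.

Heavy artefacts — the derived decision threshold, a 20-trial lateral
trial set and its 3-architecture inversion matrix — are session-scoped so
the model-selection, parameter-recovery and diagnostics tests all reuse
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from mdcm import (ARCHITECTURES, InversionOptions, TrialSetSpec,
                  generate_trial_set, invert_trial_set, load_preset)
from mdcm.inversion import DECISION_EXTRA_STARTS

MODEL_NAMES = ("lateral", "forward_backward", "full")


@pytest.fixture(scope="session")
def decision_preset():
    return load_preset("decision")


@pytest.fixture(scope="session")
def pd_preset():
    return load_preset("period_doubling")


@pytest.fixture(scope="session")
def chaos_preset():
    return load_preset("chaos")


@pytest.fixture(scope="session")
def decision_trial_set(decision_preset):
    """20 retained lateral-generated trials: 5 correct + 5 error at two
    evidence levels (the reduced model-identification design)."""
    spec = TrialSetSpec(n_correct=5, n_error=5, seed=0,
                        threshold=decision_preset.threshold,
                        epsilons=(0.064, 0.128))
    return generate_trial_set(spec, decision_preset.params)


@pytest.fixture(scope="session")
def decision_matrix(decision_preset, decision_trial_set):
    """Inversion of the 20-trial set against the three-architecture space."""
    space = [ARCHITECTURES[n] for n in MODEL_NAMES]
    return invert_trial_set(decision_trial_set.trials, space,
                            decision_preset.params,
                            options=InversionOptions(max_iter=24),
                            init_thetas=DECISION_EXTRA_STARTS)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
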