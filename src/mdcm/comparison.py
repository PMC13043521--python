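"""Group-level model comparison and parameter averaging.

Random-effects Bayesian model selection (RFX BMS) treats the generating
model as varying across trials and fits a Dirichlet distribution over
model frequencies by the variational scheme of the classic group-BMS
literature: trial-wise assignment responsibilities are softmax-weighted
by the trial's log evidence plus the current Dirichlet digamma terms, and
the Dirichlet counts are updated until convergence.  Models are
summarised by expected probabilities and *exceedance probabilities* (the
belief that a model is more frequent than every other).  Fixed-effects
(FFX) comparison simply sums free energies.  Bayesian model averaging
(BMA) pools the trial-wise Gaussian posteriors of a chosen model into a
sampled mixture and reports strengths on the positive scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import digamma
from scipy.stats import beta as beta_dist

from .inversion import InversionResult

__all__ = ["BMSResult", "BMAResult", "rfx_bms", "ffx_evidence", "bma",
           "evidence_matrix"]


@dataclass
class BMSResult:
    """Fitted Dirichlet over model frequencies plus derived summaries."""

    model_names: tuple[str, ...]
    alpha: np.ndarray                 # Dirichlet parameters, (K,)
    expected_p: np.ndarray            # E[p_k], sums to 1
    exceedance_p: np.ndarray          # P(p_k > p_j for all j), sums to 1
    summed_F: np.ndarray              # per-model free-energy column sums
    n_trials: int
    n_models: int
    n_iter: int

    @property
    def winner(self) -> str:
        return self.model_names[int(np.argmax(self.exceedance_p))]

    def to_dict(self) -> dict:
        return {"model_names": list(self.model_names),
                "alpha": self.alpha.tolist(),
                "expected_p": self.expected_p.tolist(),
                "exceedance_p": self.exceedance_p.tolist(),
                "summed_F": self.summed_F.tolist(),
                "n_trials": self.n_trials, "n_models": self.n_models,
                "winner": self.winner}


@dataclass
class BMAResult:
    """Model-averaged extrinsic strengths (sampled Gaussian mixture)."""

    param_names: tuple[str, ...]
    strength_mean: np.ndarray         # on the positive strength scale
    strength_sd: np.ndarray
    theta_mean: np.ndarray            # mixture mean in log-scaling space
    weights: np.ndarray               # per-trial mixture weights, sum to 1
    n_samples: int

    @property
    def strengths(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.strength_mean.tolist()))

    def to_dict(self) -> dict:
        return {"param_names": list(self.param_names),
                "strength_mean": self.strength_mean.tolist(),
                "strength_sd": self.strength_sd.tolist(),
                "theta_mean": self.theta_mean.tolist(),
                "weights": self.weights.tolist(),
                "n_samples": self.n_samples}


def evidence_matrix(results: Mapping[tuple[int, str], InversionResult],
                    model_names: Sequence[str]) -> tuple[np.ndarray, list[int]]:
    """Assemble the trials-by-models log-evidence matrix.

    Only trials with a result for *every* model are included (missing
    cells would bias the comparison).  Returns ``(F (N,K), trial_ids)``.
    """
    trial_ids = sorted({i for (i, _) in results})
    keep = [i for i in trial_ids
            if all((i, m) in results for m in model_names)]
    F = np.array([[results[(i, m)].free_energy for m in model_names]
                  for i in keep])
    return F, keep


def rfx_bms(log_evidence: np.ndarray, alpha0: float = 1.0,
            tol: float = 1e-6, max_iter: int = 10_000,
            n_samples: int = 1_000_000, seed: int | None = 0,
            model_names: Sequence[str] | None = None) -> BMSResult:
    """Random-effects BMS over a trials-by-models log-evidence matrix.

    ``alpha0`` is the symmetric Dirichlet prior count per model.  The
    variational update alternates trial responsibilities
    ``u_nk ∝ exp(F_nk + ψ(α_k) − ψ(Σα))`` with Dirichlet count updates
    ``α_k = α0 + Σ_n u_nk`` until the counts move less than ``tol``.
    Exceedance probabilities use the exact Beta tail when K = 2, else
    Dirichlet Monte Carlo with ``n_samples`` draws.
    """
    F = np.asarray(log_evidence, dtype=float)
    if F.ndim != 2 or F.shape[1] < 2:
        raise ValueError("need a (trials x models>=2) evidence matrix")
    if not np.all(np.isfinite(F)):
        raise ValueError("log evidences must be finite")
    N, K = F.shape
    alpha = np.full(K, alpha0, dtype=float)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logu = F + (digamma(alpha) - digamma(alpha.sum()))
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    expected = alpha / alpha.sum()
    if K == 2:
        xp1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        exceed = np.array([xp1, 1.0 - xp1])
    else:
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(alpha, size=int(n_samples))
        exceed = np.bincount(np.argmax(draws, axis=1), minlength=K) \
            / draws.shape[0]
    names = (tuple(model_names) if model_names is not None
             else tuple(f"model_{k}" for k in range(K)))
    if len(names) != K:
        raise ValueError("model_names length mismatch")
    return BMSResult(model_names=names, alpha=alpha, expected_p=expected, exceedance_p=exceed,
                     summed_F=F.sum(axis=0), n_trials=N, n_models=K,
                     n_iter=n_iter)


def ffx_evidence(log_evidence: np.ndarray) -> dict:
    """Fixed-effects comparison: summed free energies and log Bayes factors.

    Adding a per-trial constant to every model leaves the pairwise log
    Bayes factors (differences of column sums) unchanged.
    """
    F = np.asarray(log_evidence, dtype=float)
    total = F.sum(axis=0)
    return {"summed_F": total,
            "log_bayes_factors": total[:, None] - total[None, :]}


def bma(results: Sequence[InversionResult],
        weights: Sequence[float] | None = None,
        n_samples: int = 20_000, seed: int | None = 0) -> BMAResult:
    """Average extrinsic posteriors across trials of one model.

    Draws ``theta`` from each trial's Gaussian posterior (trials chosen
    with the given ``weights``; uniform by default, evidence-proportional
    weights are a caller choice), maps through ``exp`` to the positive
    strength scale and reports the mixture mean and SD per connection.
    """
    if not results:
        raise ValueError("no inversion results to average")
    names = results[0].param_names
    if any(r.param_names != names for r in results):
        raise ValueError("results mix parameterizations")
    prior_means = np.array([results[0].prior_means[n] for n in names])
    if weights is None:
        w = np.full(len(results), 1.0 / len(results))
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(results) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("invalid mixture weights")
        w = w / w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_samples, w)
    thetas = []
    for r, c in zip(results, counts):
        if c == 0:
            continue
        thetas.append(rng.multivariate_normal(r.theta_mean, r.theta_cov,
                                              size=c, method="svd"))
    theta = np.vstack(thetas)
    strength = prior_means * np.exp(theta)
    return BMAResult(param_names=names,
                     strength_mean=strength.mean(axis=0),
                     strength_sd=strength.std(axis=0),
                     theta_mean=theta.mean(axis=0),
                     weights=w, n_samples=int(n_samples))
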