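"""Model comparison and post-fit summaries.

Implements DIC with the non-response trait integrated out by
Gauss-Hermite quadrature, parameter-recovery metrics against known truth
(average absolute bias, variance, MSE with the exact bias-variance
decomposition), posterior non-informativeness summaries, and basic
single-chain convergence diagnostics (split R-hat, effective sample
size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp, ndtr

from .gibbs import PosteriorSamples
from .model import CategorySpace, InvalidParameterError, ResponseMatrix, PROB_FLOOR

__all__ = [
    "RecoveryMetrics",
    "NRSummary",
    "dic",
    "recovery_metrics",
    "nr_summary",
    "split_rhat",
    "effective_sample_size",
    "convergence_table",
]


@dataclass(frozen=True)
class RecoveryMetrics:
    """Average absolute bias, variance and MSE of point estimates.

    Per unit: bias is the across-replication mean estimate minus truth,
    variance the across-replication variance (population form, so that
    ``mse = mean(bias^2) + variance`` holds exactly on average), and MSE
    the across-replication mean squared error; each is then averaged over
    units.
    """

    avg_abs_bias: float
    variance: float
    mse: float

    def as_dict(self) -> dict[str, float]:
        return {
            "avg_abs_bias": self.avg_abs_bias,
            "variance": self.variance,
            "mse": self.mse,
        }


@dataclass(frozen=True)
class NRSummary:
    """Posterior non-informativeness proportions ``P(Z = 0 | X)``.

    ``overall`` averages over every response cell; ``middle_only`` over
    middle-category cells only; ``per_person`` and ``per_item`` average
    over the corresponding margins of the full matrix.
    """

    per_person: np.ndarray
    per_item: np.ndarray
    overall: float
    middle_only: float


# ---------------------------------------------------------------------------
# deviance / DIC


def _deviance_grm(X, alpha2, delta, theta2):
    K = X.shape[1]
    dpad = np.concatenate(
        [np.full((K, 1), -np.inf), delta, np.full((K, 1), np.inf)], axis=1
    )
    item = np.broadcast_to(np.arange(K), X.shape)
    eta = alpha2[None, :] * theta2[:, None]
    g = ndtr(eta - dpad[item, X]) - ndtr(eta - dpad[item, X + 1])
    return -2.0 * float(np.log(np.maximum(g, PROB_FLOOR)).sum())


def _deviance_tree(
    X, space, alpha1, beta, alpha2, delta, theta2, Sigma, model, n_nodes
):
    """-2 log-likelihood with theta1 integrated out against its conditional
    normal given theta2 (standardized scale: mean 0, unit variances)."""
    K = X.shape[1]
    m = space.m
    is_mid = X == m
    if model == "rmm":
        cat = X
    else:
        cat = np.where(X < m, X, X - 1)
        cat = np.where(is_mid, 0, cat)
    dpad = np.concatenate(
        [np.full((K, 1), -np.inf), delta, np.full((K, 1), np.inf)], axis=1
    )
    item = np.broadcast_to(np.arange(K), X.shape)
    eta = alpha2[None, :] * theta2[:, None]
    g = ndtr(eta - dpad[item, cat]) - ndtr(eta - dpad[item, cat + 1])
    rho = Sigma[0, 1] / np.sqrt(Sigma[0, 0] * Sigma[1, 1])
    c = rho * np.sqrt(Sigma[0, 0] / Sigma[1, 1]) * theta2
    s2 = Sigma[0, 0] * (1.0 - rho**2)
    nodes, weights = hermgauss(n_nodes)
    logw = np.log(weights) - 0.5 * np.log(np.pi)
    ll_nodes = np.empty((n_nodes, X.shape[0]))
    for j in range(n_nodes):
        t1 = c + np.sqrt(2.0 * s2) * nodes[j]
        p1 = ndtr(-alpha1 * t1[:, None] - beta[None, :])
        if model == "rmm":
            cell = np.where(is_mid, (1.0 - p1) + p1 * g, p1 * g)
        else:
            cell = np.where(is_mid, 1.0 - p1, p1 * g)
        ll_nodes[j] = np.log(np.maximum(cell, PROB_FLOOR)).sum(axis=1)
    ll = logsumexp(logw[:, None] + ll_nodes, axis=0)
    return -2.0 * float(ll.sum())


def dic(
    samples: PosteriorSamples,
    data: ResponseMatrix,
    n_nodes: int = 10,
    max_draws: int | None = None,
) -> float:
    """Deviance information criterion; lower is better.

    ``DIC = 2 * mean(D(draw)) - D(posterior means)`` (Spiegelhalter pD
    form).  For the tree models the deviance marginalizes theta1 by
    ``n_nodes``-node Gauss-Hermite quadrature against its conditional
    normal given theta2; the GRM deviance is the plain conditional
    likelihood (it has no theta1).  The plug-in point conditions on the
    posterior means of the item parameters, theta2 and the trait
    covariance.  ``max_draws`` evenly subsamples long chains for the
    posterior-mean deviance average.
    """
    if samples.n_draws == 0:
        raise InvalidParameterError("empty chain")
    X = data.scores
    space = data.space
    idx = np.arange(samples.n_draws)
    if max_draws is not None and samples.n_draws > max_draws:
        idx = np.linspace(0, samples.n_draws - 1, max_draws).round().astype(int)
    devs = np.empty(len(idx))
    for out_i, d in enumerate(idx):
        if samples.model == "grm":
            devs[out_i] = _deviance_grm(
                X, samples.alpha2[d], samples.delta[d], samples.theta[d, :, 0]
            )
        else:
            devs[out_i] = _deviance_tree(
                X,
                space,
                samples.alpha1[d],
                samples.beta[d],
                samples.alpha2[d],
                samples.delta[d],
                samples.theta[d, :, 1],
                samples.Sigma[d],
                samples.model,
                n_nodes,
            )
    dbar = float(devs.mean())
    alpha2_m = samples.alpha2.mean(axis=0)
    delta_m = np.maximum.accumulate(samples.delta.mean(axis=0), axis=1)
    if samples.model == "grm":
        dhat = _deviance_grm(X, alpha2_m, delta_m, samples.theta[:, :, 0].mean(axis=0))
    else:
        dhat = _deviance_tree(
            X,
            space,
            float(samples.alpha1.mean()),
            samples.beta.mean(axis=0),
            alpha2_m,
            delta_m,
            samples.theta[:, :, 1].mean(axis=0),
            samples.Sigma.mean(axis=0),
            samples.model,
            n_nodes,
        )
    return 2.0 * dbar - dhat


# ---------------------------------------------------------------------------
# recovery metrics


def recovery_metrics(truth: np.ndarray, estimates: np.ndarray) -> RecoveryMetrics:
    """Recovery of a parameter block across replications.

    Parameters
    ----------
    truth
        Generating values, shape ``(n_units,)``.
    estimates
        Point estimates, shape ``(n_replications, n_units)``.
    """
    truth = np.asarray(truth, float).ravel()
    estimates = np.atleast_2d(np.asarray(estimates, float))
    if estimates.shape[1] != truth.shape[0]:
        raise InvalidParameterError(
            f"estimates have {estimates.shape[1]} units, truth has {truth.shape[0]}"
        )
    bias = estimates.mean(axis=0) - truth
    var = estimates.var(axis=0)  # population form: exact decomposition
    mse = ((estimates - truth[None, :]) ** 2).mean(axis=0)
    return RecoveryMetrics(
        avg_abs_bias=float(np.abs(bias).mean()),
        variance=float(var.mean()),
        mse=float(mse.mean()),
    )


def nr_summary(samples: PosteriorSamples, data: ResponseMatrix) -> NRSummary:
    """Posterior proportions of non-informative responses at every level."""
    if samples.model != "rmm" or samples.z_mean is None:
        raise InvalidParameterError(
            "non-informativeness summaries require a mixture-model fit"
        )
    pnr = 1.0 - samples.z_mean  # exactly 0 for non-middle cells
    mid = data.middle_mask
    middle_only = float(pnr[mid].mean()) if mid.any() else 0.0
    return NRSummary(
        per_person=pnr.mean(axis=1),
        per_item=pnr.mean(axis=0),
        overall=float(pnr.mean()),
        middle_only=middle_only,
    )


# ---------------------------------------------------------------------------
# convergence diagnostics


def split_rhat(draws: np.ndarray) -> float:
    """Potential scale reduction factor from one chain split in half."""
    draws = np.asarray(draws, float).ravel()
    n = len(draws) // 2
    halves = np.stack([draws[:n], draws[n : 2 * n]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (n * w)))


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-based ESS (Geyer initial positive sequence)."""
    draws = np.asarray(draws, float).ravel()
    n = len(draws)
    x = draws - draws.mean()
    if np.allclose(x, 0):
        return float(n)
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for t in range(1, n - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def convergence_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Split R-hat and ESS for every scalar parameter in the draws frame."""
    frame = samples.to_draws_frame()
    return pd.DataFrame(
        {
            "rhat": {c: split_rhat(frame[c].to_numpy()) for c in frame},
            "ess": {c: effective_sample_size(frame[c].to_numpy()) for c in frame},
        }
    )
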