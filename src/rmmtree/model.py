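"""Closed-form probabilities and likelihoods for the response-mixture IRTree.

The model views a Likert response as the outcome of a two-node decision
tree.  At the first node the respondent decides whether to answer
informatively; a non-informative choice (indicator ``Z = 0``) lands in the
middle category and terminates the process.  An informative choice
(``Z = 1``) proceeds to a probit graded response model (GRM) over all
``h + 1`` categories, middle category included.  The middle category is
therefore a *mixture* outcome: it can be reached through either path, and
path membership is latent for every observed middle response.

Two latent traits drive the tree: ``theta1`` is a non-response tendency
(first node) and ``theta2`` the substantive trait the scale targets
(second node).  Both nodes use probit links:

* node 1:  ``P(Z = 1) = Phi(-alpha1 * theta1 - beta_i)``
* node 2:  ``P(X >= k | Z = 1) = Phi(alpha2_i * theta2 - delta_ik)``

with a common first-node slope ``alpha1`` and per-item intercepts
``-beta_i``, and per-item GRM slopes/ordered thresholds at node 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp, ndtr

__all__ = [
    "CategorySpace",
    "ItemParams",
    "PersonParams",
    "ResponseMatrix",
    "InvalidParameterError",
    "grm_cumulative",
    "grm_category_probs",
    "informative_prob",
    "response_prob",
    "posterior_informative_given_middle",
    "log_likelihood",
    "marginal_loglik_theta1",
]

#: floor applied to probabilities before taking logs; probit tails underflow
PROB_FLOOR = 1e-300


class InvalidParameterError(ValueError):
    """Raised when model parameters violate their constraints."""


@dataclass(frozen=True)
class CategorySpace:
    """Category coding of a Likert item: scores ``0..h`` with middle ``m = h/2``.

    ``h`` must be even so that a unique middle category exists (e.g. a
    5-category item has ``h = 4`` and middle category ``m = 2``).
    """

    h: int = 4

    def __post_init__(self) -> None:
        if self.h < 2 or self.h % 2 != 0:
            raise InvalidParameterError(
                f"h must be an even integer >= 2, got {self.h}"
            )

    @property
    def m(self) -> int:
        return self.h // 2

    @property
    def n_categories(self) -> int:
        return self.h + 1


@dataclass
class ItemParams:
    """Item parameters of the two tree nodes.

    Attributes
    ----------
    alpha1
        Common first-node slope (>= 0) relating ``theta1`` to the
        probability of answering informatively.
    beta
        Length-K first-node parameters; ``-beta[i]`` is item *i*'s
        first-node intercept.  More negative values make informative
        responding more likely.
    alpha2
        Per-item second-node (GRM) slopes, >= 0.
    delta
        ``(K, h)`` matrix of ordered GRM thresholds (``h`` thresholds for
        ``h + 1`` second-node categories).
    """

    alpha1: float
    beta: np.ndarray
    alpha2: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.alpha2 = np.atleast_1d(np.asarray(self.alpha2, dtype=float))
        self.delta = np.atleast_2d(np.asarray(self.delta, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.alpha1 < 0:
            raise InvalidParameterError(f"alpha1 must be >= 0, got {self.alpha1}")
        if np.any(self.alpha2 < 0):
            raise InvalidParameterError("all alpha2 must be >= 0")
        k = len(self.beta)
        if len(self.alpha2) != k or self.delta.shape[0] != k:
            raise InvalidParameterError(
                "beta, alpha2 and delta must describe the same number of items"
            )
        if np.any(np.diff(self.delta, axis=1) < 0):
            raise InvalidParameterError("thresholds must be nondecreasing per item")

    @property
    def n_items(self) -> int:
        return len(self.beta)


@dataclass
class PersonParams:
    """Latent traits ``(theta1, theta2)`` with their population distribution.

    ``theta`` is ``(N, 2)``: column 0 holds the non-response tendency,
    column 1 the substantive trait.  After identification rescaling
    ``mu = (0, 0)`` and ``diag(Sigma) = (1, 1)``.
    """

    theta: np.ndarray
    mu: np.ndarray = field(default_factory=lambda: np.zeros(2))
    Sigma: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.mu = np.asarray(self.mu, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.theta.shape[1] != 2:
            raise InvalidParameterError("theta must be N x 2")
        if not np.allclose(self.Sigma, self.Sigma.T) or np.any(
            np.linalg.eigvalsh(self.Sigma) <= 0
        ):
            raise InvalidParameterError("Sigma must be symmetric positive definite")

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]


@dataclass
class ResponseMatrix:
    """An ``N x K`` matrix of integer item scores in ``0..h``."""

    scores: np.ndarray
    space: CategorySpace = field(default_factory=CategorySpace)

    def __post_init__(self) -> None:
        scores = np.atleast_2d(np.asarray(self.scores))
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(scores == np.round(scores)):
                raise InvalidParameterError("scores must be integers")
            scores = scores.astype(np.int64)
        if scores.size and (scores.min() < 0 or scores.max() > self.space.h):
            raise InvalidParameterError(
                f"scores must lie in 0..{self.space.h}; "
                f"found range [{scores.min()}, {scores.max()}]"
            )
        self.scores = scores

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def middle_mask(self) -> np.ndarray:
        return self.scores == self.space.m


def grm_cumulative(theta2, alpha2_i, delta_i) -> np.ndarray:
    """Cumulative probabilities ``P(X >= k | Z = 1)`` for ``k = 1..h``.

    Probit GRM: ``Phi(alpha2_i * theta2 - delta_ik)``, nonincreasing in k.
    """
    delta_i = np.asarray(delta_i, dtype=float)
    if np.any(np.diff(delta_i) < 0):
        raise InvalidParameterError("thresholds must be nondecreasing")
    if np.any(np.asarray(alpha2_i) < 0):
        raise InvalidParameterError("alpha2 must be >= 0")
    eta = np.asarray(np.asarray(alpha2_i) * np.asarray(theta2))
    return ndtr(np.expand_dims(eta, -1) - delta_i)


def grm_category_probs(theta2, alpha2_i, delta_i) -> np.ndarray:
    """Category probabilities ``P(X = k | Z = 1)`` for ``k = 0..h``.

    Adjacent differences of the cumulative curve; entries are nonnegative
    and sum to one.
    """
    cum = grm_cumulative(theta2, alpha2_i, delta_i)
    padded = np.concatenate([np.ones_like(cum[..., :1]), cum, np.zeros_like(cum[..., :1])], axis=-1)
    return -np.diff(padded, axis=-1)


def informative_prob(theta1, alpha1, beta_i) -> np.ndarray:
    """First-node probability ``P(Z = 1) = Phi(-alpha1 * theta1 - beta_i)``.

    Nonincreasing in both ``theta1`` (non-response tendency) and
    ``beta_i`` (item proneness to non-response use of the middle option).
    """
    if np.any(np.asarray(alpha1) < 0):
        raise InvalidParameterError("alpha1 must be >= 0")
    return ndtr(-np.asarray(alpha1) * np.asarray(theta1) - np.asarray(beta_i))


def response_prob(
    score: int,
    theta1: float,
    theta2: float,
    alpha1: float,
    beta_i: float,
    alpha2_i: float,
    delta_i,
    space: CategorySpace,
) -> float:
    """Marginal probability of one observed score under the mixture tree.

    For ``score != m`` the response must have passed the first node, so the
    probability is the product of the informative-path and GRM terms.  For
    ``score == m`` the two paths' probabilities add.
    """
    if not 0 <= score <= space.h:
        raise InvalidParameterError(f"score {score} outside 0..{space.h}")
    p1 = informative_prob(theta1, alpha1, beta_i)
    g = grm_category_probs(theta2, alpha2_i, delta_i)[..., score]
    if score == space.m:
        return (1.0 - p1) + p1 * g
    return p1 * g


def posterior_informative_given_middle(
    theta1: float,
    theta2: float,
    alpha1: float,
    beta_i: float,
    alpha2_i: float,
    delta_i,
    space: CategorySpace,
) -> float:
    """``P(Z = 1 | X = m, theta)``: chance an observed middle response is informative.

    Bayes' rule on the two paths into the middle category.  The
    denominator is strictly positive for finite parameters; a floor guards
    against probit-tail underflow.
    """
    p1 = informative_prob(theta1, alpha1, beta_i)
    g_m = grm_category_probs(theta2, alpha2_i, delta_i)[..., space.m]
    num = p1 * g_m
    den = (1.0 - p1) + num
    den = np.maximum(den, PROB_FLOOR)
    return num / den


def _cell_log_probs(
    scores: np.ndarray,
    theta: np.ndarray,
    items: ItemParams,
    space: CategorySpace,
) -> np.ndarray:
    """Log response probability for every (person, item) cell, vectorized."""
    eta2 = items.alpha2[None, :] * theta[:, 1:2]  # (N, K)
    cum = ndtr(eta2[:, :, None] - items.delta[None, :, :])  # (N, K, h)
    one = np.ones_like(cum[:, :, :1])
    zero = np.zeros_like(one)
    cat = -np.diff(np.concatenate([one, cum, zero], axis=2), axis=2)  # (N, K, h+1)
    g = np.take_along_axis(cat, scores[:, :, None], axis=2)[:, :, 0]
    p1 = ndtr(-items.alpha1 * theta[:, 0:1] - items.beta[None, :])
    prob = np.where(scores == space.m, (1.0 - p1) + p1 * g, p1 * g)
    return np.log(np.maximum(prob, PROB_FLOOR))


def log_likelihood(
    data: ResponseMatrix,
    persons: PersonParams,
    items: ItemParams,
    space: CategorySpace | None = None,
) -> float:
    """Observed-data log-likelihood: sum of log mixture probabilities per cell.

    Middle-category cells use the two-path mixture probability; all other
    cells use the informative-path product.
    """
    space = space or data.space
    if data.n_persons != persons.n_persons or data.n_items != items.n_items:
        raise InvalidParameterError("data, persons and items have inconsistent shapes")
    return float(_cell_log_probs(data.scores, persons.theta, items, space).sum())


def marginal_loglik_theta1(
    x_row: np.ndarray,
    theta2_p: float,
    items: ItemParams,
    mu: np.ndarray,
    Sigma: np.ndarray,
    space: CategorySpace,
    n_nodes: int = 10,
    model: str = "rmm",
) -> float:
    """Per-person log-likelihood with ``theta1`` integrated out numerically.

    Integrates ``P(x_p | theta1, theta2_p)`` against the conditional normal
    ``theta1 | theta2_p`` implied by ``(mu, Sigma)`` using Gauss-Hermite
    quadrature.  Used by the deviance computation for models that carry a
    first node (``model`` in {"rmm", "irtree"}).
    """
    if n_nodes < 2:
        raise InvalidParameterError("n_nodes must be >= 2")
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if np.any(np.linalg.eigvalsh(Sigma) <= 0):
        raise InvalidParameterError("Sigma must be positive definite")
    x_row = np.asarray(x_row)
    # conditional N(c, s^2) of theta1 given theta2
    c = mu[0] + Sigma[0, 1] / Sigma[1, 1] * (theta2_p - mu[1])
    s2 = Sigma[0, 0] - Sigma[0, 1] ** 2 / Sigma[1, 1]
    nodes, weights = hermgauss(n_nodes)
    t1 = c + np.sqrt(2.0 * s2) * nodes  # (J,)
    logw = np.log(weights) - 0.5 * np.log(np.pi)
    if model == "rmm":
        g = np.array(
            [
                grm_category_probs(theta2_p, items.alpha2[i], items.delta[i])[x]
                for i, x in enumerate(x_row)
            ]
        )  # (K,)
    elif model == "irtree":
        g = _irtree_node2_probs(x_row, theta2_p, items, space)
    else:
        raise InvalidParameterError(f"model {model!r} has no theta1 to integrate")
    p1 = ndtr(-items.alpha1 * t1[:, None] - items.beta[None, :])  # (J, K)
    is_m = x_row[None, :] == space.m
    if model == "rmm":
        cell = np.where(is_m, (1.0 - p1) + p1 * g[None, :], p1 * g[None, :])
    else:  # irtree: middle <=> first-node stop
        cell = np.where(is_m, 1.0 - p1, p1 * g[None, :])
    ll_nodes = np.log(np.maximum(cell, PROB_FLOOR)).sum(axis=1)
    return float(logsumexp(logw + ll_nodes))


def _irtree_node2_probs(
    x_row: np.ndarray, theta2_p: float, items: ItemParams, space: CategorySpace
) -> np.ndarray:
    """Second-node category probabilities for the IRTree baseline.

    The baseline's second node is a GRM over the ``h`` non-middle
    categories (scores remapped monotonically, ``h - 1`` thresholds);
    middle responses never reach it, so their entry is set to 0 here.
    """
    out = np.zeros(len(x_row))
    for i, x in enumerate(x_row):
        if x == space.m:
            continue
        x2 = x if x < space.m else x - 1
        out[i] = grm_category_probs(theta2_p, items.alpha2[i], items.delta[i])[x2]
    return out
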