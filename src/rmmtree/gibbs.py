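"""Gibbs samplers with probit data augmentation for the mixture tree and baselines.

Three models share one augmentation scheme (Albert-Chib style):

``rmm``
    The response-mixture tree.  Middle responses carry a latent path
    indicator ``Z`` that is imputed each sweep; the second node is a
    probit GRM over all ``h + 1`` categories.
``grm``
    Ordinary probit graded response model (no first node); every response
    is treated as informative.
``irtree``
    The hard-assignment tree baseline: every middle response is a
    non-response (``Z = 0`` deterministically) and the second node is a
    GRM over the ``h`` remaining categories with ``h - 1`` thresholds.

Each sweep samples, in order: path indicators (rmm only), first-node
propensities ``Y1 ~ N(-alpha1*theta1 - beta_i, 1)`` sign-constrained by
``Z``, second-node propensities ``Y2 ~ N(alpha2_i*theta2, 1)`` constrained
to the observed category's threshold interval, item parameters by
conjugate (truncated-)normal regressions, thresholds uniformly between the
flanking propensities, persons from their joint bivariate-normal
conditional, and the population mean/covariance (flat / inverse-Wishart).
After every sweep the draw is rescaled so latent traits have mean 0 and
variance 1 exactly, with compensating item-parameter transforms that leave
the likelihood unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .model import (
    CategorySpace,
    InvalidParameterError,
    ItemParams,
    PersonParams,
    ResponseMatrix,
    PROB_FLOOR,
)

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "PosteriorSamples",
    "fit",
    "sample_latent_indicators",
    "rescale_identification",
    "truncated_normal",
]


@dataclass(frozen=True)
class PriorSpec:
    """Low-informative semi-conjugate priors.

    Slopes get normal priors truncated to the positive half-line;
    first-node intercept parameters ``beta_i`` get a plain normal;
    thresholds are flat on the ordered region within ``[-bound, bound]``;
    the trait mean is improper flat and the trait covariance
    inverse-Wishart.  Normal spreads are variances.
    """

    alpha1_mean: float = 0.5
    alpha1_var: float = 4.0
    beta_mean: float = -2.0
    beta_var: float = 4.0
    alpha2_mean: float = 0.5
    alpha2_var: float = 4.0
    threshold_bound: float = 5.0
    sigma_df: float = 4.0
    sigma_scale: float = 1.0  # multiplies the identity


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings; ``thin=2`` retains every second post-burnin draw."""

    n_iterations: int = 2500
    burnin: int = 500
    thin: int = 2
    seed: int = 0
    model: str = "rmm"

    def __post_init__(self) -> None:
        if self.burnin >= self.n_iterations:
            raise InvalidParameterError("burnin must be < n_iterations")
        if self.thin < 1:
            raise InvalidParameterError("thin must be >= 1")
        if self.model not in ("rmm", "grm", "irtree"):
            raise InvalidParameterError(f"unknown model {self.model!r}")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws.

    ``theta`` has trailing dimension 2 for tree models (columns
    theta1, theta2) and 1 for the GRM.  For the RMM, ``z_draws`` stores
    the imputed path indicator of every middle-category cell (columns
    indexed by ``middle_rows``/``middle_cols``) and ``z_mean`` its
    posterior mean embedded in the full matrix (1 for non-middle cells).
    """

    model: str
    space: CategorySpace
    alpha2: np.ndarray  # (d, K)
    delta: np.ndarray  # (d, K, n_thresh)
    theta: np.ndarray  # (d, N, T)
    mu: np.ndarray  # (d, T)
    Sigma: np.ndarray  # (d, T, T)
    alpha1: np.ndarray | None = None  # (d,)
    beta: np.ndarray | None = None  # (d, K)
    z_draws: np.ndarray | None = None  # (d, n_middle) uint8
    middle_rows: np.ndarray | None = None
    middle_cols: np.ndarray | None = None
    z_mean: np.ndarray | None = None  # (N, K)

    @property
    def n_draws(self) -> int:
        return self.alpha2.shape[0]

    @property
    def n_items(self) -> int:
        return self.alpha2.shape[1]

    @property
    def n_persons(self) -> int:
        return self.theta.shape[1]

    def theta2_mean(self) -> np.ndarray:
        """Posterior mean of the substantive trait per person."""
        return self.theta[:, :, -1].mean(axis=0)

    def theta_mean(self) -> np.ndarray:
        return self.theta.mean(axis=0)

    def item_params_mean(self) -> ItemParams:
        """Posterior-mean item parameters (tree models keep their first node)."""
        alpha1 = float(self.alpha1.mean()) if self.alpha1 is not None else 0.0
        beta = (
            self.beta.mean(axis=0)
            if self.beta is not None
            else np.full(self.n_items, -np.inf)
        )
        delta_mean = self.delta.mean(axis=0)
        # draw-wise ordered thresholds can violate ordering only by fp noise
        delta_mean = np.maximum.accumulate(delta_mean, axis=1)
        return ItemParams(alpha1, beta, self.alpha2.mean(axis=0), delta_mean)

    def to_draws_frame(self, include_theta: bool = False) -> pd.DataFrame:
        """Retained draws as a tidy wide table, one row per draw."""
        cols: dict[str, np.ndarray] = {}
        if self.alpha1 is not None:
            cols["alpha1"] = self.alpha1
        for i in range(self.n_items):
            if self.beta is not None:
                cols[f"beta[{i}]"] = self.beta[:, i]
            cols[f"alpha2[{i}]"] = self.alpha2[:, i]
            for k in range(self.delta.shape[2]):
                cols[f"delta[{i},{k}]"] = self.delta[:, i, k]
        t = self.mu.shape[1]
        for a in range(t):
            for b in range(a + 1, t):
                cols[f"Sigma[{a},{b}]"] = self.Sigma[:, a, b]
        if include_theta:
            for p in range(self.n_persons):
                for a in range(t):
                    cols[f"theta[{p},{a}]"] = self.theta[:, p, a]
        return pd.DataFrame(cols)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD and central 95% interval per parameter."""
        frame = self.to_draws_frame()
        return pd.DataFrame(
            {
                "mean": frame.mean(),
                "sd": frame.std(ddof=1),
                "q2.5": frame.quantile(0.025),
                "q97.5": frame.quantile(0.975),
            }
        )


# ---------------------------------------------------------------------------
# sampling utilities


def truncated_normal(rng, mean, lo, hi, sd=1.0):
    """Draw ``N(mean, sd^2)`` truncated to ``(lo, hi)``, elementwise.

    Inverse-CDF sampling for reproducibility under one seeded generator;
    entries whose truncation interval has negligible normal mass (deep
    tails, where the inverse CDF loses accuracy) fall back to
    ``scipy.stats.truncnorm``.
    """
    mean, lo, hi = np.broadcast_arrays(np.asarray(mean, float), lo, hi)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    pa = ndtr(a)
    pb = ndtr(b)
    u = pa + (pb - pa) * rng.random(mean.shape)
    x = mean + sd * ndtri(np.clip(u, 1e-300, 1 - 1e-16))
    bad = ~np.isfinite(x) | (x < lo) | (x > hi) | (pb - pa < 1e-12)
    if np.any(bad):
        x = np.array(x)
        degenerate = bad & ~(b > a)  # threshold ties give zero-width intervals
        x[degenerate] = lo[degenerate] if np.ndim(lo) else lo
        bad &= b > a
        if np.any(bad):
            x[bad] = mean[bad] + sd * stats.truncnorm.rvs(
                a[bad], b[bad], random_state=rng
            )
    return x


def _invwishart_draw(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Bartlett-decomposition inverse-Wishart draw (small dimension)."""
    p = scale.shape[0]
    v = np.linalg.inv(scale)
    cl = np.linalg.cholesky(v)
    a = np.zeros((p, p))
    for i in range(p):
        a[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            a[i, j] = rng.standard_normal()
    la = cl @ a
    w = la @ la.T
    return np.linalg.inv(w)


def sample_latent_indicators(
    rng,
    data: ResponseMatrix,
    items: ItemParams,
    persons: PersonParams,
    space: CategorySpace | None = None,
) -> np.ndarray:
    """Impute the informativeness indicator ``Z`` for every cell.

    Cells with a non-middle score are observed to be informative and stay
    at 1; middle cells draw ``Z ~ Bernoulli(P(Z=1 | X=m, theta))``.
    """
    space = space or data.space
    X = data.scores
    theta = persons.theta
    Z = np.ones_like(X, dtype=np.uint8)
    rows, cols = np.nonzero(X == space.m)
    if len(rows) == 0:
        return Z
    p1 = ndtr(-items.alpha1 * theta[rows, 0] - items.beta[cols])
    eta = items.alpha2[cols] * theta[rows, 1]
    m = space.m
    g_m = ndtr(eta - items.delta[cols, m - 1]) - ndtr(eta - items.delta[cols, m])
    num = p1 * g_m
    pz = num / np.maximum((1.0 - p1) + num, PROB_FLOOR)
    Z[rows, cols] = rng.random(len(rows)) < pz
    return Z


def rescale_identification(theta, mu, Sigma, alpha1, beta, alpha2, delta):
    """Standardize the latent scale of a draw without changing the likelihood.

    Traits are centered at ``mu`` and scaled by ``sqrt(diag(Sigma))``; the
    first-node slope absorbs the theta1 scale and ``beta`` its location,
    the second-node slopes absorb the theta2 scale and the thresholds its
    location, and ``Sigma`` becomes a correlation matrix.
    """
    Sigma = np.asarray(Sigma, float)
    sd = np.sqrt(np.diag(Sigma))
    if np.any(sd <= 0):
        raise InvalidParameterError("latent variance must be positive to rescale")
    theta = (theta - mu) / sd
    beta = beta + alpha1 * mu[0]
    alpha1 = alpha1 * sd[0]
    delta = delta - alpha2[:, None] * mu[1]
    alpha2 = alpha2 * sd[1]
    Sigma = Sigma / np.outer(sd, sd)
    mu = np.zeros_like(np.asarray(mu, float))
    return theta, mu, Sigma, alpha1, beta, alpha2, delta


# ---------------------------------------------------------------------------
# samplers


def _threshold_starts(cat2, valid, n_thr, n0):
    """Probit-transformed empirical cumulative frequencies as starts."""
    if valid.sum() == 0:
        return np.tile(np.linspace(-1.5, 1.5, n_thr), (n0, 1))
    out = np.empty((n0, n_thr))
    for i in range(n0):
        col = cat2[:, i][valid[:, i]]
        if len(col) == 0:
            out[i] = np.linspace(-1.5, 1.5, n_thr)
            continue
        for k in range(n_thr):
            p = np.clip(np.mean(col < k + 1), 0.01, 0.99)
            out[i, k] = ndtri(p)
        out[i] = np.maximum.accumulate(out[i] + 1e-6 * np.arange(n_thr))
    return out


def _mh_thresholds(rng, delta, theta2, alpha2, cat2, W, bound, step):
    """Random-walk Metropolis update of each item's threshold vector.

    Marginalizes the node-2 propensities: the acceptance ratio uses the
    ordinal-probit likelihood of the observed categories of the item's
    informative cells.  This complements the uniform Gibbs draws, whose
    order-statistic-sized moves mix far too slowly through the
    (threshold-width vs non-response share) ridge; run immediately before
    the propensities are refreshed so every subsequent conditional stays
    coherent.
    """
    K, n_thr = delta.shape
    count = np.asarray(W, float).sum(axis=0)
    step = np.clip(step / np.sqrt(count + 1.0), 0.01, 0.5)[:, None]
    prop = delta + step * rng.standard_normal(delta.shape)
    ok = (
        np.all(np.diff(prop, axis=1) > 0, axis=1)
        & (prop[:, 0] > -bound)
        & (prop[:, -1] < bound)
    )
    eta = alpha2[None, :] * theta2[:, None]
    item_idx = np.broadcast_to(np.arange(K), cat2.shape)

    def item_loglik(d):
        dpad = np.concatenate(
            [np.full((K, 1), -np.inf), d, np.full((K, 1), np.inf)], axis=1
        )
        g = ndtr(eta - dpad[item_idx, cat2]) - ndtr(eta - dpad[item_idx, cat2 + 1])
        return np.where(W, np.log(np.maximum(g, PROB_FLOOR)), 0.0).sum(axis=0)

    llr = item_loglik(prop) - item_loglik(delta)
    accept = ok & (np.log(rng.random(K)) < llr)
    delta[accept] = prop[accept]
    return delta


def _update_thresholds(rng, delta, Y2, cat2, W, n_thr, bound):
    """Uniform conditional draws of each threshold between flanking propensities."""
    K = delta.shape[0]
    neg = np.float64(-np.inf)
    for k in range(n_thr):
        below = np.where(W & (cat2 == k), Y2, neg).max(axis=0, initial=-np.inf)
        above = np.where(W & (cat2 == k + 1), Y2, np.inf).min(axis=0, initial=np.inf)
        lo = np.maximum(below, -bound)
        if k > 0:
            lo = np.maximum(lo, delta[:, k - 1])
        hi = np.minimum(above, bound)
        if k < n_thr - 1:
            hi = np.minimum(hi, delta[:, k + 1])
        hi = np.maximum(hi, lo)  # fp guard; interval is nonempty in exact arithmetic
        delta[:, k] = lo + (hi - lo) * rng.random(K)
    return delta


def _fit_tree(
    data: ResponseMatrix,
    prior: PriorSpec,
    config: ChainConfig,
    init: dict | None = None,
):
    """Shared sampler for the mixture tree (rmm) and hard tree (irtree)."""
    mixture = config.model == "rmm"
    space = data.space
    X = data.scores
    N, K = X.shape
    h, m = space.h, space.m
    rng = np.random.default_rng(config.seed)

    is_mid = X == m
    if mixture:
        n_thr = h
        cat2 = X
    else:
        n_thr = h - 1
        cat2 = np.where(X < m, X, X - 1)
        cat2 = np.where(is_mid, 0, cat2)  # placeholder, masked out below
        if N > 0 and np.any(is_mid.all(axis=0)):
            warnings.warn(
                "item(s) with only middle-category responses carry no "
                "second-node information under the irtree model; their "
                "GRM parameters are prior-dominated",
                stacklevel=3,
            )

    # Warm starts keep the chain out of a long-lived metastable basin in
    # which the middle thresholds absorb the non-response excess (threshold
    # moves are order-statistic sized, so escaping it takes thousands of
    # sweeps).  The excess of an item's middle share over the average of
    # its neighbouring categories' shares estimates its non-informative
    # share; this seeds beta, the middle-cell indicators, the thresholds
    # (quantiles of the excess-corrected category frequencies) and theta1
    # (standardized per-person middle counts).
    theta = rng.standard_normal((N, 2))
    alpha1 = prior.alpha1_mean
    alpha2 = np.full(K, prior.alpha2_mean)
    mu = np.zeros(2)
    Sigma = np.eye(2)
    if mixture and N > 0:
        freq = np.stack(
            [np.bincount(X[:, i], minlength=h + 1) / N for i in range(K)]
        )  # (K, h+1)
        smooth_mid = 0.5 * (freq[:, m - 1] + freq[:, m + 1])
        excess = np.clip(freq[:, m] - smooth_mid, 0.005, 0.95)  # ~ item NR-rate
        beta = -np.sqrt(1.0 + alpha1**2) * ndtri(1.0 - excess)
        p_noninf = np.clip(excess / np.maximum(freq[:, m], 1e-12), 0.0, 0.99)
        Z = np.ones((N, K), dtype=bool)
        Z[is_mid] = rng.random(is_mid.sum()) >= p_noninf[np.nonzero(is_mid)[1]]
        # thresholds at probit quantiles of the informative-path frequencies
        cum_obs = np.cumsum(freq, axis=1)[:, :-1]  # (K, h): P(X < k), k=1..h
        cum_inf = np.where(
            np.arange(1, h + 1)[None, :] <= m,
            cum_obs,
            cum_obs - excess[:, None],
        ) / (1.0 - excess[:, None])
        delta = ndtri(np.clip(cum_inf, 0.01, 0.99))
        delta = np.maximum.accumulate(delta + 1e-6 * np.arange(n_thr), axis=1)
        # theta1 from each person's standardized middle-usage
        mid_count = is_mid.sum(axis=1).astype(float)
        sd = mid_count.std()
        if sd > 0:
            theta[:, 0] = (mid_count - mid_count.mean()) / sd
    else:
        Z = np.ones((N, K), dtype=bool) if mixture else ~is_mid
        beta = np.full(K, prior.beta_mean)
        valid = np.ones_like(Z) if mixture else ~is_mid
        delta = _threshold_starts(cat2, valid, n_thr, K)
    if init:
        theta = np.array(init.get("theta", theta), float)
        alpha1 = float(init.get("alpha1", alpha1))
        beta = np.array(init.get("beta", beta), float)
        alpha2 = np.array(init.get("alpha2", alpha2), float)
        delta = np.array(init.get("delta", delta), float)

    mid_rows, mid_cols = np.nonzero(is_mid)
    n_mid = len(mid_rows)
    item_idx = np.broadcast_to(np.arange(K), (N, K))

    n_ret = (config.n_iterations - config.burnin) // config.thin
    ret = {
        "alpha1": np.empty(n_ret),
        "beta": np.empty((n_ret, K)),
        "alpha2": np.empty((n_ret, K)),
        "delta": np.empty((n_ret, K, n_thr)),
        "theta": np.empty((n_ret, N, 2)),
        "mu": np.empty((n_ret, 2)),
        "Sigma": np.empty((n_ret, 2, 2)),
        "z": np.empty((n_ret, n_mid), dtype=np.uint8) if mixture else None,
    }
    r = 0

    for it in range(config.n_iterations):
        # -- path indicators for middle cells (rmm only)
        if mixture and n_mid:
            p1m = ndtr(-alpha1 * theta[mid_rows, 0] - beta[mid_cols])
            eta = alpha2[mid_cols] * theta[mid_rows, 1]
            g_m = ndtr(eta - delta[mid_cols, m - 1]) - ndtr(eta - delta[mid_cols, m])
            num = p1m * g_m
            pz = num / np.maximum((1.0 - p1m) + num, PROB_FLOOR)
            Z[mid_rows, mid_cols] = rng.random(n_mid) < pz

        # -- first-node propensities, sign-linked to Z
        mean1 = -alpha1 * theta[:, 0:1] - beta[None, :]
        lo1 = np.where(Z, 0.0, -np.inf)
        hi1 = np.where(Z, np.inf, 0.0)
        Y1 = truncated_normal(rng, mean1, lo1, hi1)

        # -- thresholds, propensity-marginal Metropolis move
        delta = _mh_thresholds(
            rng, delta, theta[:, 1], alpha2, cat2, Z, prior.threshold_bound, 2.4
        )

        # -- second-node propensities within the observed category interval
        dpad = np.concatenate(
            [np.full((K, 1), -np.inf), delta, np.full((K, 1), np.inf)], axis=1
        )
        lo2 = dpad[item_idx, cat2]
        hi2 = dpad[item_idx, cat2 + 1]
        if not mixture:  # middle cells have no node-2 outcome; draw unconstrained
            lo2 = np.where(is_mid, -np.inf, lo2)
            hi2 = np.where(is_mid, np.inf, hi2)
        mean2 = theta[:, 1:2] * alpha2[None, :]
        Y2 = truncated_normal(rng, mean2, lo2, hi2)

        # -- second-node slopes: per-item truncated-normal regression on theta2
        t2 = theta[:, 1]
        s_tt = Z.T @ (t2**2) + 1.0 / prior.alpha2_var
        s_ty = (Z * Y2).T @ t2 + prior.alpha2_mean / prior.alpha2_var
        alpha2 = truncated_normal(
            rng, s_ty / s_tt, 0.0, np.inf, sd=1.0 / np.sqrt(s_tt)
        )

        # -- thresholds
        delta = _update_thresholds(
            rng, delta, Y2, cat2, Z, n_thr, prior.threshold_bound
        )

        # -- first-node slope (pooled) and intercept parameters
        t1 = theta[:, 0]
        prec_a1 = K * float(t1 @ t1) + 1.0 / prior.alpha1_var
        lin_a1 = (
            -float(t1 @ (Y1 + beta[None, :]).sum(axis=1))
            + prior.alpha1_mean / prior.alpha1_var
        )
        alpha1 = float(
            truncated_normal(
                rng, lin_a1 / prec_a1, 0.0, np.inf, sd=1.0 / np.sqrt(prec_a1)
            )
        )
        prec_b = N + 1.0 / prior.beta_var
        mean_b = (
            -(Y1 + alpha1 * t1[:, None]).sum(axis=0) + prior.beta_mean / prior.beta_var
        ) / prec_b
        beta = mean_b + rng.standard_normal(K) / np.sqrt(prec_b)

        if N > 0:
            # -- persons: joint bivariate-normal conditional
            s_inv = np.linalg.inv(Sigma)
            prior_lin = s_inv @ mu
            p11 = s_inv[0, 0] + K * alpha1**2
            p22 = s_inv[1, 1] + Z @ (alpha2**2)
            p12 = s_inv[0, 1]
            l1 = prior_lin[0] - alpha1 * (Y1 + beta[None, :]).sum(axis=1)
            l2 = prior_lin[1] + (Z * Y2) @ alpha2
            det = p11 * p22 - p12**2
            c11 = p22 / det
            c22 = p11 / det
            c12 = -p12 / det
            mean_t1 = c11 * l1 + c12 * l2
            mean_t2 = c12 * l1 + c22 * l2
            l11 = np.sqrt(c11)
            l21 = c12 / l11
            l22 = np.sqrt(np.maximum(c22 - l21**2, 1e-300))
            zdraw = rng.standard_normal((N, 2))
            theta = np.column_stack(
                [
                    mean_t1 + l11 * zdraw[:, 0],
                    mean_t2 + l21 * zdraw[:, 0] + l22 * zdraw[:, 1],
                ]
            )

            # -- population mean (flat prior) and covariance (inverse-Wishart)
            mu = theta.mean(axis=0) + np.linalg.cholesky(
                Sigma / N
            ) @ rng.standard_normal(2)
            dev = theta - mu
            scale = prior.sigma_scale * np.eye(2) + dev.T @ dev
            Sigma = _invwishart_draw(rng, prior.sigma_df + N, scale)

            # -- identification: standardize the latent scale each sweep
            theta, mu, Sigma, alpha1, beta, alpha2, delta = rescale_identification(
                theta, mu, Sigma, alpha1, beta, alpha2, delta
            )

        if it >= config.burnin and (it - config.burnin) % config.thin == 0:
            ret["alpha1"][r] = alpha1
            ret["beta"][r] = beta
            ret["alpha2"][r] = alpha2
            ret["delta"][r] = delta
            ret["theta"][r] = theta
            ret["mu"][r] = mu
            ret["Sigma"][r] = Sigma
            if mixture:
                ret["z"][r] = Z[mid_rows, mid_cols]
            r += 1

    z_mean = None
    z_draws = None
    if mixture:
        z_draws = ret["z"]
        z_mean = np.ones((N, K))
        if n_mid:
            z_mean[mid_rows, mid_cols] = z_draws.mean(axis=0)
    else:
        z_mean = (~is_mid).astype(float)

    return PosteriorSamples(
        model=config.model,
        space=space,
        alpha1=ret["alpha1"],
        beta=ret["beta"],
        alpha2=ret["alpha2"],
        delta=ret["delta"],
        theta=ret["theta"],
        mu=ret["mu"],
        Sigma=ret["Sigma"],
        z_draws=z_draws,
        middle_rows=mid_rows if mixture else None,
        middle_cols=mid_cols if mixture else None,
        z_mean=z_mean,
    )


def _fit_grm(data: ResponseMatrix, prior: PriorSpec, config: ChainConfig):
    """Ordinary probit GRM sampler (single trait, no first node)."""
    space = data.space
    X = data.scores
    N, K = X.shape
    h = space.h
    n_thr = h
    rng = np.random.default_rng(config.seed)

    theta = rng.standard_normal(N)
    alpha2 = np.full(K, prior.alpha2_mean)
    delta = _threshold_starts(X, np.ones_like(X, dtype=bool), n_thr, K)
    mu = 0.0
    sig2 = 1.0
    item_idx = np.broadcast_to(np.arange(K), (N, K))
    ones = np.ones((N, K), dtype=bool)

    n_ret = (config.n_iterations - config.burnin) // config.thin
    ret = {
        "alpha2": np.empty((n_ret, K)),
        "delta": np.empty((n_ret, K, n_thr)),
        "theta": np.empty((n_ret, N, 1)),
        "mu": np.empty((n_ret, 1)),
        "Sigma": np.empty((n_ret, 1, 1)),
    }
    r = 0

    for it in range(config.n_iterations):
        delta = _mh_thresholds(
            rng, delta, theta, alpha2, X, ones, prior.threshold_bound, 2.4
        )
        dpad = np.concatenate(
            [np.full((K, 1), -np.inf), delta, np.full((K, 1), np.inf)], axis=1
        )
        lo2 = dpad[item_idx, X]
        hi2 = dpad[item_idx, X + 1]
        Y2 = truncated_normal(rng, theta[:, None] * alpha2[None, :], lo2, hi2)

        s_tt = float(theta @ theta) + 1.0 / prior.alpha2_var
        s_ty = Y2.T @ theta + prior.alpha2_mean / prior.alpha2_var
        alpha2 = truncated_normal(
            rng, s_ty / s_tt, 0.0, np.inf, sd=1.0 / np.sqrt(s_tt)
        )

        delta = _update_thresholds(rng, delta, Y2, X, ones, n_thr, prior.threshold_bound)

        if N > 0:
            prec = float(alpha2 @ alpha2) + 1.0 / sig2
            lin = Y2 @ alpha2 + mu / sig2
            theta = lin / prec + rng.standard_normal(N) / np.sqrt(prec)

            mu = theta.mean() + np.sqrt(sig2 / N) * rng.standard_normal()
            ss = prior.sigma_scale + float(((theta - mu) ** 2).sum())
            sig2 = ss / rng.chisquare(prior.sigma_df + N)

            sd = np.sqrt(sig2)
            theta = (theta - mu) / sd
            delta = delta - alpha2[:, None] * mu
            alpha2 = alpha2 * sd
            mu, sig2 = 0.0, 1.0

        if it >= config.burnin and (it - config.burnin) % config.thin == 0:
            ret["alpha2"][r] = alpha2
            ret["delta"][r] = delta
            ret["theta"][r, :, 0] = theta
            ret["mu"][r, 0] = mu
            ret["Sigma"][r, 0, 0] = sig2
            r += 1

    return PosteriorSamples(
        model="grm",
        space=space,
        alpha2=ret["alpha2"],
        delta=ret["delta"],
        theta=ret["theta"],
        mu=ret["mu"],
        Sigma=ret["Sigma"],
    )


def fit(
    data: ResponseMatrix,
    prior: PriorSpec | None = None,
    config: ChainConfig | None = None,
    init: dict | None = None,
) -> PosteriorSamples:
    """Run the Gibbs sampler selected by ``config.model`` and return retained draws.

    Runs are reproducible: the same data, prior and config (including
    seed) give bit-identical chains.  ``init`` optionally overrides the
    default starting values (keys among theta, alpha1, beta, alpha2,
    delta) for diagnostics such as truth-initialized chains.
    """
    prior = prior or PriorSpec()
    config = config or ChainConfig()
    if config.model == "grm":
        return _fit_grm(data, prior, config)
    return _fit_tree(data, prior, config, init)
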