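"""Bayesian variable selection (BVS) over a binary probit model.

The model: y_i = 1{z_i > 0} with latent z_i ~ N(w_i' beta, 1), where w_i
holds an intercept plus the expression of the currently included genes.
Coefficients carry a zero-mean Gaussian prior N(0, c I) and are integrated
out analytically, so the Markov chain moves on the gene-inclusion vector
gamma (Metropolis-Hastings add/delete/swap moves scored by the marginal
likelihood of the latent variables) interleaved with Gibbs updates of the
latent variables through their truncated-normal full conditionals.
Post-burn-in visit counts over subsets and per-gene marginal inclusion
frequencies summarise each chain; chains run at prior mean model sizes of
10 and 20 in the reference protocol and the pooled minimum-error subset is
the method's representative model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import truncnorm
from sklearn.model_selection import StratifiedKFold

from .datasets import ExpressionDataset
from .summary import RepresentativeModel


class UnsupportedEndpointError(ValueError):
    """The endpoint is not a two-class label vector."""


@dataclass(frozen=True)
class BVSConfig:
    """MCMC settings.

    ``expected_model_size`` sets the Bernoulli prior inclusion rate
    (expected_model_size / n_genes), so the prior mean model size equals it.
    ``prior_scale`` is c in the N(0, c I) coefficient prior.  Moves are
    add/delete/swap with probabilities ``move_probs``.
    """

    expected_model_size: int = 10
    prior_scale: float = 10.0
    n_iterations: int = 10000
    burn_in: int = 2000
    n_chains: int = 2
    seed: int = 0
    move_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)

    def __post_init__(self) -> None:
        if self.expected_model_size < 1:
            raise ValueError("expected_model_size must be positive")
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if abs(sum(self.move_probs) - 1.0) > 1e-9 or min(self.move_probs) < 0:
            raise ValueError("move_probs must be non-negative and sum to 1")


@dataclass
class BVSState:
    """Current MCMC state: inclusion vector, latent variables, log marginal."""

    gamma: np.ndarray
    latent: np.ndarray
    log_marginal: float


@dataclass
class ChainSummary:
    """Post-burn-in record of one chain."""

    visited_subsets: Counter
    marginal_inclusion: np.ndarray
    n_kept: int
    config: BVSConfig
    trace: list[tuple[int, int, float]] = field(default_factory=list, repr=False)

    def top_subsets(self, k: int) -> list[tuple[tuple[int, ...], int]]:
        return sorted(
            self.visited_subsets.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0])
        )[:k]


def log_marginal_latent(z: np.ndarray, x_incl: np.ndarray, c: float) -> float:
    """log N(z; 0, I + c W W') for W = [1, x_incl], coefficients integrated out.

    Uses the Sylvester determinant identity and the Woodbury inverse, so the
    cost is cubic in the (small) number of included genes, not in samples.
    """
    n = len(z)
    w = np.column_stack([np.ones(n), x_incl]) if x_incl.size else np.ones((n, 1))
    p = w.shape[1]
    m = w.T @ w + np.eye(p) / c
    cho = linalg.cho_factor(m, lower=True)
    logdet = p * np.log(c) + 2.0 * np.sum(np.log(np.diag(cho[0])))
    v = w.T @ z
    quad = z @ z - v @ linalg.cho_solve(cho, v)
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + quad))


def _sample_beta(z: np.ndarray, w: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    """Draw beta | z from N(M^-1 W'z, M^-1) with M = W'W + I/c."""
    p = w.shape[1]
    m = w.T @ w + np.eye(p) / c
    chol = linalg.cholesky(m, lower=True)
    mean = linalg.cho_solve((chol, True), w.T @ z)
    # M^-1 = L^-T L^-1, so mean + L^-T eps has covariance M^-1
    return mean + linalg.solve_triangular(chol, rng.standard_normal(p), lower=True, trans="T")


def _sample_latent(
    mean: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal draws keeping sign(z_i) consistent with y_i."""
    a = np.where(y == 1, -mean, -np.inf)
    b = np.where(y == 1, np.inf, -mean)
    return truncnorm.rvs(a, b, loc=mean, scale=1.0, random_state=rng)


def run_chain(
    ds: ExpressionDataset,
    endpoint: str,
    cfg: BVSConfig,
    chain_seed: int,
) -> ChainSummary:
    """Run one MCMC chain and summarise its post-burn-in visits."""
    y = ds.endpoint(endpoint)
    classes = np.unique(y)
    if len(classes) != 2:
        raise UnsupportedEndpointError(
            f"endpoint {endpoint!r} has {len(classes)} classes; BVS requires 2"
        )
    if len(y) < 4 or min((y == c).sum() for c in classes) < 1:
        raise UnsupportedEndpointError("need >= 4 samples with both classes present")
    x = ds.matrix
    n, n_genes = x.shape
    c = cfg.prior_scale
    pi = min(cfg.expected_model_size / n_genes, 0.5)
    log_odds = np.log(pi) - np.log1p(-pi)
    rng = np.random.default_rng(chain_seed)

    gamma = np.zeros(n_genes, dtype=bool)
    init = rng.choice(n_genes, size=min(cfg.expected_model_size, n_genes), replace=False)
    gamma[init] = True
    z = _sample_latent(np.zeros(n), y, rng)
    incl = np.flatnonzero(gamma)
    logm = log_marginal_latent(z, x[:, incl], c)

    visits: Counter = Counter()
    inclusion = np.zeros(n_genes)
    trace: list[tuple[int, int, float]] = []
    move_kinds = np.array([0, 1, 2])

    for it in range(cfg.n_iterations):
        # (a) Gibbs refresh of beta and the latent variables for current gamma
        w = np.column_stack([np.ones(n), x[:, incl]])
        beta = _sample_beta(z, w, c, rng)
        z = _sample_latent(w @ beta, y, rng)
        logm = log_marginal_latent(z, x[:, incl], c)

        # (b) Metropolis-Hastings add/delete/swap on gamma
        kind = int(rng.choice(move_kinds, p=cfg.move_probs))
        prop = gamma.copy()
        n_in = incl.size
        n_out = n_genes - n_in
        log_q = 0.0
        d_prior = 0.0
        ok = True
        if kind == 0:  # add
            if n_out == 0:
                ok = False
            else:
                excl = np.flatnonzero(~gamma)
                prop[excl[rng.integers(n_out)]] = True
                log_q = np.log(n_out) - np.log(n_in + 1)  # q(del back)/q(add)
                d_prior = log_odds
        elif kind == 1:  # delete
            if n_in == 0:
                ok = False
            else:
                prop[incl[rng.integers(n_in)]] = False
                log_q = np.log(n_in) - np.log(n_out + 1)
                d_prior = -log_odds
        else:  # swap (symmetric proposal, size-preserving)
            if n_in == 0 or n_out == 0:
                ok = False
            else:
                excl = np.flatnonzero(~gamma)
                prop[incl[rng.integers(n_in)]] = False
                prop[excl[rng.integers(n_out)]] = True
        if ok:
            prop_incl = np.flatnonzero(prop)
            prop_logm = log_marginal_latent(z, x[:, prop_incl], c)
            if np.log(rng.random()) < prop_logm - logm + d_prior + log_q:
                gamma, incl, logm = prop, prop_incl, prop_logm

        if it >= cfg.burn_in:
            visits[tuple(incl.tolist())] += 1
            inclusion[incl] += 1.0
        trace.append((it, int(incl.size), logm))

    n_kept = cfg.n_iterations - cfg.burn_in
    return ChainSummary(
        visited_subsets=visits,
        marginal_inclusion=inclusion / n_kept,
        n_kept=n_kept,
        config=cfg,
        trace=trace,
    )


def _probit_posterior_mean_beta(
    x: np.ndarray, y: np.ndarray, c: float, rng: np.random.Generator,
    n_sweeps: int = 150, n_burn: int = 30,
) -> np.ndarray:
    """Posterior mean of beta for a fixed gene subset via the latent Gibbs sampler."""
    n = len(y)
    w = np.column_stack([np.ones(n), x])
    z = _sample_latent(np.zeros(n), y, rng)
    total = np.zeros(w.shape[1])
    for sweep in range(n_sweeps):
        beta = _sample_beta(z, w, c, rng)
        z = _sample_latent(w @ beta, y, rng)
        if sweep >= n_burn:
            total += beta
    return total / (n_sweeps - n_burn)


def subset_cv_error(
    ds: ExpressionDataset,
    endpoint: str,
    genes,
    c: float = 10.0,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated misclassification error of the probit predictive rule.

    The subset is refit on each training fold (posterior-mean linear
    predictor); a test sample is called positive when its predictor is
    positive.  An empty subset predicts the training majority class.
    """
    y = ds.endpoint(endpoint)
    genes = list(genes)
    x = ds.matrix[:, genes] if genes else np.empty((len(y), 0))
    rng = np.random.default_rng(seed)
    k = min(k, int(np.bincount(y).min()))
    if k < 2:
        raise ValueError("need at least 2 samples per class for CV error")
    errs = []
    for tr, te in StratifiedKFold(k, shuffle=True, random_state=seed).split(x, y):
        if not genes:
            pred = np.full(len(te), np.bincount(y[tr]).argmax())
        else:
            beta = _probit_posterior_mean_beta(x[tr], y[tr], c, rng)
            eta = np.column_stack([np.ones(len(te)), x[te]]) @ beta
            pred = (eta > 0).astype(int)
        errs.append(np.mean(pred != y[te]))
    return float(np.mean(errs))


def pool_chains(
    summaries: list[ChainSummary],
    ds: ExpressionDataset,
    endpoint: str,
    tissue: str | None = None,
    top_models: int = 10,
    cv_seed: int = 0,
) -> RepresentativeModel:
    """Select the minimum-CV-error subset from the union of the chains.

    Candidates are the most-visited subsets across all chains; each is
    scored by :func:`subset_cv_error` and the minimum-error subset wins,
    ties broken by smaller size, then by higher pooled visit count.
    """
    if not summaries:
        raise ValueError("need at least one chain summary")
    pooled: Counter = Counter()
    for s in summaries:
        pooled.update(s.visited_subsets)
    if not pooled:
        raise ValueError("chains recorded no visits (burn_in too large?)")
    nonempty = {k: v for k, v in pooled.items() if k} or pooled
    candidates = sorted(nonempty.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))[:top_models]
    c = summaries[0].config.prior_scale
    scored = []
    for subset, n_visits in candidates:
        err = subset_cv_error(ds, endpoint, list(subset), c=c, seed=cv_seed)
        scored.append((err, len(subset), -n_visits, subset))
    scored.sort()
    err, size, neg_visits, best = scored[0]
    genes = [ds.gene_ids[i] for i in best]
    return RepresentativeModel(
        genes=genes,
        method="BVS",
        endpoint=endpoint,
        tissue=tissue or ds.tissue,
        accuracy=1.0 - err,
        size=len(genes),
        extras={"cv_error": err, "visits": -neg_visits},
    )
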