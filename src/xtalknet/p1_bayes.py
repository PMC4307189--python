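"""Joint hierarchical Bayesian fit of the undirected p1-model.

Model
-----
For each condition c in {resistant (R), parental (P)} the observed
relationship network is modelled dyad-independently:

    u_ij^c ~ Bernoulli(sigma(theta_c + alpha_i^c + alpha_j^c)),  i < j

where sigma is the logistic function, theta_c is a global density
parameter and alpha_i^c the propensity ("expansiveness/attractiveness")
of gene i under condition c.  The per-dyad scaling constant that makes
the two dyad states sum to one is eliminated analytically, which is what
collapses the dyad likelihood to the Bernoulli-logistic form above.

Priors couple the two conditions through the genes:

    theta_c ~ N(0, 1/tau_c),  tau_c ~ Gamma(a0, b0)       (a0 = b0 = 0.001)
    (alpha_i^R, alpha_i^P) ~ N(0, Sigma)
    Sigma^{-1} ~ Wishart(scale R0 = I, df 2)

The Wishart is parameterized so that the prior density is proportional to
|S^-1|^((df-3)/2) exp(-tr(R0 S^-1)/2); the full conditional of Sigma^{-1}
is then Wishart with df (2 + g) and scale matrix (R0 + sum_i a_i a_i^T)^{-1}
in scipy's convention, where a_i is the i-th propensity pair.

Sampling
--------
The default sampler augments every dyad with a Polya-Gamma latent
variable, making the full conditionals of all alpha (jointly, a 2g-dim
Gaussian), theta_R and theta_P exact Gaussian draws; tau and Sigma^{-1}
are conjugate Gamma/Wishart draws.  PG(1, z) variables are generated
from the infinite convolution of scaled exponentials, truncated with an
analytic tail-mean correction (see ``_sample_pg``).  A random-walk
Metropolis-within-Gibbs sampler with adaptive step sizes is provided as
an independent alternative; both target the same posterior.

Posterior edge probabilities follow the posterior-predictive rule: per
retained draw each dyad carries probability sigma(theta + alpha_i +
alpha_j); the "draws" estimator flips one coin per dyad per retained
iteration and reports the proportion of sampled networks containing the
edge, while the "mean" estimator averages the probabilities directly
(same expectation, lower variance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import expit
from scipy.stats import wishart

from .network_builder import RelationshipNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "P1Config",
    "P1Posterior",
    "edge_probability",
    "dyad_probabilities",
    "log_likelihood",
    "gibbs_fit",
    "posterior_edge_probs",
    "brute_force_posterior",
]


# ---------------------------------------------------------------------------
# dyad probabilities and likelihood
# ---------------------------------------------------------------------------

def edge_probability(theta, alpha_i, alpha_j):
    """Probability that a dyad carries an edge: logistic of the linear predictor.

    Numerically stable for linear predictors up to +/- ~700.
    """
    return expit(np.asarray(theta, dtype=float) + alpha_i + alpha_j)


def dyad_probabilities(theta, alpha_i, alpha_j):
    """(Pr[edge present], Pr[edge absent]) for one dyad.

    The absent-state probability is the exact floating-point complement, so
    the two states sum to one by construction (the role the per-dyad scaling
    constant plays in the model).
    """
    p1 = edge_probability(theta, alpha_i, alpha_j)
    return p1, 1.0 - p1


def log_likelihood(network: RelationshipNetwork, theta: float, alpha: np.ndarray) -> float:
    """Bernoulli log-likelihood of an observed network given (theta, alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    g = network.n_genes
    if alpha.shape != (g,):
        raise ValueError("alpha length must equal number of genes")
    iu = np.triu_indices(g, 1)
    psi = theta + alpha[iu[0]] + alpha[iu[1]]
    u = network.adjacency[iu].astype(float)
    # u*psi - log(1 + e^psi), computed stably
    return float(np.sum(u * psi - np.logaddexp(0.0, psi)))


# ---------------------------------------------------------------------------
# configuration and posterior containers
# ---------------------------------------------------------------------------

@dataclass
class P1Config:
    """Settings for the MCMC fit.

    Defaults follow the study design: 6000 total iterations with the first
    5000 discarded, leaving 1000 retained networks; vague Gamma(0.001, 0.001)
    hyperpriors on the theta precisions; Wishart(identity, 2) prior on the
    propensity precision matrix.  ``fixed_sigma`` / ``fixed_tau_theta``
    clamp the corresponding hyperparameters instead of sampling them (used
    when comparing against the small-instance grid oracle).
    """

    seed: int
    n_iter: int = 6000
    burn_in: int = 5000
    a0: float = 0.001
    b0: float = 0.001
    wishart_df: float = 2.0
    wishart_scale: np.ndarray = field(default_factory=lambda: np.eye(2))
    edge_prob_estimator: str = "mean"
    sampler: str = "polya_gamma"
    fixed_sigma: np.ndarray | None = None
    fixed_tau_theta: float | None = None
    pg_trunc: int = 100

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.burn_in >= self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.n_iter - self.burn_in < 100:
            raise ValueError("need at least 100 retained iterations")
        if self.edge_prob_estimator not in ("mean", "draws"):
            raise ValueError(f"unknown estimator {self.edge_prob_estimator!r}")
        if self.sampler not in ("polya_gamma", "metropolis_within_gibbs"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("Gamma hyperparameters must be positive")
        self.wishart_scale = np.asarray(self.wishart_scale, dtype=float)
        _check_spd(self.wishart_scale, "wishart_scale")
        if self.wishart_df < 2:
            raise ValueError("wishart_df must be >= 2")
        if self.fixed_sigma is not None:
            self.fixed_sigma = np.asarray(self.fixed_sigma, dtype=float)
            _check_spd(self.fixed_sigma, "fixed_sigma")
        if self.fixed_tau_theta is not None and self.fixed_tau_theta <= 0:
            raise ValueError("fixed_tau_theta must be positive")


def _check_spd(m: np.ndarray, name: str) -> None:
    if m.shape != (2, 2) or not np.allclose(m, m.T):
        raise ValueError(f"{name} must be a symmetric 2x2 matrix")
    if np.any(np.linalg.eigvalsh(m) <= 0):
        raise ValueError(f"{name} must be positive-definite")


@dataclass
class P1Posterior:
    """Retained MCMC draws plus derived posterior edge probabilities.

    ``theta`` has shape (T, 2) ordered (resistant, parental); ``alpha``
    (T, g, 2) with column 0 the resistant propensity; ``sigma`` (T, 2, 2);
    ``tau_theta`` (T, 2).  ``edge_prob_R`` / ``edge_prob_P`` are symmetric
    g x g matrices of posterior edge probabilities with zero diagonal.
    """

    gene_ids: list[str]
    theta: np.ndarray
    alpha: np.ndarray
    sigma: np.ndarray
    tau_theta: np.ndarray
    edge_prob_R: np.ndarray
    edge_prob_P: np.ndarray
    config: P1Config

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    def diagnostics(self) -> "pd.DataFrame":
        """Posterior mean, sd and effective sample size per scalar parameter."""
        import pandas as pd

        def ess(x: np.ndarray) -> float:
            try:
                import arviz as az

                return float(az.ess(np.asarray(x)[None, :]))
            except Exception:  # pragma: no cover - arviz always available in practice
                return float(len(x))

        rows = {}
        for k, label in enumerate(("theta_R", "theta_P")):
            x = self.theta[:, k]
            rows[label] = (x.mean(), x.std(), ess(x))
        corr = self.sigma[:, 0, 1] / np.sqrt(self.sigma[:, 0, 0] * self.sigma[:, 1, 1])
        rows["sigma_corr"] = (corr.mean(), corr.std(), ess(corr))
        for k, label in enumerate(("tau_theta_R", "tau_theta_P")):
            x = self.tau_theta[:, k]
            rows[label] = (x.mean(), x.std(), ess(x))
        return pd.DataFrame(rows, index=["mean", "sd", "ess"]).T


# ---------------------------------------------------------------------------
# Polya-Gamma sampling
# ---------------------------------------------------------------------------

def _sample_pg(z: np.ndarray, rng: np.random.Generator, trunc: int = 100) -> np.ndarray:
    """Draw PG(1, z) elementwise.

    Uses the representation PG(1, z) = (1/(2 pi^2)) * sum_k E_k /
    ((k - 1/2)^2 + z^2/(4 pi^2)) with E_k iid Exp(1), truncated at
    ``trunc`` terms; the omitted tail (O(1/trunc) of the mass, nearly
    deterministic) is replaced by its analytic expectation.
    """
    z = np.asarray(z, dtype=float)
    flat = np.abs(z).ravel() / (2.0 * np.pi)
    k = np.arange(1, trunc + 1, dtype=float) - 0.5
    denom = k[:, None] ** 2 + flat[None, :] ** 2
    e = rng.standard_exponential(size=denom.shape)
    s = (e / denom).sum(axis=0)
    small = flat < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = (np.pi / 2.0 - np.arctan((trunc - 0.5) / flat)) / flat
    tail[small] = 1.0 / (trunc - 0.5)
    out = (s + tail) / (2.0 * np.pi ** 2)
    return out.reshape(z.shape)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _validate_pair(network_R: RelationshipNetwork, network_P: RelationshipNetwork):
    if network_R.gene_ids != network_P.gene_ids:
        raise ValueError("resistant and parental networks must share gene_ids in order")
    g = network_R.n_genes
    if g < 2:
        raise ValueError("need at least 2 genes")
    return g


def gibbs_fit(
    network_R: RelationshipNetwork,
    network_P: RelationshipNetwork,
    config: P1Config,
) -> P1Posterior:
    """Jointly fit the two-condition p1-model by MCMC.

    The resistant likelihood touches only (theta_R, alpha^R) and the
    parental likelihood only (theta_P, alpha^P); the conditions are coupled
    solely through the shared propensity covariance Sigma.  Fully
    reproducible given ``config.seed``.
    """
    g = _validate_pair(network_R, network_P)
    rng = np.random.default_rng(config.seed)
    if config.sampler == "polya_gamma":
        return _gibbs_pg(network_R, network_P, config, rng)
    return _gibbs_mwg(network_R, network_P, config, rng)


def _init_state(network_R, network_P, config):
    g = network_R.n_genes
    u = [network_R.adjacency.astype(float), network_P.adjacency.astype(float)]
    dens = [min(max(a.sum() / (g * (g - 1)), 1e-3), 1 - 1e-3) for a in u]
    theta = np.array([np.log(d / (1 - d)) for d in dens])
    alpha = np.zeros((g, 2))
    sigma = np.eye(2) if config.fixed_sigma is None else config.fixed_sigma.copy()
    tau = np.full(2, config.fixed_tau_theta if config.fixed_tau_theta else 1.0)
    return u, theta, alpha, sigma, tau


def _conjugate_hyper_updates(theta, alpha, sigma, tau, config, rng, g):
    """Shared Gamma / Wishart full-conditional updates of tau and Sigma."""
    if config.fixed_tau_theta is None:
        for c in range(2):
            tau[c] = rng.gamma(config.a0 + 0.5, 1.0 / (config.b0 + 0.5 * theta[c] ** 2))
    if config.fixed_sigma is None:
        s = alpha.T @ alpha
        scale = np.linalg.inv(config.wishart_scale + s)
        scale = 0.5 * (scale + scale.T)
        lam = wishart.rvs(df=config.wishart_df + g, scale=scale, random_state=rng)
        sigma = np.linalg.inv(lam)
        sigma = 0.5 * (sigma + sigma.T)
    return sigma, tau


def _gibbs_pg(network_R, network_P, config, rng):
    g = network_R.n_genes
    u, theta, alpha, sigma, tau = _init_state(network_R, network_P, config)
    iu = np.triu_indices(g, 1)
    kappa = [a - 0.5 for a in u]  # u_ij - 1/2 off-diagonal
    for kmat in kappa:
        np.fill_diagonal(kmat, 0.0)

    n_ret = config.n_iter - config.burn_in
    theta_draws = np.empty((n_ret, 2))
    alpha_draws = np.empty((n_ret, g, 2))
    sigma_draws = np.empty((n_ret, 2, 2))
    tau_draws = np.empty((n_ret, 2))
    ep_acc = [np.zeros((g, g)), np.zeros((g, g))]
    eye = np.eye(g)

    for t in range(config.n_iter):
        prec_sigma = np.linalg.inv(sigma)
        # --- Polya-Gamma latents for every dyad of both conditions
        w = []
        for c in range(2):
            psi = theta[c] + alpha[:, c][:, None] + alpha[:, c][None, :]
            wij = _sample_pg(psi[iu], rng, config.pg_trunc)
            wmat = np.zeros((g, g))
            wmat[iu] = wij
            wmat += wmat.T
            w.append(wmat)
        # --- joint Gaussian draw of all 2g propensities
        prec = np.zeros((2 * g, 2 * g))
        b = np.empty(2 * g)
        for c in range(2):
            sl = slice(c * g, (c + 1) * g)
            prec[sl, sl] = np.diag(w[c].sum(axis=1)) + w[c] + prec_sigma[c, c] * eye
            b[sl] = (kappa[c] - w[c] * theta[c]).sum(axis=1)
        prec[:g, g:] = prec_sigma[0, 1] * eye
        prec[g:, :g] = prec_sigma[0, 1] * eye
        chol = cholesky(prec, lower=True)
        mean = cho_solve((chol, True), b)
        x = mean + solve_triangular(chol.T, rng.standard_normal(2 * g), lower=False)
        alpha = np.column_stack([x[:g], x[g:]])
        # --- theta, one Gaussian draw per condition
        for c in range(2):
            asum = alpha[:, c][iu[0]] + alpha[:, c][iu[1]]
            wij = w[c][iu]
            prec_t = tau[c] + wij.sum()
            mean_t = (kappa[c][iu] - wij * asum).sum() / prec_t
            theta[c] = mean_t + rng.standard_normal() / np.sqrt(prec_t)
        # --- hyperparameters
        sigma, tau = _conjugate_hyper_updates(theta, alpha, sigma, tau, config, rng, g)
        if not (np.isfinite(theta).all() and np.isfinite(alpha).all()):
            raise FloatingPointError(f"non-finite sampler state at iteration {t}")
        if t >= config.burn_in:
            r = t - config.burn_in
            theta_draws[r] = theta
            alpha_draws[r] = alpha
            sigma_draws[r] = sigma
            tau_draws[r] = tau
            _accumulate_edge_probs(ep_acc, theta, alpha, config, rng, iu)
        if (t + 1) % 100 == 0:
            logger.debug("iteration %d/%d", t + 1, config.n_iter)

    return _finalize(network_R.gene_ids, theta_draws, alpha_draws, sigma_draws,
                     tau_draws, ep_acc, n_ret, config)


def _accumulate_edge_probs(ep_acc, theta, alpha, config, rng, iu):
    for c in range(2):
        p = expit(theta[c] + alpha[:, c][iu[0]] + alpha[:, c][iu[1]])
        if config.edge_prob_estimator == "draws":
            p = (rng.random(p.shape) < p).astype(float)
        ep_acc[c][iu] += p


def _finalize(gene_ids, theta_draws, alpha_draws, sigma_draws, tau_draws,
              ep_acc, n_ret, config):
    mats = []
    for acc in ep_acc:
        m = acc / n_ret
        m = m + m.T
        mats.append(m)
    return P1Posterior(
        gene_ids=list(gene_ids),
        theta=theta_draws,
        alpha=alpha_draws,
        sigma=sigma_draws,
        tau_theta=tau_draws,
        edge_prob_R=mats[0],
        edge_prob_P=mats[1],
        config=config,
    )


def _gibbs_mwg(network_R, network_P, config, rng):
    """Random-walk Metropolis-within-Gibbs alternative sampler.

    Scalar random-walk updates for each alpha_i^c and each theta_c with
    Robbins-Monro step-size adaptation during burn-in (target acceptance
    0.44); tau and Sigma keep their conjugate draws.
    """
    g = network_R.n_genes
    u, theta, alpha, sigma, tau = _init_state(network_R, network_P, config)
    iu = np.triu_indices(g, 1)

    n_ret = config.n_iter - config.burn_in
    theta_draws = np.empty((n_ret, 2))
    alpha_draws = np.empty((n_ret, g, 2))
    sigma_draws = np.empty((n_ret, 2, 2))
    tau_draws = np.empty((n_ret, 2))
    ep_acc = [np.zeros((g, g)), np.zeros((g, g))]

    step_alpha = np.full((g, 2), 0.5)
    step_theta = np.full(2, 0.5)

    def dyad_ll(c, i, a_i):
        """Log-likelihood terms of condition c touching gene i."""
        others = np.delete(np.arange(g), i)
        psi = theta[c] + a_i + alpha[others, c]
        uu = u[c][i, others]
        return np.sum(uu * psi - np.logaddexp(0.0, psi))

    for t in range(config.n_iter):
        prec_sigma = np.linalg.inv(sigma)
        adapting = t < config.burn_in
        for c in range(2):
            for i in range(g):
                cur = alpha[i, c]
                prop = cur + step_alpha[i, c] * rng.standard_normal()
                a_pair_cur = alpha[i].copy()
                a_pair_prop = a_pair_cur.copy()
                a_pair_prop[c] = prop
                logr = (
                    dyad_ll(c, i, prop) - dyad_ll(c, i, cur)
                    - 0.5 * a_pair_prop @ prec_sigma @ a_pair_prop
                    + 0.5 * a_pair_cur @ prec_sigma @ a_pair_cur
                )
                accept = np.log(rng.random()) < logr
                if accept:
                    alpha[i, c] = prop
                if adapting:
                    step_alpha[i, c] *= np.exp(0.05 * ((1.0 if accept else 0.0) - 0.44))
        for c in range(2):
            asum = alpha[:, c][iu[0]] + alpha[:, c][iu[1]]
            uu = u[c][iu]

            def theta_ll(th):
                psi = th + asum
                return np.sum(uu * psi - np.logaddexp(0.0, psi)) - 0.5 * tau[c] * th ** 2

            prop = theta[c] + step_theta[c] * rng.standard_normal()
            accept = np.log(rng.random()) < theta_ll(prop) - theta_ll(theta[c])
            if accept:
                theta[c] = prop
            if adapting:
                step_theta[c] *= np.exp(0.05 * ((1.0 if accept else 0.0) - 0.44))
        sigma, tau = _conjugate_hyper_updates(theta, alpha, sigma, tau, config, rng, g)
        if not (np.isfinite(theta).all() and np.isfinite(alpha).all()):
            raise FloatingPointError(f"non-finite sampler state at iteration {t}")
        if t >= config.burn_in:
            r = t - config.burn_in
            theta_draws[r] = theta
            alpha_draws[r] = alpha
            sigma_draws[r] = sigma
            tau_draws[r] = tau
            _accumulate_edge_probs(ep_acc, theta, alpha, config, rng, iu)

    return _finalize(network_R.gene_ids, theta_draws, alpha_draws, sigma_draws,
                     tau_draws, ep_acc, n_ret, config)


# ---------------------------------------------------------------------------
# posterior edge probabilities from stored draws
# ---------------------------------------------------------------------------

def posterior_edge_probs(
    posterior: P1Posterior,
    estimator: str = "mean",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Recompute (edge_prob_R, edge_prob_P) from the stored draws.

    ``estimator="draws"`` reproduces the proportion-of-sampled-networks
    rule (one Bernoulli network per retained draw); ``"mean"`` averages the
    per-draw dyad probabilities.
    """
    if estimator not in ("mean", "draws"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if posterior.n_draws == 0:
        raise ValueError("no retained draws")
    rng = np.random.default_rng(posterior.config.seed if seed is None else seed)
    g = len(posterior.gene_ids)
    iu = np.triu_indices(g, 1)
    out = []
    for c in range(2):
        psi = (
            posterior.theta[:, c][:, None]
            + posterior.alpha[:, iu[0], c]
            + posterior.alpha[:, iu[1], c]
        )
        p = expit(psi)
        if estimator == "draws":
            p = (rng.random(p.shape) < p).astype(float)
        m = np.zeros((g, g))
        m[iu] = p.mean(axis=0)
        out.append(m + m.T)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# small-instance grid oracle
# ---------------------------------------------------------------------------

def brute_force_posterior(
    network_R: RelationshipNetwork,
    network_P: RelationshipNetwork,
    theta_grid: np.ndarray,
    alpha_grid: np.ndarray,
    sigma: np.ndarray,
    tau_theta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior edge probabilities by direct summation over a parameter grid.

    Tractable only for tiny networks (g <= 4).  Sigma must be fixed and
    diagonal: the two conditions are then a-priori independent and each
    condition's posterior is a (1+g)-dimensional grid sum over (theta,
    alpha_1..alpha_g).  Passing a single-point ``alpha_grid`` of [0.0]
    clamps the propensities, reducing to one-dimensional quadrature over
    theta.  Intended as a test oracle, not for analysis use.
    """
    g = _validate_pair(network_R, network_P)
    if g > 4:
        raise ValueError("grid oracle is restricted to g <= 4")
    sigma = np.asarray(sigma, dtype=float)
    _check_spd(sigma, "sigma")
    if abs(sigma[0, 1]) > 1e-12:
        raise NotImplementedError("grid oracle requires diagonal Sigma")
    if tau_theta <= 0:
        raise ValueError("tau_theta must be positive")
    theta_grid = np.asarray(theta_grid, dtype=float)
    alpha_grid = np.asarray(alpha_grid, dtype=float)

    out = []
    for c, net in enumerate((network_R, network_P)):
        sd_a = float(np.sqrt(sigma[c, c]))
        ep = _grid_condition(net, theta_grid, alpha_grid, sd_a, 1.0 / np.sqrt(tau_theta))
        out.append(ep)
    return out[0], out[1]


def _grid_condition(net, theta_grid, alpha_grid, sd_alpha, sd_theta):
    g = net.n_genes
    t_ax = theta_grid.reshape((-1,) + (1,) * g)
    a_ax = [alpha_grid.reshape((1,) * (i + 1) + (-1,) + (1,) * (g - 1 - i)) for i in range(g)]
    logw = -0.5 * (t_ax / sd_theta) ** 2
    if alpha_grid.size > 1:
        for i in range(g):
            logw = logw + -0.5 * (a_ax[i] / sd_alpha) ** 2
    for i in range(g):
        for j in range(i + 1, g):
            psi = t_ax + a_ax[i] + a_ax[j]
            logw = logw + net.adjacency[i, j] * psi - np.logaddexp(0.0, psi)
    w = np.exp(logw - logw.max())
    z = w.sum()
    ep = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            psi = t_ax + a_ax[i] + a_ax[j]
            ep[i, j] = ep[j, i] = float((w * expit(psi)).sum() / z)
    return ep
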