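"""Bayesian estimation of the popularity-sensitivity parameter L.

Given two-choice records on a fixed stimulus graph, this module fits:

* per-participant L (joint over both choices, or each choice separately),
* a shared L across all participants,
* a hierarchical model in which L varies across participants as a Gaussian
  with unknown mean and standard deviation,

all by random-walk Metropolis (Metropolis-within-Gibbs for the hierarchical
model), with Gelman–Rubin convergence checks, and compares the shared and
hierarchical models by AICc with the participant effects integrated out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize
from scipy.special import logsumexp, ndtr, ndtri
from scipy.stats import gaussian_kde, norm, truncnorm

_LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


def _norm_logpdf(x, mu: float, sd: float):
    """Vector-friendly normal log-density without scipy dispatch overhead."""
    z = (np.asarray(x) - mu) / sd
    return -0.5 * z * z - math.log(sd) - _LOG_SQRT_2PI


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    """Inverse-CDF draw from a truncated normal (fast scalar path)."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.uniform()
    return float(mean + sd * ndtri(a + u * (b - a)))

from .netgrow import Graph, choice_probabilities

__all__ = [
    "ChoiceRecord",
    "TruncNormPrior",
    "LogNormPrior",
    "MCMCConfig",
    "ParticipantFit",
    "PopulationFit",
    "ModelComparison",
    "participant_loglik",
    "log_posterior",
    "mh_chain",
    "gelman_rubin",
    "fit_participant",
    "fit_choices_separately",
    "fit_shared",
    "fit_hierarchical",
    "marginal_loglik",
    "aicc",
    "compare_models",
    "ChoiceLikelihood",
]

# Per-participant L values are evaluated with this numeric clamp in the
# hierarchical sampler; wide enough that the likelihood is flat beyond it.
_L_WINDOW = (-30.0, 30.0)


@dataclass(frozen=True)
class ChoiceRecord:
    """One participant's two friend selections on the stimulus graph."""

    participant_id: str
    first_choice: int
    second_choice: int

    def __post_init__(self) -> None:
        if self.first_choice == self.second_choice:
            raise ValueError("first and second choices must differ")

    def validate(self, graph: Graph) -> None:
        for c in (self.first_choice, self.second_choice):
            if not (0 <= c < graph.node_count):
                raise ValueError(f"choice {c} not a node of the stimulus graph")


@dataclass(frozen=True)
class TruncNormPrior:
    mu: float = 0.0
    sd: float = 5.0
    lo: float = -10.0
    hi: float = 10.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not self.lo < self.hi:
            raise ValueError("lo must be below hi")
        a, b = (self.lo - self.mu) / self.sd, (self.hi - self.mu) / self.sd
        # log of sd * sqrt(2*pi) * (Phi(b) - Phi(a)), cached for fast logpdf
        log_mass = logsumexp([norm.logcdf(b), norm.logcdf(a)], b=[1.0, -1.0])
        object.__setattr__(
            self, "_log_norm", float(math.log(self.sd) + 0.5 * math.log(2 * math.pi) + log_mass)
        )

    def logpdf(self, x: float) -> float:
        if not (self.lo <= x <= self.hi):
            return -np.inf
        z = (x - self.mu) / self.sd
        return -0.5 * z * z - self._log_norm


@dataclass(frozen=True)
class LogNormPrior:
    """Lognormal prior on a positive scale parameter: log(x) ~ Normal(mu, sd)."""

    mu: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        return float(norm.logpdf(math.log(x), self.mu, self.sd) - math.log(x))

    def logpdf_of_log(self, logx: float) -> float:
        """Density of log(x), i.e. the plain normal — used when sampling in log space."""
        return float(norm.logpdf(logx, self.mu, self.sd))


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 5
    starts: tuple[float, ...] = (-8.0, -2.0, 0.0, 2.0, 8.0)
    proposal_sd: float = 0.1
    tune_interval: int = 200
    n_samples: int = 6000
    rhat_threshold: float = 1.1
    max_extensions: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.starts) != self.n_chains:
            raise ValueError("starts must have one entry per chain")
        if self.proposal_sd <= 0 or self.tune_interval < 1 or self.n_samples < 1:
            raise ValueError("invalid MCMC configuration")
        if self.rhat_threshold <= 1:
            raise ValueError("rhat_threshold must exceed 1")


@dataclass
class ParticipantFit:
    L_map: float
    samples: np.ndarray
    rhat: float
    log_posterior_at_map: float
    converged: bool = True
    message: str = ""


@dataclass
class PopulationFit:
    mu_map: float
    sigma_map: float
    mu_ci: tuple[float, float]
    sigma_ci: tuple[float, float]
    mu_samples: np.ndarray
    sigma_samples: np.ndarray
    rhat: float
    converged: bool = True
    message: str = ""


@dataclass(frozen=True)
class ModelComparison:
    aicc_shared: float
    aicc_hier: float
    n_obs: int
    k_shared: int = 1
    k_hier: int = 2

    @property
    def delta(self) -> float:
        return self.aicc_shared - self.aicc_hier


# ---------------------------------------------------------------------------
# Likelihood


class ChoiceLikelihood:
    """Vectorised two-choice log-likelihood on a fixed stimulus graph.

    For a record (a, b) the log-likelihood at sensitivity L is

        L*log d_a - log sum_j d_j^L  +  L*log d_b - log sum_{j != a} d_j^L,

    evaluated stably in log space; the second normaliser reuses the full one
    via log1p rather than re-summing.
    """

    def __init__(self, graph: Graph, records: Sequence[ChoiceRecord]):
        for r in records:
            r.validate(graph)
        self.graph = graph
        self.records = list(records)
        self.logd = np.log(graph.degrees().astype(float))
        self.a = np.array([r.first_choice for r in records], dtype=np.intp)
        self.b = np.array([r.second_choice for r in records], dtype=np.intp)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def loglik_scalar(self, L: float, which: str = "both") -> np.ndarray:
        """Per-record log-likelihood at a single L shared by all records."""
        w = L * self.logd
        wmax = w.max()
        lse = wmax + math.log(np.exp(w - wmax).sum())
        t1 = w[self.a] - lse
        # normaliser with the first choice removed
        frac = np.exp(np.minimum(t1, -1e-12))
        lse_ex = lse + np.log1p(-frac)
        t2 = w[self.b] - lse_ex
        if which == "first":
            return t1
        if which == "second":
            return t2
        return t1 + t2

    def loglik_vector(self, L: np.ndarray, which: str = "both") -> np.ndarray:
        """Per-record log-likelihood with record i evaluated at L[i]."""
        L = np.asarray(L, dtype=float)
        W = L[:, None] * self.logd[None, :]
        wmax = W.max(axis=1)
        lse = wmax + np.log(np.exp(W - wmax[:, None]).sum(axis=1))
        wa = L * self.logd[self.a]
        t1 = wa - lse
        frac = np.exp(np.minimum(t1, -1e-12))
        lse_ex = lse + np.log1p(-frac)
        t2 = L * self.logd[self.b] - lse_ex
        if which == "first":
            return t1
        if which == "second":
            return t2
        return t1 + t2

    def total_loglik(self, L: float, which: str = "both") -> float:
        return float(self.loglik_scalar(L, which).sum())


def participant_loglik(record: ChoiceRecord, graph: Graph, L: float) -> float:
    """Log-probability of one participant's two choices under sensitivity L.

    The first node is chosen from all nodes; the second from all nodes with
    the first choice excluded.  Degrees are the true stimulus-graph degrees.
    """
    record.validate(graph)
    degrees = graph.degrees().astype(float)
    p1 = choice_probabilities(degrees, L)
    p2 = choice_probabilities(degrees, L, excluded={record.first_choice})
    return float(np.log(p1[record.first_choice]) + np.log(p2[record.second_choice]))


def log_posterior(
    record: ChoiceRecord, graph: Graph, L: float, prior: TruncNormPrior
) -> float:
    if not (prior.lo <= L <= prior.hi):
        return -np.inf
    return participant_loglik(record, graph, L) + prior.logpdf(L)


# ---------------------------------------------------------------------------
# Samplers


def mh_chain(
    logdensity: Callable[[float], float],
    start: float,
    config: MCMCConfig,
    rng: np.random.Generator,
    n_keep: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk Metropolis over a scalar parameter.

    Runs ``n_keep`` post-burn-in steps after a burn-in of half that length.
    The Gaussian proposal scale starts at ``config.proposal_sd`` and is
    re-tuned every ``tune_interval`` steps during burn-in only (multiplied by
    ``exp(2*(acceptance - 0.3))``, steering acceptance towards ~0.3), then
    frozen so the kept portion of the chain is Markovian.

    Returns ``(samples, logdensities)`` for the kept portion.
    """
    if n_keep is None:
        n_keep = config.n_samples
    lp = float(logdensity(start))
    if not np.isfinite(lp):
        raise ValueError("logdensity must be finite at the chain start")

    n_burn = max(n_keep // 2, config.tune_interval)
    total = n_burn + n_keep
    samples = np.empty(n_keep)
    logps = np.empty(n_keep)

    x = float(start)
    scale = config.proposal_sd
    accepted_window = 0
    noise = rng.normal(size=total)
    log_u = np.log(rng.uniform(size=total))
    for step in range(total):
        prop = x + scale * noise[step]
        lp_prop = float(logdensity(prop))
        if log_u[step] < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted_window += 1
        if step < n_burn and (step + 1) % config.tune_interval == 0:
            acc = accepted_window / config.tune_interval
            scale *= math.exp(2.0 * (acc - 0.3))
            accepted_window = 0
        if step >= n_burn:
            samples[step - n_burn] = x
            logps[step - n_burn] = lp
    return samples, logps


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    Each chain is split in half; R-hat is sqrt(((n-1)/n * W + B/n) / W) over
    the resulting 2m half-chains of common length n.
    """
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    n_half = min(len(c) for c in chains) // 2
    if n_half < 1:
        raise ValueError("chains too short for split R-hat")
    halves = []
    for c in chains:
        c = np.asarray(c, dtype=float)
        halves.append(c[:n_half])
        halves.append(c[-n_half:])
    arr = np.stack(halves)  # (2m, n)
    m, n = arr.shape
    chain_means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return np.inf if B > 0 or n > 1 else 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _grid_argmax(logpost: Callable[[float], float], lo: float, hi: float,
                 n_grid: int = 401) -> tuple[float, float]:
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([logpost(g) for g in grid])
    i = int(np.argmax(vals))
    return float(grid[i]), float(vals[i])


def _polish_map(logpost: Callable[[float], float], x0: float, lo: float, hi: float,
                half_width: float = 0.5) -> tuple[float, float]:
    a = max(lo, x0 - half_width)
    b = min(hi, x0 + half_width)
    res = optimize.minimize_scalar(lambda x: -logpost(x), bounds=(a, b), method="bounded")
    if -res.fun >= logpost(x0):
        return float(res.x), float(-res.fun)
    return float(x0), float(logpost(x0))


def _fit_scalar(
    logpost: Callable[[float], float],
    lo: float,
    hi: float,
    config: MCMCConfig,
    rng: np.random.Generator,
) -> ParticipantFit:
    """Shared machinery for every single-parameter fit.

    Runs ``n_chains`` chains from the configured starts, checks split R-hat,
    and doubles the chain length up to ``max_extensions`` times on
    non-convergence.  The MAP is the pooled sample with the highest evaluated
    log-posterior, refined by a bounded local optimisation; if the chains
    never converge the fit falls back to a 401-point grid argmax and is
    flagged rather than failing silently.
    """
    n_keep = max(config.n_samples // config.n_chains, 2)
    starts = [min(max(s, lo), hi) for s in config.starts]
    for attempt in range(config.max_extensions + 1):
        chains, chain_lps = [], []
        for c, start in enumerate(starts):
            if not np.isfinite(logpost(start)):
                start = 0.5 * (lo + hi)
            sub = np.random.default_rng(rng.integers(2**63))
            s, lp = mh_chain(logpost, start, config, sub, n_keep=n_keep)
            chains.append(s)
            chain_lps.append(lp)
        rhat = gelman_rubin(chains)
        if rhat < config.rhat_threshold:
            pooled = np.concatenate(chains)
            pooled_lp = np.concatenate(chain_lps)
            best = int(np.argmax(pooled_lp))
            L_map, lp_map = _polish_map(logpost, float(pooled[best]), lo, hi)
            return ParticipantFit(L_map, pooled, float(rhat), lp_map)
        n_keep *= 2

    g_map, g_lp = _grid_argmax(logpost, lo, hi)
    L_map, lp_map = _polish_map(logpost, g_map, lo, hi, half_width=(hi - lo) / 400)
    pooled = np.concatenate(chains)
    return ParticipantFit(
        L_map, pooled, float(rhat), lp_map, converged=False,
        message=f"chains failed to converge (R-hat {rhat:.3f}); MAP from grid fallback",
    )


def _single_record_logpost(lik: ChoiceLikelihood, idx: int, prior: TruncNormPrior,
                           which: str = "both") -> Callable[[float], float]:
    def logpost(L: float) -> float:
        if not (prior.lo <= L <= prior.hi):
            return -np.inf
        ll = float(lik.loglik_scalar(L, which=which)[idx])
        return ll + prior.logpdf(L)

    return logpost


def fit_participant(
    record: ChoiceRecord,
    graph: Graph,
    prior: TruncNormPrior = TruncNormPrior(),
    config: MCMCConfig = MCMCConfig(),
    rng: np.random.Generator | None = None,
) -> ParticipantFit:
    """Posterior over one participant's L from both choices jointly."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lik = ChoiceLikelihood(graph, [record])
    logpost = _single_record_logpost(lik, 0, prior)
    return _fit_scalar(logpost, prior.lo, prior.hi, config, rng)


def fit_choices_separately(
    record: ChoiceRecord,
    graph: Graph,
    prior: TruncNormPrior = TruncNormPrior(),
    config: MCMCConfig = MCMCConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[ParticipantFit, ParticipantFit]:
    """Fit L once from the first choice only and once from the second only."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lik = ChoiceLikelihood(graph, [record])
    fit1 = _fit_scalar(_single_record_logpost(lik, 0, prior, "first"),
                       prior.lo, prior.hi, config, rng)
    fit2 = _fit_scalar(_single_record_logpost(lik, 0, prior, "second"),
                       prior.lo, prior.hi, config, rng)
    return fit1, fit2


def fit_shared(
    records: Sequence[ChoiceRecord],
    graph: Graph,
    prior: TruncNormPrior = TruncNormPrior(),
    config: MCMCConfig = MCMCConfig(),
    rng: np.random.Generator | None = None,
) -> ParticipantFit:
    """Posterior over a single L shared by every participant."""
    if not records:
        raise ValueError("records must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lik = ChoiceLikelihood(graph, records)

    def logpost(L: float) -> float:
        if not (prior.lo <= L <= prior.hi):
            return -np.inf
        return lik.total_loglik(L) + prior.logpdf(L)

    return _fit_scalar(logpost, prior.lo, prior.hi, config, rng)


# ---------------------------------------------------------------------------
# Hierarchical model


def _kde_mode(samples: np.ndarray, lo: float | None = None, hi: float | None = None,
              n_grid: int = 512) -> float:
    samples = np.asarray(samples, dtype=float)
    if samples.std() == 0:
        return float(samples[0])
    kde = gaussian_kde(samples)
    a = samples.min() if lo is None else max(lo, samples.min())
    b = samples.max() if hi is None else min(hi, samples.max())
    grid = np.linspace(a, b, n_grid)
    return float(grid[int(np.argmax(kde(grid)))])


def _run_hier_chain(
    lik: ChoiceLikelihood,
    mu_start: float,
    hyperprior_mu: TruncNormPrior,
    hyperprior_sd: LogNormPrior,
    n_keep: int,
    config: MCMCConfig,
    rng: np.random.Generator,
    L_init: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Metropolis-within-Gibbs chain over (mu, sigma, L_1..L_n).

    Per sweep: all L_i are block-proposed by independent random walks and
    accepted componentwise (their full conditionals are independent given
    mu, sigma); mu is drawn exactly from its truncated-normal full
    conditional; log(sigma) takes a random-walk Metropolis step against its
    standard-normal prior.  Returns kept (mu, sigma, log-joint) vectors.
    """
    n = lik.n_records
    lo_w, hi_w = _L_WINDOW
    L = L_init.copy()
    mu = float(mu_start)
    sigma = math.exp(hyperprior_sd.mu)  # prior-median start
    ll_cur = lik.loglik_vector(np.clip(L, lo_w, hi_w))

    n_burn = max(n_keep // 2, 1)
    total = n_burn + n_keep
    mus = np.empty(n_keep)
    sigmas = np.empty(n_keep)
    logjoint = np.empty(n_keep)

    scale_L = 0.5
    scale_s = 0.25
    acc_L = 0
    acc_s = 0
    tune_every = min(config.tune_interval, max(n_burn // 4, 1))

    a_mu = hyperprior_mu
    for step in range(total):
        # --- L block (componentwise accept of a joint random-walk proposal)
        prop = L + scale_L * rng.normal(size=n)
        ll_prop = lik.loglik_vector(np.clip(prop, lo_w, hi_w))
        delta = (
            ll_prop - ll_cur
            + _norm_logpdf(prop, mu, sigma) - _norm_logpdf(L, mu, sigma)
        )
        accept = np.log(rng.uniform(size=n)) < delta
        L[accept] = prop[accept]
        ll_cur[accept] = ll_prop[accept]
        acc_L += accept.mean()

        # --- mu: exact draw from its truncated-normal full conditional
        prec = 1.0 / a_mu.sd**2 + n / sigma**2
        mean = (a_mu.mu / a_mu.sd**2 + L.sum() / sigma**2) / prec
        sd = math.sqrt(1.0 / prec)
        mu = _truncnorm_draw(rng, mean, sd, a_mu.lo, a_mu.hi)

        # --- log(sigma): random-walk Metropolis
        logsig = math.log(sigma)
        logsig_prop = logsig + scale_s * rng.normal()
        sig_prop = math.exp(logsig_prop)
        d = (
            float(_norm_logpdf(L, mu, sig_prop).sum() - _norm_logpdf(L, mu, sigma).sum())
            + hyperprior_sd.logpdf_of_log(logsig_prop)
            - hyperprior_sd.logpdf_of_log(logsig)
        )
        if math.log(rng.uniform()) < d:
            sigma = sig_prop
            acc_s += 1

        if step < n_burn and (step + 1) % tune_every == 0:
            scale_L *= math.exp(2.0 * (acc_L / tune_every - 0.3))
            rate_s = acc_s / tune_every
            scale_s *= math.exp(2.0 * (rate_s - 0.3))
            acc_L = 0
            acc_s = 0

        if step >= n_burn:
            k = step - n_burn
            mus[k] = mu
            sigmas[k] = sigma
            logjoint[k] = (
                ll_cur.sum()
                + float(_norm_logpdf(L, mu, sigma).sum())
                + a_mu.logpdf(mu)
                + hyperprior_sd.logpdf(sigma)
            )
    return mus, sigmas, logjoint


def fit_hierarchical(
    records: Sequence[ChoiceRecord],
    graph: Graph,
    hyperprior_mu: TruncNormPrior = TruncNormPrior(),
    hyperprior_sd: LogNormPrior = LogNormPrior(),
    config: MCMCConfig = MCMCConfig(),
    rng: np.random.Generator | None = None,
) -> PopulationFit:
    """Fit the individual-differences model: L_i ~ Normal(mu, sigma).

    mu carries the truncated-normal hyperprior and sigma the lognormal
    hyperprior; the population Gaussian itself is not truncated.  MAP values
    for mu and sigma are marginal KDE modes of the pooled converged samples;
    credible intervals are central 95% sample percentiles.
    """
    if len(records) < 2:
        raise ValueError("hierarchical model needs at least 2 records")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lik = ChoiceLikelihood(graph, records)

    # initialise each L_i at its likelihood argmax on a coarse grid so the
    # chains start in the bulk of the posterior regardless of mu's start
    grid = np.linspace(hyperprior_mu.lo, hyperprior_mu.hi, 201)
    ll_grid = np.stack([lik.loglik_scalar(g) for g in grid])  # (grid, n)
    L_init = grid[np.argmax(ll_grid, axis=0)]

    n_keep = max(config.n_samples // config.n_chains, 2)
    for attempt in range(config.max_extensions + 1):
        mu_chains, sig_chains, lp_chains = [], [], []
        for start in config.starts:
            sub = np.random.default_rng(rng.integers(2**63))
            mus, sigmas, lps = _run_hier_chain(
                lik, start, hyperprior_mu, hyperprior_sd, n_keep, config, sub, L_init
            )
            mu_chains.append(mus)
            sig_chains.append(sigmas)
            lp_chains.append(lps)
        rhat = max(
            gelman_rubin(mu_chains), gelman_rubin([np.log(s) for s in sig_chains])
        )
        if rhat < config.rhat_threshold:
            break
        n_keep *= 2
    converged = rhat < config.rhat_threshold

    mu_s = np.concatenate(mu_chains)
    sig_s = np.concatenate(sig_chains)
    return PopulationFit(
        mu_map=_kde_mode(mu_s),
        sigma_map=_kde_mode(sig_s),
        mu_ci=(float(np.percentile(mu_s, 2.5)), float(np.percentile(mu_s, 97.5))),
        sigma_ci=(float(np.percentile(sig_s, 2.5)), float(np.percentile(sig_s, 97.5))),
        mu_samples=mu_s,
        sigma_samples=sig_s,
        rhat=float(rhat),
        converged=bool(converged),
        message="" if converged else f"chains failed to converge (R-hat {rhat:.3f})",
    )


# ---------------------------------------------------------------------------
# Marginal likelihood and model comparison


def marginal_loglik(
    record: ChoiceRecord,
    graph: Graph,
    mu: float,
    sigma: float,
    method: str = "quad",
) -> float:
    """log integral of the two-choice likelihood against Normal(L; mu, sigma).

    ``method="quad"`` uses adaptive quadrature over [mu - 8 sigma, mu + 8 sigma]
    intersected with a wide numeric window; ``method="gauss"`` uses 101-node
    Gauss–Hermite quadrature (fast path used inside optimisation loops).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    lik = ChoiceLikelihood(graph, [record])
    return float(_marginal_loglik_many(lik, mu, sigma, method)[0])


def _marginal_loglik_many(
    lik: ChoiceLikelihood, mu: float, sigma: float, method: str = "gauss"
) -> np.ndarray:
    lo_w, hi_w = _L_WINDOW
    if sigma < 1e-8:
        return lik.loglik_scalar(float(np.clip(mu, lo_w, hi_w)))
    if method == "gauss":
        nodes, weights = np.polynomial.hermite_e.hermegauss(101)
        Ls = np.clip(mu + sigma * nodes, lo_w, hi_w)
        llm = np.stack([lik.loglik_scalar(L) for L in Ls])  # (nodes, n)
        logw = np.log(weights) - 0.5 * math.log(2 * math.pi)
        return logsumexp(llm + logw[:, None], axis=0)
    if method != "quad":
        raise ValueError(f"unknown method {method!r}")
    lo = max(mu - 8 * sigma, lo_w)
    hi = min(mu + 8 * sigma, hi_w)
    out = np.empty(lik.n_records)
    probe = np.linspace(lo, hi, 41)
    ll_probe = np.stack([lik.loglik_scalar(L) for L in probe])
    for i in range(lik.n_records):
        shift = float(ll_probe[:, i].max())

        def integrand(L: float, i=i, shift=shift) -> float:
            ll = float(lik.loglik_scalar(L)[i])
            return math.exp(ll - shift) * norm.pdf(L, mu, sigma)

        val, _ = integrate.quad(integrand, lo, hi, limit=200)
        out[i] = shift + math.log(max(val, 1e-300))
    return out


def aicc(loglik: float, k: int, n_obs: int) -> float:
    """Akaike Information Criterion with the finite-sample correction."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    if n_obs <= k + 1:
        raise ValueError("AICc requires n_obs > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def compare_models(
    records: Sequence[ChoiceRecord],
    graph: Graph,
    prior: TruncNormPrior = TruncNormPrior(),
    hyperprior_sd: LogNormPrior = LogNormPrior(),
    config: MCMCConfig = MCMCConfig(),
    rng: np.random.Generator | None = None,
) -> ModelComparison:
    """AICc comparison of the shared-L and individual-differences models.

    The shared model is scored at its maximised likelihood with k = 1.  The
    hierarchical model is scored at the (mu, sigma) maximising the summed
    per-participant marginal likelihood (participant effects integrated out)
    with k = 2.  n_obs counts both choices of every participant.
    """
    if not records:
        raise ValueError("records must be non-empty")
    lik = ChoiceLikelihood(graph, records)
    n_obs = 2 * len(records)
    lo, hi = prior.lo, prior.hi

    res = optimize.minimize_scalar(
        lambda L: -lik.total_loglik(L), bounds=(lo, hi), method="bounded"
    )
    ll_shared = -float(res.fun)

    def neg_marg(theta: np.ndarray) -> float:
        mu, logsig = theta
        return -float(_marginal_loglik_many(lik, mu, math.exp(logsig), "gauss").sum())

    best = None
    for mu0 in (0.0, float(res.x)):
        for logsig0 in (math.log(0.3), math.log(3.0)):
            r = optimize.minimize(
                neg_marg, x0=[mu0, logsig0], method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6},
            )
            if best is None or r.fun < best.fun:
                best = r
    ll_hier = -float(best.fun)

    return ModelComparison(
        aicc_shared=aicc(ll_shared, 1, n_obs),
        aicc_hier=aicc(ll_hier, 2, n_obs),
        n_obs=n_obs,
    )
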