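"""Hierarchical Poisson-lognormal dynamic spatial one-factor model.

Observation layer, for region i, year j, outcome k:

    Y_ij^(k) ~ Poisson(E_ij^(k) * lambda_ij^(k)),
    log lambda_ij^(k) = gamma_i^(k) * f_ij + eps_ij^(k),
    eps_ij^(k) ~ N(0, sigma_k^2),

where E_ij^(k) = P_ij * r^(k) is an expected count built from population and
a baseline-year statewide rate, so exp(log lambda) is a relative risk
against the baseline year.  Counts of one outcome may be interval-censored
(small-cell suppression, e.g. counts in [1, 5]), handled by summing the
Poisson pmf over the interval.

Latent layer: the factor field f_.j is ICAR in space with full-conditional
variance tau_f^2 / w_i+ and an AR(1)-in-time mean
mu~_ij = mu_j + eta (f_i,j-1 - mu_{j-1}); non-reference loadings
gamma^(k) are mean-one ICAR fields with shared variance tau_g^2 (or
scalars gamma^(k) ~ N(1, tau_g^2) in the spatially constant variant).
The reference outcome's loading is fixed at 1 for identifiability.

Priors: inverse-gamma(0.5, 0.5) on all variance components by default
(a Gamma(5, 2)-on-precision sensitivity alternative is available), flat
priors on the yearly intercepts mu_j, uniform(-1, 1) on eta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .graph import AdjacencyGraph

__all__ = [
    "ObservationData",
    "ModelState",
    "PriorSpec",
    "log_likelihood_obs",
    "log_prior_icar",
    "log_posterior",
    "DynamicSpatialFactorModel",
]


# ----------------------------------------------------------------------
# data container
# ----------------------------------------------------------------------
@dataclass
class ObservationData:
    """Rectangular (region x year x outcome) count data with offsets.

    ``counts`` holds observed values (NaN where censored or missing);
    ``censored`` flags interval-censored cells whose bounds live in
    ``cens_low``/``cens_high``; ``missing`` flags cells with no
    observation at all.  ``offsets`` are the expected counts E_ij^(k).
    """

    counts: np.ndarray  # (N, J, K) float, NaN at censored/missing cells
    offsets: np.ndarray  # (N, J, K) > 0
    populations: np.ndarray  # (N, J) > 0
    censored: np.ndarray | None = None  # (N, J, K) bool
    cens_low: np.ndarray | None = None  # (N, J, K) int, valid where censored
    cens_high: np.ndarray | None = None
    missing: np.ndarray | None = None  # (N, J, K) bool
    region_labels: Sequence[str] | None = None
    years: Sequence[int] | None = None
    outcome_labels: Sequence[str] | None = None
    reference_outcome: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a (regions, years, outcomes) array")
        shape = self.counts.shape
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.shape != shape:
            raise ValueError("offsets shape must match counts")
        if np.any(self.offsets <= 0):
            raise ValueError("offsets must be strictly positive")
        self.populations = np.asarray(self.populations, dtype=float)
        if self.populations.shape != shape[:2]:
            raise ValueError("populations must be (regions, years)")
        if np.any(self.populations <= 0):
            raise ValueError("populations must be strictly positive")
        for name in ("censored", "missing"):
            v = getattr(self, name)
            setattr(
                self,
                name,
                np.zeros(shape, dtype=bool) if v is None else np.asarray(v, dtype=bool),
            )
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape must match counts")
        if self.cens_low is None:
            self.cens_low = np.zeros(shape, dtype=np.int64)
        if self.cens_high is None:
            self.cens_high = np.zeros(shape, dtype=np.int64)
        self.cens_low = np.asarray(self.cens_low, dtype=np.int64)
        self.cens_high = np.asarray(self.cens_high, dtype=np.int64)

        observed = ~self.censored & ~self.missing
        vals = self.counts[observed]
        if np.any(np.isnan(vals)):
            raise ValueError("uncensored, non-missing cells must carry a count value")
        if np.any(vals < 0) or np.any(vals != np.round(vals)):
            raise ValueError("counts must be nonnegative integers")
        if np.any(~np.isnan(self.counts[self.censored])):
            raise ValueError("censored cells must carry an interval flag, not a value")
        cl, ch = self.cens_low[self.censored], self.cens_high[self.censored]
        if np.any(cl < 0) or np.any(cl > ch):
            raise ValueError("censoring bounds must satisfy 0 <= low <= high")

        N, J, K = shape
        if self.region_labels is None:
            self.region_labels = [str(i) for i in range(N)]
        if self.years is None:
            self.years = list(range(J))
        if self.outcome_labels is None:
            self.outcome_labels = [f"outcome_{k}" for k in range(K)]
        if not (0 <= self.reference_outcome < K):
            raise ValueError("reference_outcome out of range")

    @property
    def shape(self):
        return self.counts.shape

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]

    @property
    def n_years(self) -> int:
        return self.counts.shape[1]

    @property
    def n_outcomes(self) -> int:
        return self.counts.shape[2]


# ----------------------------------------------------------------------
# parameters / priors
# ----------------------------------------------------------------------
@dataclass
class ModelState:
    """All latent quantities of one MCMC iteration.

    ``log_rate`` is log lambda; the error field eps = log_rate -
    gamma_i^(k) f_ij is derived, not stored.  In the spatially constant
    variant ``gamma`` holds each scalar loading replicated across regions.
    """

    f: np.ndarray  # (N, J)
    gamma: np.ndarray  # (N, K), reference column == 1
    log_rate: np.ndarray  # (N, J, K)
    sigma2: np.ndarray  # (K,)
    tau_f2: float
    tau_g2: float
    mu: np.ndarray  # (J,)
    eta: float

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.log_rate = np.asarray(self.log_rate, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)

    def validate(self, reference_outcome: int = 0) -> None:
        if not np.allclose(self.gamma[:, reference_outcome], 1.0):
            raise ValueError("reference loading column must be fixed at 1")
        if np.any(self.sigma2 <= 0) or self.tau_f2 <= 0 or self.tau_g2 <= 0:
            raise ValueError("variance components must be positive")

    def linear_predictor(self) -> np.ndarray:
        """gamma_i^(k) f_ij, shape (N, J, K)."""
        return self.gamma[:, None, :] * self.f[:, :, None]

    def epsilon(self) -> np.ndarray:
        return self.log_rate - self.linear_predictor()

    def mu_tilde(self, j: int) -> np.ndarray:
        """AR(1)-adjusted ICAR prior mean of year j's factor field."""
        if j == 0:
            return np.full(self.f.shape[0], self.mu[0])
        return self.mu[j] + self.eta * (self.f[:, j - 1] - self.mu[j - 1])

    def copy(self) -> "ModelState":
        return ModelState(
            f=self.f.copy(),
            gamma=self.gamma.copy(),
            log_rate=self.log_rate.copy(),
            sigma2=self.sigma2.copy(),
            tau_f2=float(self.tau_f2),
            tau_g2=float(self.tau_g2),
            mu=self.mu.copy(),
            eta=float(self.eta),
        )


@dataclass
class PriorSpec:
    """Prior hyperparameters.

    Variance components get inverse-gamma(shape, scale) priors; the
    default IG(0.5, 0.5) corresponds to a Gamma(0.5, rate 0.5) prior on
    the precision.  ``gamma_precision_sensitivity`` switches to a
    Gamma(5, rate 2) precision prior, i.e. IG(5, 2) on the variance.
    Yearly intercepts are flat on the reals; eta is uniform on
    ``eta_bounds``.
    """

    sigma2_shape: float = 0.5
    sigma2_scale: float = 0.5
    tau_f2_shape: float = 0.5
    tau_f2_scale: float = 0.5
    tau_g2_shape: float = 0.5
    tau_g2_scale: float = 0.5
    eta_bounds: tuple = (-1.0, 1.0)

    def __post_init__(self):
        for name in (
            "sigma2_shape",
            "sigma2_scale",
            "tau_f2_shape",
            "tau_f2_scale",
            "tau_g2_shape",
            "tau_g2_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.eta_bounds
        if not lo < hi:
            raise ValueError("eta_bounds must be an ordered interval")

    @classmethod
    def default(cls) -> "PriorSpec":
        return cls()

    @classmethod
    def gamma_precision_sensitivity(cls) -> "PriorSpec":
        """Sensitivity alternative: precision ~ Gamma(5, rate 2) on all variances."""
        return cls(
            sigma2_shape=5.0,
            sigma2_scale=2.0,
            tau_f2_shape=5.0,
            tau_f2_scale=2.0,
            tau_g2_shape=5.0,
            tau_g2_scale=2.0,
        )

    def log_invgamma(self, x: float, shape: float, scale: float) -> float:
        if x <= 0:
            return -np.inf
        return float(stats.invgamma.logpdf(x, shape, scale=scale))

    def log_eta(self, eta: float) -> float:
        lo, hi = self.eta_bounds
        return 0.0 if lo <= eta <= hi else -np.inf


# ----------------------------------------------------------------------
# log-density components
# ----------------------------------------------------------------------
def log_likelihood_obs(count_or_interval, offset: float, log_rate: float) -> float:
    """Observation log-likelihood of one cell.

    ``count_or_interval`` is either a nonnegative integer count or an
    ``(a, b)`` inclusive interval for a censored cell, in which case the
    likelihood is log sum_{y=a}^{b} Poisson(y; m) with m = offset *
    exp(log_rate), computed via log-sum-exp.  ``b = inf`` is allowed.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    m = offset * np.exp(log_rate)
    if np.ndim(count_or_interval) == 0:
        y = count_or_interval
        if y < 0:
            raise ValueError("count must be nonnegative")
        return float(stats.poisson.logpmf(y, m))
    a, b = count_or_interval
    if a < 0 or a > b:
        raise ValueError("censoring interval must satisfy 0 <= a <= b")
    if np.isinf(b):
        return float(stats.poisson.logsf(a - 1, m))
    ys = np.arange(int(a), int(b) + 1)
    return float(special.logsumexp(stats.poisson.logpmf(ys, m)))


def log_prior_icar(
    values: np.ndarray, prior_means: np.ndarray, tau2: float, graph: AdjacencyGraph
) -> float:
    """Unnormalized joint ICAR log-density in pairwise-difference form.

    -((N - c)/2) log tau2 - (1/(2 tau2)) sum_{i<l} w_il (d_i - d_l)^2,
    with d = values - prior_means and c the number of connected
    components (the standard rank correction for the improper ICAR).
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    values = np.asarray(values, dtype=float)
    prior_means = np.asarray(prior_means, dtype=float)
    d = values - prior_means
    quad = 0.0
    for (i, l) in graph.edges:
        quad += (d[i] - d[l]) ** 2
    rank = graph.n_regions - graph.n_components
    return -0.5 * rank * np.log(tau2) - quad / (2.0 * tau2)


def _cell_loglik_terms(data: ObservationData, log_rate: np.ndarray) -> float:
    """Poisson/censored observation log-likelihood summed over all cells."""
    m = data.offsets * np.exp(np.clip(log_rate, -700, 700))
    total = 0.0
    obs = ~data.censored & ~data.missing
    if np.any(obs):
        y = data.counts[obs]
        mo = m[obs]
        total += float(np.sum(y * np.log(np.maximum(mo, 1e-300)) - mo - special.gammaln(y + 1.0)))
    if np.any(data.censored):
        idx = np.nonzero(data.censored)
        for i, j, k in zip(*idx):
            lo, hi = data.cens_low[i, j, k], data.cens_high[i, j, k]
            ys = np.arange(lo, hi + 1)
            mc = m[i, j, k]
            terms = ys * np.log(max(mc, 1e-300)) - mc - special.gammaln(ys + 1.0)
            total += float(special.logsumexp(terms))
    return total


def log_posterior(
    state: ModelState,
    data: ObservationData,
    priors: PriorSpec,
    graph: AdjacencyGraph,
    loadings_mode: str = "varying",
) -> float:
    """Joint log-posterior (up to a constant) of the full model.

    Sum of: observation likelihood; Gaussian error layer of log_rate
    around gamma*f; per-year factor ICAR priors with AR(1)-adjusted
    means; mean-one ICAR (or N(1, tau_g2)) priors on non-reference
    loadings; inverse-gamma priors on variances; the eta prior.  Flat
    mu_j priors contribute nothing.
    """
    state.validate(data.reference_outcome)
    N, J, K = data.shape
    total = _cell_loglik_terms(data, state.log_rate)

    eps = state.epsilon()
    total += float(
        -0.5 * N * J * np.sum(np.log(2 * np.pi * state.sigma2))
        - np.sum(eps**2 / (2.0 * state.sigma2)[None, None, :])
    )

    for j in range(J):
        total += log_prior_icar(state.f[:, j], state.mu_tilde(j), state.tau_f2, graph)

    ref = data.reference_outcome
    ones = np.ones(N)
    for k in range(K):
        if k == ref:
            continue
        if loadings_mode == "constant":
            # spatially constant variant: scalar gamma^(k) ~ N(1, tau_g2)
            g = state.gamma[0, k]
            total += float(stats.norm.logpdf(g, loc=1.0, scale=np.sqrt(state.tau_g2)))
        else:
            total += log_prior_icar(state.gamma[:, k], ones, state.tau_g2, graph)

    for k in range(K):
        total += priors.log_invgamma(state.sigma2[k], priors.sigma2_shape, priors.sigma2_scale)
    total += priors.log_invgamma(state.tau_f2, priors.tau_f2_shape, priors.tau_f2_scale)
    total += priors.log_invgamma(state.tau_g2, priors.tau_g2_shape, priors.tau_g2_scale)
    total += priors.log_eta(state.eta)
    return float(total)


# ----------------------------------------------------------------------
# model object
# ----------------------------------------------------------------------
class DynamicSpatialFactorModel:
    """Bayesian dynamic spatial one-factor model for areal count outcomes.

    Parameters
    ----------
    data : ObservationData
        Counts, censoring flags and offsets on a (region, year, outcome)
        grid.
    graph : AdjacencyGraph
        Areal adjacency shared by the factor and loadings ICAR priors.
    priors : PriorSpec, optional
        Hyperparameters; defaults to the weakly informative IG(0.5, 0.5)
        setup.
    loadings_mode : {"varying", "constant"}
        Spatially varying (ICAR) or spatially constant (scalar) loadings.

    ``fit`` runs the Metropolis-within-Gibbs sampler and returns a
    :class:`~spatialfactor.results.DynamicSpatialFactorResults`.
    """

    def __init__(
        self,
        data: ObservationData,
        graph: AdjacencyGraph,
        priors: PriorSpec | None = None,
        loadings_mode: str = "varying",
    ):
        if graph.n_regions != data.n_regions:
            raise ValueError("graph and data disagree on the number of regions")
        if loadings_mode not in ("varying", "constant"):
            raise ValueError("loadings_mode must be 'varying' or 'constant'")
        if not graph.is_connected:
            import warnings

            warnings.warn(
                f"adjacency graph has {graph.n_components} connected components; "
                "ICAR rank corrections use the component count",
                stacklevel=2,
            )
        self.data = data
        self.graph = graph
        self.priors = priors if priors is not None else PriorSpec.default()
        self.loadings_mode = loadings_mode

    @classmethod
    def from_dataframe(
        cls,
        frame,
        graph: AdjacencyGraph,
        priors: PriorSpec | None = None,
        loadings_mode: str = "varying",
        reference_outcome=None,
    ) -> "DynamicSpatialFactorModel":
        """Build from the long-format observation table (see io module)."""
        from .io import observation_data_from_frame

        data = observation_data_from_frame(
            frame, region_order=list(graph.labels), reference_outcome=reference_outcome
        )
        return cls(data, graph, priors=priors, loadings_mode=loadings_mode)

    def log_posterior(self, state: ModelState) -> float:
        return log_posterior(state, self.data, self.priors, self.graph, self.loadings_mode)

    def initial_state(self) -> ModelState:
        """Cheap in-support starting point.

        log_rate at log((count + 1/2)/offset) with censored cells at the
        interval midpoint and missing cells at the offset; f and mu at 0,
        loadings at 1, variances at 1, eta at 0.
        """
        d = self.data
        proxy = np.where(np.isnan(d.counts), 0.0, d.counts)
        proxy = np.where(d.censored, (d.cens_low + d.cens_high) / 2.0, proxy)
        proxy = np.where(d.missing, d.offsets, proxy)
        log_rate = np.log((proxy + 0.5) / d.offsets)
        N, J, K = d.shape
        return ModelState(
            f=np.zeros((N, J)),
            gamma=np.ones((N, K)),
            log_rate=log_rate,
            sigma2=np.ones(K),
            tau_f2=1.0,
            tau_g2=1.0,
            mu=np.zeros(J),
            eta=0.0,
        )

    def fit(
        self,
        n_iterations: int = 1_000_000,
        n_burnin: int = 500_000,
        thin: int = 50,
        n_chains: int = 2,
        seed: int = 0,
        store_log_rate: bool = True,
        prior_only: bool = False,
        constrain_loading_level: bool = True,
        progress: bool = False,
    ):
        """Run the Metropolis-within-Gibbs sampler.

        Defaults mirror the reference analysis (10^6 iterations, half
        discarded as burn-in, thinning interval 50, two chains); scale
        these down for exploratory work.
        """
        from .mcmc import MCMCConfig, run_mcmc
        from .results import DynamicSpatialFactorResults

        config = MCMCConfig(
            n_iterations=n_iterations,
            n_burnin=n_burnin,
            thin=thin,
            n_chains=n_chains,
            seed=seed,
            loadings_mode=self.loadings_mode,
            constrain_loading_level=constrain_loading_level,
            store_log_rate=store_log_rate,
            prior_only=prior_only,
            progress=progress,
        )
        chains = run_mcmc(self.data, self.graph, self.priors, config)
        return DynamicSpatialFactorResults(self, chains)
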