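"""Synthetic data from the generative model of the factor analysis.

Generates complete datasets — latent factor fields, loading fields,
log-rates and interval-censored Poisson counts — so that every
downstream stage (likelihoods, sampler, postprocessing) can be exercised
and calibrated without surveillance data.

ICAR fields are drawn jointly rather than by Gibbs sweeps: deviations
come from N(0, tau^2 Q^+) supported on the sum-to-zero subspace (the
standard proper representative of the improper ICAR), then shifted by
the stated mean.  This keeps the yearly intercepts mu_j and the mean-one
loading anchor identified in simulation.

The default configuration is a desk-scale replica of a
100-county / 5-year / 6-outcome surveillance panel: a 5 x 6 queen
lattice (N = 30), J = 5 years, K = 3 outcomes, lognormal county
populations around 50k, baseline rates spanning treatment-like (2e-3)
to death-like (2e-4) magnitudes, and small-cell suppression of the
reference outcome's counts on [1, 5].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .graph import AdjacencyGraph, generate_lattice
from .model import ModelState, ObservationData

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "default_config",
    "simulate_factors",
    "simulate_loadings",
    "compute_expected_counts",
    "simulate_counts",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Generative-model settings for one synthetic dataset."""

    graph: AdjacencyGraph
    n_years: int = 5
    n_outcomes: int = 3
    mu: np.ndarray | None = None  # yearly factor intercepts, length J
    eta: float = 0.5  # AR(1) coefficient, |eta| <= 1
    tau_f2: float = 0.5  # factor ICAR variance
    tau_g2: float = 0.25  # loadings ICAR variance
    sigma2: np.ndarray | None = None  # per-outcome error variances
    populations: np.ndarray | None = None  # (N, J) > 0
    baseline_rates: np.ndarray | None = None  # per-outcome r^(k) > 0
    censor_outcome: int | None = 0  # index of the suppressed outcome, or None
    censor_bounds: tuple = (1, 5)  # inclusive integer interval
    mean_ceiling: float = 1e9  # overflow guard on E * lambda
    seed: int = 0

    def __post_init__(self):
        N, J, K = self.graph.n_regions, self.n_years, self.n_outcomes
        if J < 1 or K < 2:
            raise ValueError("need J >= 1 years and K >= 2 outcomes")
        if not abs(self.eta) <= 1:
            raise ValueError("|eta| must be <= 1")
        if self.tau_f2 <= 0 or self.tau_g2 <= 0:
            raise ValueError("ICAR variances must be positive")
        rng = np.random.default_rng(self.seed)
        if self.mu is None:
            # gentle upward trend in the latent factor across years
            self.mu = np.linspace(0.0, 0.4, J)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (J,):
            raise ValueError("mu must have length n_years")
        if self.sigma2 is None:
            self.sigma2 = np.full(K, 0.05)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.sigma2.shape != (K,) or np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be K positive variances")
        if self.populations is None:
            # lognormal county-like populations, constant over years
            pop = np.exp(rng.normal(np.log(5e4), 0.6, size=N))
            self.populations = np.tile(pop[:, None], (1, J))
        self.populations = np.asarray(self.populations, dtype=float)
        if self.populations.shape != (N, J) or np.any(self.populations <= 0):
            raise ValueError("populations must be positive with shape (N, J)")
        if self.baseline_rates is None:
            # treatment-like rate for the reference outcome, then smaller
            base = np.array([2e-3, 2e-4, 5e-4, 1e-3, 3e-4, 5e-5])
            self.baseline_rates = base[:K] if K <= 6 else np.full(K, 5e-4)
        self.baseline_rates = np.asarray(self.baseline_rates, dtype=float)
        if self.baseline_rates.shape != (K,) or np.any(self.baseline_rates <= 0):
            raise ValueError("baseline_rates must be K positive rates")
        lo, hi = self.censor_bounds
        if not (float(lo).is_integer() and float(hi).is_integer() and 0 <= lo <= hi):
            raise ValueError("censor bounds must be ordered integers >= 0")
        if self.censor_outcome is not None and not 0 <= self.censor_outcome < K:
            raise ValueError("censor_outcome out of range")

    @property
    def offsets(self) -> np.ndarray:
        """Expected counts E_ij^(k) = P_ij * r^(k), shape (N, J, K)."""
        return self.populations[:, :, None] * self.baseline_rates[None, None, :]


@dataclass
class SyntheticDataset:
    """A generated dataset plus the latent truth that produced it."""

    true_state: ModelState
    observations: ObservationData
    config: SimulationConfig


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale default: 5 x 6 queen lattice, J=5 years, K=3 outcomes."""
    cfg = SimulationConfig(graph=generate_lattice(5, 6, "queen"), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def simulate_factors(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the (N, J) latent factor field.

    Year 1 is an ICAR draw centred at mu_1; year j >= 2 is an ICAR draw
    centred at mu~_ij = mu_j + eta (f_i,j-1 - mu_{j-1}).  Deviations are
    joint sum-to-zero ICAR draws with variance parameter tau_f2.
    """
    if not config.graph.is_connected:
        raise ValueError("factor simulation requires a connected graph")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, J = config.graph.n_regions, config.n_years
    f = np.empty((N, J))
    for j in range(J):
        if j == 0:
            center = np.full(N, config.mu[0])
        else:
            center = config.mu[j] + config.eta * (f[:, j - 1] - config.mu[j - 1])
        f[:, j] = center + config.graph.draw_icar(config.tau_f2, rng)
    return f


def simulate_loadings(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the (N, K) loading field.

    The reference outcome's column is identically 1; each other column is
    an independent mean-one sum-to-zero ICAR draw with variance tau_g2.
    """
    if not config.graph.is_connected:
        raise ValueError("loading simulation requires a connected graph")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, K = config.graph.n_regions, config.n_outcomes
    ref = config.censor_outcome if config.censor_outcome is not None else 0
    gamma = np.empty((N, K))
    for k in range(K):
        if k == ref:
            gamma[:, k] = 1.0
        else:
            gamma[:, k] = 1.0 + config.graph.draw_icar(config.tau_g2, rng)
    return gamma


def compute_expected_counts(
    populations: np.ndarray, baseline_counts: np.ndarray
) -> tuple:
    """Offsets from observed baseline-year counts.

    ``r^(k) = sum_i Y_i,baseline^(k) / sum_i P_i,baseline`` and
    ``E_ij^(k) = P_ij * r^(k)``.  ``populations`` is (N, J) with year 0
    the baseline year; ``baseline_counts`` is (N, K).  Returns
    ``(rates (K,), offsets (N, J, K))``.
    """
    populations = np.asarray(populations, dtype=float)
    baseline_counts = np.asarray(baseline_counts, dtype=float)
    if np.any(populations <= 0):
        raise ValueError("populations must be positive")
    total_pop = populations[:, 0].sum()
    totals = baseline_counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("zero total baseline count for some outcome; offset would be 0")
    rates = totals / total_pop
    offsets = populations[:, :, None] * rates[None, None, :]
    return rates, offsets


def simulate_counts(
    config: SimulationConfig,
    factors: np.ndarray,
    loadings: np.ndarray,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Draw counts given latent fields and apply interval censoring.

    eps_ij^(k) ~ N(0, sigma_k^2) independently; Y_ij^(k) ~ Poisson(E *
    exp(gamma f + eps)); counts of the censored outcome inside the
    inclusive censor interval are replaced by an interval flag.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, J, K = config.graph.n_regions, config.n_years, config.n_outcomes
    factors = np.asarray(factors, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    if factors.shape != (N, J) or loadings.shape != (N, K):
        raise ValueError("factor/loading dimensions inconsistent with config")
    eps = rng.normal(0.0, np.sqrt(config.sigma2)[None, None, :], size=(N, J, K))
    log_rate = loadings[:, None, :] * factors[:, :, None] + eps
    E = config.offsets
    mean = E * np.exp(log_rate)
    if np.any(mean > config.mean_ceiling):
        raise ValueError(
            f"Poisson mean exceeds overflow ceiling {config.mean_ceiling:g}; "
            "check simulation parameters"
        )
    counts = rng.poisson(mean).astype(float)

    censored = np.zeros((N, J, K), dtype=bool)
    cens_low = np.zeros((N, J, K), dtype=np.int64)
    cens_high = np.zeros((N, J, K), dtype=np.int64)
    if config.censor_outcome is not None:
        lo, hi = int(config.censor_bounds[0]), int(config.censor_bounds[1])
        k = config.censor_outcome
        hit = (counts[:, :, k] >= lo) & (counts[:, :, k] <= hi)
        censored[:, :, k] = hit
        cens_low[:, :, k] = lo
        cens_high[:, :, k] = hi
        counts[:, :, k] = np.where(hit, np.nan, counts[:, :, k])

    ref = config.censor_outcome if config.censor_outcome is not None else 0
    obs = ObservationData(
        counts=counts,
        offsets=E,
        populations=config.populations,
        censored=censored,
        cens_low=cens_low,
        cens_high=cens_high,
        region_labels=list(config.graph.labels),
        years=list(range(J)),
        outcome_labels=[f"outcome_{k}" for k in range(K)],
        reference_outcome=ref,
    )
    truth = ModelState(
        f=factors,
        gamma=loadings,
        log_rate=log_rate,
        sigma2=config.sigma2.copy(),
        tau_f2=config.tau_f2,
        tau_g2=config.tau_g2,
        mu=config.mu.copy(),
        eta=config.eta,
    )
    return SyntheticDataset(true_state=truth, observations=obs, config=config)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full pipeline: factors, loadings, counts — reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    factors = simulate_factors(config, rng)
    loadings = simulate_loadings(config, rng)
    return simulate_counts(config, factors, loadings, rng)
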