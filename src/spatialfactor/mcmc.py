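"""Metropolis-within-Gibbs sampler for the dynamic spatial factor model.

One sweep updates, in order:

(a) every latent log-rate cell by adaptive random-walk Metropolis against
    the Poisson / interval-censored likelihood plus its Gaussian error
    layer (in prior-only mode the Poisson term is dropped and the cell is
    drawn exactly from the Gaussian layer);
(b) the factor field year by year from its exact Gaussian full
    conditional (the error layer and the ICAR/AR structure are jointly
    Gaussian given the log-rates and loadings), followed by a forward
    recentring sweep that absorbs each year's mean deviation into mu_j —
    mu_j carries no density information under the pairwise-difference
    ICAR (Q 1 = 0), so this moves the state along an exact flat direction
    and identifies mu_j as the level of the factor field;
(c) the loading columns from their Gaussian full conditionals (scalar
    loadings in the spatially constant variant);
(d) the three variance groups from conjugate inverse-gamma conditionals,
    with the (N - c) rank correction for each ICAR field;
(e) eta by adaptive random-walk Metropolis restricted to its prior
    support.

Proposal scales adapt toward a 0.44 per-site acceptance rate during
burn-in and are frozen afterwards, preserving ergodicity.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg, special

from .graph import AdjacencyGraph
from .model import ModelState, ObservationData, PriorSpec

__all__ = ["MCMCConfig", "PosteriorChains", "run_mcmc", "fit_constant_variant", "gelman_rubin"]

_TARGET_ACCEPT = 0.44
_ADAPT_BATCH = 50


@dataclass
class MCMCConfig:
    """Sampler settings.

    Defaults mirror the reference analysis (10^6 iterations, 5*10^5
    burn-in, thinning 50, two chains); tests and desk-scale runs override
    them.
    """

    n_iterations: int = 1_000_000
    n_burnin: int = 500_000
    thin: int = 50
    n_chains: int = 2
    seed: int = 0
    loadings_mode: str = "varying"
    constrain_loading_level: bool = True
    initial_scale: float = 0.5
    store_log_rate: bool = True
    prior_only: bool = False
    progress: bool = False

    def __post_init__(self):
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("need 0 <= n_burnin < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.loadings_mode not in ("varying", "constant"):
            raise ValueError("loadings_mode must be 'varying' or 'constant'")

    @property
    def n_stored(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass
class PosteriorChains:
    """Thinned multi-chain draws of every model component.

    ``draws[name]`` has shape ``(n_chains, n_stored, *component_shape)``.
    """

    draws: dict
    config: MCMCConfig
    acceptance: dict
    chain_seeds: list
    runtime_seconds: float = 0.0
    region_labels: list = field(default_factory=list)
    outcome_labels: list = field(default_factory=list)
    years: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_stored(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains, shape (n_chains * n_stored, ...)."""
        arr = self.draws[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])


# ----------------------------------------------------------------------
# internals
# ----------------------------------------------------------------------
class _ChainRunner:
    def __init__(
        self,
        data: ObservationData,
        graph: AdjacencyGraph,
        priors: PriorSpec,
        config: MCMCConfig,
    ):
        self.data = data
        self.graph = graph
        self.priors = priors
        self.config = config
        self.N, self.J, self.K = data.shape
        self.ref = data.reference_outcome
        self.Q = graph.icar_precision()
        self.icar_rank = graph.n_regions - graph.n_components

        self.obs = ~data.censored & ~data.missing
        self.y = np.where(self.obs, np.nan_to_num(data.counts), 0.0)
        self.E = data.offsets
        ci = np.nonzero(data.censored)
        self.cens_idx = ci
        if ci[0].size:
            lo = data.cens_low[ci]
            hi = data.cens_high[ci]
            width = int((hi - lo).max()) + 1
            ys = lo[:, None] + np.arange(width)[None, :]
            self.cens_ys = ys.astype(float)
            self.cens_mask = ys <= hi[:, None]
            self.cens_lgamma = special.gammaln(self.cens_ys + 1.0)
        else:
            self.cens_ys = None

    # Poisson(-censored) log-likelihood per cell as a function of the
    # Poisson mean array m = E * exp(log_rate); constants in y are kept so
    # deltas are exact.
    def _pois_loglik(self, log_rate: np.ndarray) -> np.ndarray:
        ll = np.clip(log_rate, -700.0, 700.0)
        m = self.E * np.exp(ll)
        out = np.where(self.obs, self.y * (np.log(self.E) + ll) - m, 0.0)
        out -= np.where(self.obs, special.gammaln(self.y + 1.0), 0.0)
        if self.cens_ys is not None:
            mc = m[self.cens_idx]
            logm = np.log(np.maximum(mc, 1e-300))
            terms = -mc[:, None] + self.cens_ys * logm[:, None] - self.cens_lgamma
            terms = np.where(self.cens_mask, terms, -np.inf)
            out[self.cens_idx] = special.logsumexp(terms, axis=1)
        return out

    def run(self, seed: int, init: ModelState | None = None) -> dict:
        cfg = self.config
        rng = np.random.default_rng(seed)
        N, J, K = self.N, self.J, self.K
        Q = self.Q
        prior_only = cfg.prior_only

        if init is None:
            from .model import DynamicSpatialFactorModel

            model = DynamicSpatialFactorModel(
                self.data, self.graph, self.priors, cfg.loadings_mode
            )
            state = model.initial_state()
        else:
            state = init.copy()

        f = state.f
        gamma = state.gamma
        ll = state.log_rate.copy()
        sigma2 = state.sigma2.copy()
        tau_f2 = float(state.tau_f2)
        tau_g2 = float(state.tau_g2)
        mu = state.mu.copy()
        eta = float(state.eta)

        if not prior_only:
            pois = self._pois_loglik(ll)
            if not np.all(np.isfinite(pois)):
                raise RuntimeError(
                    "non-finite observation log-likelihood at initialization; "
                    f"offending cells: {np.argwhere(~np.isfinite(pois))[:5].tolist()}"
                )

        log_scale = np.full((N, J, K), np.log(cfg.initial_scale))
        eta_log_scale = np.log(0.2)
        acc_ll = np.zeros((N, J, K))
        batch_acc_ll = np.zeros((N, J, K))
        acc_eta = 0.0
        batch_acc_eta = 0.0
        n_eta_props = 0
        adapt_count = 0

        n_stored = cfg.n_stored
        store = {
            "factor": np.empty((n_stored, N, J)),
            "loadings": np.empty((n_stored, N, K)),
            "sigma2": np.empty((n_stored, K)),
            "tau_f2": np.empty(n_stored),
            "tau_g2": np.empty(n_stored),
            "mu": np.empty((n_stored, J)),
            "eta": np.empty(n_stored),
        }
        if cfg.store_log_rate:
            store["log_rate"] = np.empty((n_stored, N, J, K))

        a_sig, b_sig = self.priors.sigma2_shape, self.priors.sigma2_scale
        a_tf, b_tf = self.priors.tau_f2_shape, self.priors.tau_f2_scale
        a_tg, b_tg = self.priors.tau_g2_shape, self.priors.tau_g2_scale
        eta_lo, eta_hi = self.priors.eta_bounds
        ref = self.ref
        nonref = [k for k in range(K) if k != ref]

        M = gamma[:, None, :] * f[:, :, None]
        stored = 0
        for it in range(cfg.n_iterations):
            # ---- (a) log-rate cells -----------------------------------
            if prior_only:
                ll = M + np.sqrt(sigma2)[None, None, :] * rng.standard_normal((N, J, K))
            else:
                scale = np.exp(log_scale)
                prop = ll + scale * rng.standard_normal((N, J, K))
                d_pois = self._pois_loglik(prop) - self._pois_loglik(ll)
                d_gauss = ((ll - M) ** 2 - (prop - M) ** 2) / (2.0 * sigma2)[None, None, :]
                accept = np.log(rng.random((N, J, K))) < d_pois + d_gauss
                ll = np.where(accept, prop, ll)
                batch_acc_ll += accept
                acc_ll += accept

            # ---- (b) factor field, year by year -----------------------
            c_lik = (gamma**2 / sigma2[None, :]).sum(axis=1)  # (N,)
            for j in range(J):
                mu_t = mu[j] + (eta * (f[:, j - 1] - mu[j - 1]) if j > 0 else 0.0)
                mult = (1.0 + (eta**2 if j < J - 1 else 0.0)) / tau_f2
                A = mult * Q + np.diag(c_lik)
                b = (gamma / sigma2[None, :] * ll[:, j, :]).sum(axis=1)
                b = b + Q @ (np.full(N, mu[j]) if j == 0 else mu_t) / tau_f2
                if j < J - 1:
                    a_next = f[:, j + 1] - mu[j + 1] + eta * mu[j]
                    b = b + (eta / tau_f2) * (Q @ a_next)
                L = np.linalg.cholesky(A)
                mean = linalg.cho_solve((L, True), b)
                z = rng.standard_normal(N)
                f[:, j] = mean + linalg.solve_triangular(L, z, lower=True, trans="T")

            # recenter: absorb each year's mean deviation into mu_j
            # (density-invariant; identifies mu_j as the factor level)
            for j in range(J):
                mu_t = mu[j] + (eta * (f[:, j - 1] - mu[j - 1]) if j > 0 else 0.0)
                mu[j] += float(np.mean(f[:, j] - mu_t))

            # ---- (c) loadings ------------------------------------------
            f2w = (f**2).sum(axis=1)  # (N,)
            if cfg.loadings_mode == "varying":
                for k in nonref:
                    A = Q / tau_g2 + np.diag(f2w / sigma2[k])
                    b = (f * ll[:, :, k]).sum(axis=1) / sigma2[k]
                    L = np.linalg.cholesky(A)
                    mean = linalg.cho_solve((L, True), b)
                    z = rng.standard_normal(N)
                    draw = mean + linalg.solve_triangular(L, z, lower=True, trans="T")
                    if cfg.constrain_loading_level:
                        # condition the Gaussian draw on the mean-one anchor
                        # 1'gamma = N (proper representative of the mean-one
                        # ICAR; matches the generative model exactly)
                        s = linalg.cho_solve((L, True), np.ones(N))
                        draw = draw + s * (N - draw.sum()) / s.sum()
                    gamma[:, k] = draw
            else:
                tot_f2 = f2w.sum()
                for k in nonref:
                    prec = 1.0 / tau_g2 + tot_f2 / sigma2[k]
                    mean = (1.0 / tau_g2 + (f * ll[:, :, k]).sum() / sigma2[k]) / prec
                    gamma[:, k] = mean + rng.standard_normal() / np.sqrt(prec)
            M = gamma[:, None, :] * f[:, :, None]

            # ---- (d) variance components -------------------------------
            eps2 = (ll - M) ** 2
            ss_k = eps2.sum(axis=(0, 1))
            sigma2 = (b_sig + 0.5 * ss_k) / rng.gamma(a_sig + 0.5 * N * J, 1.0, size=K)

            quad_f = 0.0
            for j in range(J):
                mu_t = mu[j] + (eta * (f[:, j - 1] - mu[j - 1]) if j > 0 else 0.0)
                u = f[:, j] - mu_t
                quad_f += float(u @ Q @ u)
            tau_f2 = (b_tf + 0.5 * quad_f) / rng.gamma(a_tf + 0.5 * J * self.icar_rank, 1.0)

            if cfg.loadings_mode == "varying":
                quad_g = 0.0
                for k in nonref:
                    d = gamma[:, k] - 1.0
                    quad_g += float(d @ Q @ d)
                tau_g2 = (b_tg + 0.5 * quad_g) / rng.gamma(
                    a_tg + 0.5 * len(nonref) * self.icar_rank, 1.0
                )
            else:
                quad_g = float(sum((gamma[0, k] - 1.0) ** 2 for k in nonref))
                tau_g2 = (b_tg + 0.5 * quad_g) / rng.gamma(a_tg + 0.5 * len(nonref), 1.0)

            # ---- (e) eta ----------------------------------------------
            if J > 1:
                u_prev = f[:, :-1] - mu[None, :-1]
                u_cur = f[:, 1:] - mu[None, 1:]
                Qup = Q @ u_prev
                A2 = float(np.sum(u_prev * Qup))
                A1 = float(np.sum(u_cur * Qup))
                A0 = float(np.sum(u_cur * (Q @ u_cur)))

                def eta_logtarget(e):
                    return -(A0 - 2.0 * e * A1 + e * e * A2) / (2.0 * tau_f2)

                prop_eta = eta + np.exp(eta_log_scale) * rng.standard_normal()
                n_eta_props += 1
                if eta_lo <= prop_eta <= eta_hi:
                    if np.log(rng.random()) < eta_logtarget(prop_eta) - eta_logtarget(eta):
                        eta = float(prop_eta)
                        acc_eta += 1
                        batch_acc_eta += 1

            # ---- adaptation (burn-in only) -----------------------------
            if it < cfg.n_burnin and (it + 1) % _ADAPT_BATCH == 0:
                adapt_count += 1
                delta = min(0.1, 1.0 / np.sqrt(adapt_count))
                rate = batch_acc_ll / _ADAPT_BATCH
                log_scale += np.where(rate > _TARGET_ACCEPT, delta, -delta)
                batch_acc_ll[:] = 0.0
                if J > 1:
                    eta_rate = batch_acc_eta / _ADAPT_BATCH
                    eta_log_scale += delta if eta_rate > _TARGET_ACCEPT else -delta
                    batch_acc_eta = 0.0

            # ---- storage ----------------------------------------------
            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                if stored < n_stored:
                    store["factor"][stored] = f
                    store["loadings"][stored] = gamma
                    store["sigma2"][stored] = sigma2
                    store["tau_f2"][stored] = tau_f2
                    store["tau_g2"][stored] = tau_g2
                    store["mu"][stored] = mu
                    store["eta"][stored] = eta
                    if cfg.store_log_rate:
                        store["log_rate"][stored] = ll
                    stored += 1

        store["_acc_log_rate"] = acc_ll.sum() / (cfg.n_iterations * N * J * K)
        store["_acc_eta"] = acc_eta / max(n_eta_props, 1)
        return store


def run_mcmc(
    data: ObservationData,
    graph: AdjacencyGraph,
    priors: PriorSpec,
    config: MCMCConfig,
    init: ModelState | None = None,
    on_chain_complete: Callable[[int, dict], None] | None = None,
) -> PosteriorChains:
    """Run ``config.n_chains`` independent chains and collect thinned draws."""
    runner = _ChainRunner(data, graph, priors, config)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(config.seed).spawn(config.n_chains)]
    t0 = time.time()
    per_chain = []
    for c, s in enumerate(seeds):
        out = runner.run(s, init=init)
        per_chain.append(out)
        if on_chain_complete is not None:
            on_chain_complete(c, out)
        if config.progress:
            print(f"chain {c + 1}/{config.n_chains} done ({time.time() - t0:.1f}s)")
    names = [k for k in per_chain[0] if not k.startswith("_")]
    draws = {name: np.stack([out[name] for out in per_chain]) for name in names}
    acceptance = {
        "log_rate": float(np.mean([out["_acc_log_rate"] for out in per_chain])),
        "eta": float(np.mean([out["_acc_eta"] for out in per_chain])),
    }
    return PosteriorChains(
        draws=draws,
        config=config,
        acceptance=acceptance,
        chain_seeds=seeds,
        runtime_seconds=time.time() - t0,
        region_labels=list(data.region_labels),
        outcome_labels=list(data.outcome_labels),
        years=list(data.years),
    )


def fit_constant_variant(
    data: ObservationData,
    graph: AdjacencyGraph,
    priors: PriorSpec,
    config: MCMCConfig,
) -> PosteriorChains:
    """Spatially constant loadings variant: scalar gamma^(k) ~ N(1, tau_g2)."""
    from dataclasses import replace

    return run_mcmc(data, graph, priors, replace(config, loadings_mode="constant"))


def gelman_rubin(chains: PosteriorChains | np.ndarray, parameter: str | None = None) -> np.ndarray:
    """Classic Gelman-Rubin potential scale reduction factor.

    Accepts either a :class:`PosteriorChains` plus a parameter name, or a
    raw ``(n_chains, n_draws, ...)`` array.  Returns the PSRF
    sqrt(((n-1)/n * W + B/n) / W) per scalar component; components with
    zero within-chain variance are flagged as NaN rather than raising.
    """
    if isinstance(chains, PosteriorChains):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorChains input")
        arr = chains.draws[parameter]
    else:
        arr = np.asarray(chains, dtype=float)
    if arr.ndim < 2:
        raise ValueError("expected (n_chains, n_draws, ...) array")
    m, n = arr.shape[0], arr.shape[1]
    if m < 2:
        raise ValueError("need >= 2 chains for the Gelman-Rubin diagnostic")
    if n < 10:
        raise ValueError("need >= 10 stored draws per chain")
    flat = arr.reshape(m, n, -1)
    chain_means = flat.mean(axis=1)  # (m, P)
    W = flat.var(axis=1, ddof=1).mean(axis=0)  # (P,)
    B_over_n = chain_means.var(axis=0, ddof=1)  # B/n
    with np.errstate(divide="ignore", invalid="ignore"):
        psrf = np.sqrt(((n - 1) / n * W + B_over_n) / W)
    psrf = np.where(W > 0, psrf, np.nan)
    return psrf.reshape(arr.shape[2:]) if arr.ndim > 2 else float(psrf[0])
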