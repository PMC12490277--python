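"""Posterior postprocessing: summaries, scaled loadings, variance ratios.

Turns :class:`~spatialfactor.mcmc.PosteriorChains` into the quantities an
analyst reports:

* posterior means with central 95% credible intervals, formatted
  "mean (lo, hi)";
* scaled loadings — each region's loading divided by the sum of all K
  loadings there, interpretable against the equal-contribution baseline
  1/K;
* variance-explained ratios — the share of each outcome's temporal
  variance (on the log-rate scale) attributable to the loading-times-
  factor product rather than idiosyncratic error, with a 0.50
  classification threshold;
* log relative risk fields — posterior mean of log lambda per cell,
  where zero means the baseline-year statewide rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorChains, gelman_rubin

__all__ = [
    "SummaryTable",
    "summarize",
    "scale_loadings",
    "variance_explained",
    "log_relative_risk",
    "DynamicSpatialFactorResults",
]

_SUM_TOL = 1e-6


@dataclass
class SummaryTable:
    """Posterior mean and central 95% interval per scalar parameter."""

    frame: pd.DataFrame  # columns: parameter, mean, lo, hi, formatted, degenerate

    def __str__(self) -> str:
        return self.frame.to_string(index=False)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _format(mean: float, lo: float, hi: float) -> str:
    return f"{mean:.3f} ({lo:.3f},{hi:.3f})"


def summarize(chains: PosteriorChains, parameter: str, labels=None) -> SummaryTable:
    """Pooled-across-chains posterior mean and 2.5/97.5 percentile interval.

    Deterministic given the draws and permutation-invariant in them.
    Degenerate (constant-draw) parameters are flagged.
    """
    draws = chains.pooled(parameter)
    if draws.size == 0:
        raise ValueError(f"no draws stored for parameter {parameter!r}")
    if draws.shape[0] < 40:
        raise ValueError("need >= 40 pooled draws for a meaningful 2.5% quantile")
    flat = draws.reshape(draws.shape[0], -1)
    mean = flat.mean(axis=0)
    lo = np.percentile(flat, 2.5, axis=0)
    hi = np.percentile(flat, 97.5, axis=0)
    n_comp = flat.shape[1]
    if labels is None:
        if n_comp == 1:
            labels = [parameter]
        else:
            labels = [
                f"{parameter}[{','.join(map(str, idx))}]"
                for idx in np.ndindex(draws.shape[1:])
            ]
    frame = pd.DataFrame(
        {
            "parameter": labels,
            "mean": mean,
            "lo": lo,
            "hi": hi,
            "formatted": [_format(m, a, b) for m, a, b in zip(mean, lo, hi)],
            "degenerate": lo == hi,
        }
    )
    return SummaryTable(frame)


def scale_loadings(raw: np.ndarray, tol: float = _SUM_TOL):
    """Scale each region's K loadings by their sum.

    Returns ``(scaled, defined)`` where ``scaled[i, k] = raw[i, k] /
    sum_k raw[i, k]`` and ``defined[i]`` is False where the sum's
    magnitude falls below ``tol`` (the region is flagged undefined, not
    dropped).  Scaled rows sum to 1 wherever defined; 1/K is the
    equal-contribution baseline.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[None, :]
    if raw.shape[-1] < 2:
        raise ValueError("need K >= 2 outcomes to scale loadings")
    sums = raw.sum(axis=-1)
    defined = np.abs(sums) >= tol
    safe = np.where(defined, sums, 1.0)
    scaled = raw / safe[..., None]
    scaled = np.where(defined[..., None], scaled, np.nan)
    return scaled, defined


def variance_explained(
    loadings_mean: np.ndarray,
    factor_mean: np.ndarray,
    sigma2_mean: np.ndarray,
):
    """Share of temporal variance explained by the loading-factor product.

    For region i, outcome k: Var_j(gamma_i^(k) f_ij) / (Var_j(...) +
    sigma_k^2), using posterior means and the empirical variance over
    the J time points.  Returns ``(ratio, above_half)`` with ratio in
    [0, 1] and the 0.50 classification flag.
    """
    loadings_mean = np.asarray(loadings_mean, dtype=float)
    factor_mean = np.asarray(factor_mean, dtype=float)
    sigma2_mean = np.asarray(sigma2_mean, dtype=float)
    if factor_mean.shape[1] < 2:
        raise ValueError("need J >= 2 time points to compute temporal variance")
    prod = loadings_mean[:, None, :] * factor_mean[:, :, None]  # (N, J, K)
    v = prod.var(axis=1)  # (N, K), population variance over time
    ratio = v / (v + sigma2_mean[None, :])
    ratio = np.where(v + sigma2_mean[None, :] > 0, ratio, 0.0)
    return ratio, ratio >= 0.5


def log_relative_risk(chains: PosteriorChains):
    """Posterior mean and 95% CI of log lambda per (region, year, outcome).

    Zero corresponds to the baseline-year statewide rate.
    """
    if "log_rate" not in chains.draws:
        raise ValueError("chains were run without storing log-rate draws")
    draws = chains.pooled("log_rate")
    return draws.mean(axis=0), np.percentile(draws, 2.5, axis=0), np.percentile(draws, 97.5, axis=0)


class DynamicSpatialFactorResults:
    """Posterior results of a fitted dynamic spatial factor model."""

    def __init__(self, model, chains: PosteriorChains):
        self.model = model
        self.chains = chains

    # -- basic accessors ------------------------------------------------
    @property
    def loadings_mean(self) -> np.ndarray:
        return self.chains.pooled("loadings").mean(axis=0)

    @property
    def factor_mean(self) -> np.ndarray:
        return self.chains.pooled("factor").mean(axis=0)

    @property
    def sigma2_mean(self) -> np.ndarray:
        return self.chains.pooled("sigma2").mean(axis=0)

    # -- reporting ------------------------------------------------------
    def summary(self, parameters=("loadings", "sigma2", "tau_f2", "tau_g2", "mu", "eta")) -> SummaryTable:
        """Table-style posterior summary of the requested parameter blocks.

        In the spatially constant variant the loadings block collapses to
        one row per outcome.
        """
        frames = []
        for p in parameters:
            if p == "loadings" and self.model.loadings_mode == "constant":
                draws = self.chains.pooled("loadings")[:, 0, :]  # scalars, region 0
                sub = _summary_of_array(draws, [f"loading[{o}]" for o in self.chains.outcome_labels])
            elif p == "loadings":
                labels = [
                    f"loading[{r},{o}]"
                    for r in self.chains.region_labels
                    for o in self.chains.outcome_labels
                ]
                sub = summarize(self.chains, p, labels=labels).frame
            elif p == "sigma2":
                sub = summarize(
                    self.chains, p, labels=[f"sigma2[{o}]" for o in self.chains.outcome_labels]
                ).frame
            elif p == "mu":
                sub = summarize(self.chains, p, labels=[f"mu[{y}]" for y in self.chains.years]).frame
            else:
                sub = summarize(self.chains, p).frame
            frames.append(sub)
        return SummaryTable(pd.concat(frames, ignore_index=True))

    def scaled_loadings(self, method: str = "per_draw"):
        """Posterior scaled loadings per region.

        ``per_draw`` scales within each posterior draw then averages
        (propagates uncertainty); ``posterior_mean`` scales the posterior
        mean loadings directly.  Returns ``(scaled (N, K), defined (N,))``.
        """
        if method == "per_draw":
            draws = self.chains.pooled("loadings")  # (S, N, K)
            scaled, defined = scale_loadings(draws.reshape(-1, draws.shape[-1]))
            scaled = scaled.reshape(draws.shape)
            defined = defined.reshape(draws.shape[:2])
            with np.errstate(invalid="ignore"):
                out = np.nanmean(np.where(defined[:, :, None], scaled, np.nan), axis=0)
            return out, defined.all(axis=0)
        if method == "posterior_mean":
            return scale_loadings(self.loadings_mean)
        raise ValueError("method must be 'per_draw' or 'posterior_mean'")

    def variance_explained(self):
        return variance_explained(self.loadings_mean, self.factor_mean, self.sigma2_mean)

    def log_relative_risk(self):
        return log_relative_risk(self.chains)

    def gelman_rubin(self, parameter: str):
        return gelman_rubin(self.chains, parameter)

    # -- plotting -------------------------------------------------------
    def plot_factor(self, regions=None, ax=None):
        """Posterior-mean factor trajectories over years, one line per region."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fm = self.factor_mean
        years = self.chains.years
        idx = range(fm.shape[0]) if regions is None else regions
        for i in idx:
            ax.plot(years, fm[i], alpha=0.5, label=self.chains.region_labels[i])
        ax.set_xlabel("year")
        ax.set_ylabel("posterior mean factor")
        return ax

    def plot_trace(self, parameter: str, index=0, ax=None):
        """Trace plot of one scalar component across chains."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        arr = self.chains.draws[parameter]
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for c in range(flat.shape[0]):
            ax.plot(flat[c, :, index], alpha=0.7, label=f"chain {c}")
        ax.set_xlabel("stored draw")
        ax.set_ylabel(f"{parameter}[{index}]")
        return ax


def _summary_of_array(draws: np.ndarray, labels) -> pd.DataFrame:
    mean = draws.mean(axis=0)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    return pd.DataFrame(
        {
            "parameter": labels,
            "mean": mean,
            "lo": lo,
            "hi": hi,
            "formatted": [_format(m, a, b) for m, a, b in zip(mean, lo, hi)],
            "degenerate": lo == hi,
        }
    )
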