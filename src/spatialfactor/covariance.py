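"""Closed-form marginal covariance of a one-factor spatial model.

For the Gaussian linear layer

    Y_i^(k) = gamma_i^(k) f_i + eps_i^(k),

with F ~ N(0, Sigma_F), independent loadings gamma^(k) ~ N(mu^(k), Sigma_Gamma^(k))
for non-reference outcomes (outcome 1 fixed at 1), and independent errors
eps_i^(k) ~ N(0, sigma_k^2), the marginal covariance of the stacked outcome
vector Y = (Y_1:N^(1), ..., Y_1:N^(K)) has closed form.  The (k1, k2) block's
(i, j) entry is

    [ delta_{k1 k2} * Sigma_Gamma^(k1)_ij + mu_i^(k1) mu_j^(k2) ] * Sigma_F_ij
      + delta_{k1 k2} delta_ij sigma_k1^2,

which specializes to the spatially constant case by replacing
Sigma_Gamma^(k) with the scalar tau_gamma(k)^2 and mu^(k) with a scalar.
The spatially varying case lets both the loading covariance and the factor
covariance shape the outcome covariance; in the constant case spatial
heterogeneity comes from the factor alone.

``mc_cov_oracle`` is a brute-force sampling check of the same algebra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovarianceSpec",
    "BlockCovariance",
    "marginal_cov_varying",
    "marginal_cov_constant",
    "mc_cov_oracle",
]

_PSD_RTOL = 1e-8


def _check_psd(mat: np.ndarray, name: str) -> None:
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    evals = np.linalg.eigvalsh(mat)
    floor = -_PSD_RTOL * max(evals.max(), 1.0)
    if evals.min() < floor:
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {evals.min():.3g})")


@dataclass
class CovarianceSpec:
    """Inputs to the marginal covariance of the stacked outcome vector.

    Parameters
    ----------
    sigma_f : (N, N) array
        Spatial covariance of the latent factor vector.
    loading_means : sequence of length K
        Per-outcome loading means.  Entry 0 (reference outcome) must be
        the all-ones vector (varying form) or 1.0 (constant form).
    loading_covs : sequence of length K
        Per-outcome loading covariances: (N, N) arrays in the varying
        form, nonnegative scalars tau_gamma^2 in the constant form.
        Entry 0 must be zero (the reference loading is fixed).
    error_vars : sequence of length K
        Outcome-specific error variances sigma_k^2 >= 0.
    """

    sigma_f: np.ndarray
    loading_means: Sequence
    loading_covs: Sequence
    error_vars: Sequence

    def __post_init__(self):
        self.sigma_f = np.asarray(self.sigma_f, dtype=float)
        if self.sigma_f.ndim != 2 or self.sigma_f.shape[0] != self.sigma_f.shape[1]:
            raise ValueError("sigma_f must be a square matrix")
        _check_psd(self.sigma_f, "sigma_f")
        N = self.sigma_f.shape[0]
        K = len(self.loading_means)
        if not (len(self.loading_covs) == K and len(self.error_vars) == K):
            raise ValueError("loading_means, loading_covs, error_vars must share length K")
        if K < 2:
            raise ValueError("need at least 2 outcomes (reference plus one)")
        self.error_vars = np.asarray(self.error_vars, dtype=float)
        if np.any(self.error_vars < 0):
            raise ValueError("error variances must be nonnegative")

        self.mode = "constant" if np.isscalar(self.loading_covs[1]) else "varying"
        if self.mode == "varying":
            means, covs = [], []
            for k in range(K):
                m = np.asarray(self.loading_means[k], dtype=float).reshape(-1)
                C = np.asarray(self.loading_covs[k], dtype=float)
                if m.shape[0] != N or C.shape != (N, N):
                    raise ValueError(f"outcome {k}: loading mean/cov dimension mismatch with N={N}")
                _check_psd(C, f"loading_covs[{k}]")
                means.append(m)
                covs.append(C)
            if not np.allclose(means[0], 1.0):
                raise ValueError("reference outcome loading mean must be the all-ones vector")
            if not np.allclose(covs[0], 0.0):
                raise ValueError("reference outcome loading covariance must be zero")
            self.loading_means = means
            self.loading_covs = covs
        else:
            means = [float(m) for m in self.loading_means]
            covs = [float(c) for c in self.loading_covs]
            if means[0] != 1.0 or covs[0] != 0.0:
                raise ValueError("reference outcome must have mean 1 and variance 0")
            if any(c < 0 for c in covs):
                raise ValueError("loading variances must be nonnegative")
            self.loading_means = means
            self.loading_covs = covs

    @property
    def n_regions(self) -> int:
        return self.sigma_f.shape[0]

    @property
    def n_outcomes(self) -> int:
        return len(self.loading_means)

    def mean_vector(self, k: int) -> np.ndarray:
        """Loading mean of outcome k as a length-N vector (either form)."""
        m = self.loading_means[k]
        return np.full(self.n_regions, m) if self.mode == "constant" else m


class BlockCovariance:
    """(N*K) x (N*K) covariance organized as a K x K grid of N x N blocks.

    Stacking is outcome-major: entry index ``k * N + i`` is region ``i``
    of outcome ``k``.
    """

    def __init__(self, full: np.ndarray, n_regions: int, n_outcomes: int):
        full = np.asarray(full, dtype=float)
        if full.shape != (n_regions * n_outcomes,) * 2:
            raise ValueError("full matrix shape inconsistent with N, K")
        self.full = full
        self.n_regions = n_regions
        self.n_outcomes = n_outcomes

    def block(self, k1: int, k2: int) -> np.ndarray:
        N = self.n_regions
        return self.full[k1 * N : (k1 + 1) * N, k2 * N : (k2 + 1) * N]

    def cov(self, k1: int, i: int, k2: int, j: int) -> float:
        """Cov(Y_i^(k1), Y_j^(k2))."""
        N = self.n_regions
        return float(self.full[k1 * N + i, k2 * N + j])

    def is_symmetric(self, atol: float = 1e-10) -> bool:
        return bool(np.allclose(self.full, self.full.T, atol=atol))

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.full).min())

    def to_frame(self) -> pd.DataFrame:
        """Flat long-format export: one row per matrix entry."""
        N, K = self.n_regions, self.n_outcomes
        rows = []
        for k1 in range(K):
            for k2 in range(K):
                blk = self.block(k1, k2)
                for i in range(N):
                    for j in range(N):
                        rows.append((k1, k2, i, j, blk[i, j]))
        return pd.DataFrame(
            rows, columns=["outcome_row", "outcome_col", "region_row", "region_col", "value"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _assemble(spec: CovarianceSpec, loading_second_moment) -> BlockCovariance:
    N, K = spec.n_regions, spec.n_outcomes
    full = np.zeros((N * K, N * K))
    for k1 in range(K):
        for k2 in range(k1, K):
            blk = loading_second_moment(k1, k2) * spec.sigma_f
            if k1 == k2:
                blk = blk + spec.error_vars[k1] * np.eye(N)
            full[k1 * N : (k1 + 1) * N, k2 * N : (k2 + 1) * N] = blk
            if k1 != k2:
                full[k2 * N : (k2 + 1) * N, k1 * N : (k1 + 1) * N] = blk.T
    return BlockCovariance(full, N, K)


def marginal_cov_varying(spec: CovarianceSpec) -> BlockCovariance:
    """Marginal Cov(Y) with spatially varying loadings.

    Diagonal block k: [Sigma_Gamma^(k) + mu^(k) mu^(k)^T] (elementwise *) Sigma_F
    + sigma_k^2 I; cross block (k1, k2): [mu^(k1) mu^(k2)^T] (elementwise *) Sigma_F.
    """
    if spec.mode != "varying":
        raise ValueError("spec is in constant form; use marginal_cov_constant")

    def second_moment(k1, k2):
        m = np.outer(spec.loading_means[k1], spec.loading_means[k2])
        if k1 == k2:
            m = m + spec.loading_covs[k1]
        return m

    return _assemble(spec, second_moment)


def marginal_cov_constant(spec: CovarianceSpec) -> BlockCovariance:
    """Marginal Cov(Y) with spatially constant loadings.

    Diagonal block k: (tau_gamma(k)^2 + mu^(k)^2) Sigma_F + sigma_k^2 I;
    cross block (k1, k2): mu^(k1) mu^(k2) Sigma_F.
    """
    if spec.mode != "constant":
        raise ValueError("spec is in varying form; use marginal_cov_varying")

    def second_moment(k1, k2):
        m = spec.loading_means[k1] * spec.loading_means[k2]
        if k1 == k2:
            m = m + spec.loading_covs[k1]
        return m

    return _assemble(spec, second_moment)


def mc_cov_oracle(
    spec: CovarianceSpec,
    n_draws: int = 1_000_000,
    seed: int = 0,
    return_se: bool = False,
    chunk: int = 100_000,
):
    """Brute-force Monte-Carlo estimate of Cov(Y) under the generative model.

    Draws F ~ N(0, Sigma_F), loadings from their Gaussian model, and
    independent errors; forms Y_i^(k) = gamma_i^(k) f_i + eps_i^(k) and
    returns the empirical cross-covariance (optionally with entrywise
    Monte-Carlo standard errors).
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10^4 for a meaningful oracle")
    rng = np.random.default_rng(seed)
    N, K = spec.n_regions, spec.n_outcomes
    D = N * K

    # spectral square roots (inputs may be singular, e.g. ICAR pseudo-covariances)
    def sqrt_of(C):
        evals, evecs = np.linalg.eigh(C)
        evals = np.clip(evals, 0.0, None)
        return evecs * np.sqrt(evals)

    Lf = sqrt_of(spec.sigma_f)
    if spec.mode == "varying":
        Lg = [None] + [sqrt_of(spec.loading_covs[k]) for k in range(1, K)]

    sum_y = np.zeros(D)
    sum_p = np.zeros((D, D))
    sum_p2 = np.zeros((D, D))
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        F = rng.standard_normal((m, N)) @ Lf.T
        gamma = np.empty((m, N, K))
        gamma[:, :, 0] = 1.0
        for k in range(1, K):
            if spec.mode == "varying":
                gamma[:, :, k] = spec.loading_means[k] + rng.standard_normal((m, N)) @ Lg[k].T
            else:
                g = spec.loading_means[k] + np.sqrt(spec.loading_covs[k]) * rng.standard_normal(m)
                gamma[:, :, k] = g[:, None]
        eps = rng.standard_normal((m, N, K)) * np.sqrt(spec.error_vars)[None, None, :]
        Y = gamma * F[:, :, None] + eps  # (m, N, K)
        Y = Y.transpose(0, 2, 1).reshape(m, D)  # outcome-major stacking
        sum_y += Y.sum(axis=0)
        P = np.einsum("ma,mb->ab", Y, Y)
        sum_p += P
        sum_p2 += np.einsum("ma,mb->ab", Y**2, Y**2)
        done += m

    mean = sum_y / n_draws
    cov = sum_p / n_draws - np.outer(mean, mean)
    cov *= n_draws / (n_draws - 1)
    result = BlockCovariance(cov, N, K)
    if not return_se:
        return result
    # SE of each empirical covariance entry: sd of centered products / sqrt(n).
    # E[(y_a y_b)^2] - E[y_a y_b]^2 with means ~ 0; adequate for oracle bands.
    second = sum_p / n_draws
    var_prod = sum_p2 / n_draws - second**2
    se = np.sqrt(np.clip(var_prod, 0.0, None) / n_draws)
    return result, se
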