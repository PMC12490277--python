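"""Areal adjacency graphs and intrinsic CAR (ICAR) machinery.

An :class:`AdjacencyGraph` stores the binary neighborhood structure
``w_il`` of a set of areal units (counties, grid cells, ...) together with
the neighbor totals ``w_i+``.  It is the shared spatial backbone for both
the latent factor field and the spatially varying loadings: each gets an
ICAR prior whose full conditional at region ``i`` has mean equal to the
prior mean plus the average deviation of the neighbors, and variance
``tau2 / w_i+``.

The ICAR joint density is improper; we work with the unnormalized
pairwise-difference form and, where a proper representative is needed
(simulation, closed-form covariances), with the rank-corrected
pseudo-inverse of the precision ``Q = D - W`` restricted to the
sum-to-zero subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AdjacencyGraph",
    "build_adjacency",
    "generate_lattice",
    "icar_conditional",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric binary adjacency among ``n_regions`` areal units.

    Attributes
    ----------
    n_regions : int
        Number of areal units.
    edges : tuple of (int, int)
        Unordered, deduplicated neighbor pairs ``(i, l)`` with ``i < l``;
        ``w_il = 1`` iff the pair is present.
    labels : tuple of str
        Region labels in index order (defaults to stringified indices).
    """

    n_regions: int
    edges: tuple
    labels: tuple = field(default=None)

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValueError("n_regions must be a positive integer")
        seen = set()
        for (i, l) in self.edges:
            if i == l:
                raise ValueError(f"self-loop at region {i}: ICAR adjacency forbids w_ii != 0")
            if not (0 <= i < self.n_regions and 0 <= l < self.n_regions):
                raise ValueError(f"edge ({i},{l}) out of range [0, {self.n_regions})")
            key = (min(i, l), max(i, l))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
        object.__setattr__(self, "edges", tuple(sorted(seen)))
        if self.labels is None:
            object.__setattr__(self, "labels", tuple(str(i) for i in range(self.n_regions)))
        elif len(self.labels) != self.n_regions:
            raise ValueError("labels length must equal n_regions")
        deg = np.zeros(self.n_regions, dtype=np.int64)
        for (i, l) in self.edges:
            deg[i] += 1
            deg[l] += 1
        if np.any(deg == 0):
            isolated = [self.labels[i] for i in np.nonzero(deg == 0)[0]]
            raise ValueError(
                f"isolated region(s) {isolated}: ICAR conditional is undefined at w_i+ = 0"
            )
        object.__setattr__(self, "_degrees", deg)
        g = nx.Graph()
        g.add_nodes_from(range(self.n_regions))
        g.add_edges_from(self.edges)
        object.__setattr__(self, "_n_components", nx.number_connected_components(g))

    # ------------------------------------------------------------------
    @property
    def degrees(self) -> np.ndarray:
        """Neighbor totals ``w_i+`` per region."""
        return self._degrees.copy()

    @property
    def n_components(self) -> int:
        return self._n_components

    @property
    def is_connected(self) -> bool:
        return self._n_components == 1

    def neighbors(self, i: int) -> list:
        return sorted(
            [l for (a, l) in self.edges if a == i] + [a for (a, l) in self.edges if l == i]
        )

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 matrix W."""
        W = np.zeros((self.n_regions, self.n_regions))
        for (i, l) in self.edges:
            W[i, l] = W[l, i] = 1.0
        return W

    def icar_precision(self) -> np.ndarray:
        """Unscaled ICAR precision ``Q = D - W`` (graph Laplacian, singular)."""
        W = self.adjacency_matrix()
        return np.diag(self._degrees.astype(float)) - W

    def icar_covariance(self, tau2: float = 1.0) -> np.ndarray:
        """Proper covariance ``tau2 * Q^+`` of the sum-to-zero ICAR representative.

        The Moore-Penrose pseudo-inverse drops the null space of ``Q``
        (constant vectors on each connected component), which is the
        standard proper representative of the improper ICAR law.
        """
        if tau2 <= 0:
            raise ValueError("tau2 must be positive")
        return tau2 * np.linalg.pinv(self.icar_precision(), hermitian=True)

    def icar_sqrt(self) -> np.ndarray:
        """Matrix B with ``B @ z`` (z std-normal) ~ sum-to-zero ICAR at tau2=1.

        Columns span the complement of the Laplacian null space, so draws
        automatically sum to zero on each connected component.
        """
        Q = self.icar_precision()
        evals, evecs = np.linalg.eigh(Q)
        tol = max(evals.max(), 1.0) * 1e-10
        pos = evals > tol
        return evecs[:, pos] / np.sqrt(evals[pos])

    def draw_icar(self, tau2: float, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Draw sum-to-zero ICAR deviation vectors with variance parameter tau2."""
        if tau2 <= 0:
            raise ValueError("tau2 must be positive")
        B = self.icar_sqrt()
        k = B.shape[1]
        if size is None:
            return np.sqrt(tau2) * B @ rng.standard_normal(k)
        return np.sqrt(tau2) * rng.standard_normal((size, k)) @ B.T


def build_adjacency(
    edge_list: Iterable[tuple], n_regions: int, labels: Sequence[str] | None = None
) -> AdjacencyGraph:
    """Build a validated :class:`AdjacencyGraph` from an edge list.

    Duplicate edges and reversed orientations are collapsed; self-loops
    and isolated regions are rejected.
    """
    edges = list(edge_list)
    if not edges:
        raise ValueError("edge list must be non-empty")
    dedup = set()
    for (i, l) in edges:
        if i == l:
            raise ValueError(f"self-loop at region {i}")
        dedup.add((min(i, l), max(i, l)))
    return AdjacencyGraph(
        n_regions=n_regions, edges=tuple(sorted(dedup)), labels=tuple(labels) if labels else None
    )


def generate_lattice(rows: int, cols: int, rule: str = "queen") -> AdjacencyGraph:
    """Regular ``rows x cols`` lattice under rook or queen contiguity.

    Queen contiguity (any shared point, including corners) mimics the
    point-touch county adjacency used in state-level analyses; rook
    restricts to shared edges.
    """
    if rows * cols < 2:
        raise ValueError("lattice must contain at least 2 cells")
    if rule not in ("rook", "queen"):
        raise ValueError(f"unknown contiguity rule {rule!r}; expected 'rook' or 'queen'")
    edges = []
    idx = lambda r, c: r * cols + c
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((idx(r, c), idx(r, c + 1)))
            if r + 1 < rows:
                edges.append((idx(r, c), idx(r + 1, c)))
            if rule == "queen":
                if r + 1 < rows and c + 1 < cols:
                    edges.append((idx(r, c), idx(r + 1, c + 1)))
                if r + 1 < rows and c - 1 >= 0:
                    edges.append((idx(r, c), idx(r + 1, c - 1)))
    return build_adjacency(edges, rows * cols)


def icar_conditional(
    values: np.ndarray,
    prior_means: np.ndarray,
    tau2: float,
    graph: AdjacencyGraph,
    i: int,
) -> tuple:
    """Full conditional mean and variance of the ICAR field at region ``i``.

    mean = m_i + (1/w_i+) * sum_{l ~ i} (values_l - m_l),
    variance = tau2 / w_i+.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    values = np.asarray(values, dtype=float)
    prior_means = np.asarray(prior_means, dtype=float)
    w_plus = graph.degrees[i]
    nbrs = graph.neighbors(i)
    dev = values[nbrs] - prior_means[nbrs]
    return prior_means[i] + dev.sum() / w_plus, tau2 / w_plus
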