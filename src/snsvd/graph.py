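"""Normalized graph Laplacian and the smoothing operator W.

For an undirected binary adjacency A with degrees d_i, the normalized
Laplacian is

    L_ij = 1              if i = j and d_i != 0,
    L_ij = -A_ij/sqrt(d_i d_j)   if i and j are adjacent,
    L_ij = 0              otherwise,

and W = D^{-1/2} A D^{-1/2} is its complement on non-isolated nodes.
Isolated nodes contribute all-zero rows to both L and W (so the network
term of the solver vanishes for genes absent from the network).  The
quadratic form u^T L u = (1/2) sum_ij A_ij (u_i/sqrt(d_i) - u_j/sqrt(d_j))^2
penalizes loading differences across edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import GeneNetwork


@dataclass
class LaplacianPair:
    """Sparse L and W = D^{-1/2} A D^{-1/2} for one network.

    Both matrices are symmetric CSR; W has an exactly zero diagonal
    (A has no self-loops) and all-zero rows for isolated nodes.
    """

    L: sp.csr_matrix
    W: sp.csr_matrix
    degrees: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.L.shape[0]


def normalized_laplacian(net: GeneNetwork) -> LaplacianPair:
    """Build the normalized Laplacian pair from a :class:`GeneNetwork`."""
    p = net.n_nodes
    a = net.adjacency()
    d = np.asarray(a.sum(axis=1)).ravel()
    inv_sqrt = np.zeros(p)
    nz = d > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(d[nz])
    d_half = sp.diags(inv_sqrt)
    w = (d_half @ a @ d_half).tocsr()
    diag = np.zeros(p)
    diag[nz] = 1.0
    lap = (sp.diags(diag) - w).tocsr()
    return LaplacianPair(L=lap, W=w, degrees=d.astype(int))


def quadratic_form(lap: LaplacianPair, u: np.ndarray) -> float:
    """Evaluate the network smoothness penalty u^T L u (always >= 0)."""
    u = np.asarray(u, dtype=float).ravel()
    if u.shape[0] != lap.n_nodes:
        raise ValueError(
            f"vector length {u.shape[0]} != number of nodes {lap.n_nodes}"
        )
    return float(u @ (lap.L @ u))


def pairwise_difference_form(net: GeneNetwork, u: np.ndarray) -> float:
    """u^T L u via the edgewise sum (1/2) sum A_ij (u_i/sqrt(d_i)-u_j/sqrt(d_j))^2.

    Independent of the matrix product; used to cross-check
    :func:`quadratic_form`.
    """
    u = np.asarray(u, dtype=float).ravel()
    if u.shape[0] != net.n_nodes:
        raise ValueError("vector length mismatch")
    d = net.degrees()
    total = 0.0
    for i, j in net.edges:
        total += (u[i] / np.sqrt(d[i]) - u[j] / np.sqrt(d[j])) ** 2
    return total
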