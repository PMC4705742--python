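"""Shared oracles and random-instance builders for the test suite.

The dense KKT solver here is intentionally independent of the package's
gene-elimination path: it assembles the full (B + m + 1) stationarity
system in (b, alpha, lambda) and solves it with a generic dense routine.
"""

from __future__ import annotations

import numpy as np

from erable.core import GeneMatrix, SolverConfig, assemble
from erable.distmat import DistanceMatrix
from erable.simulate import random_base_tree
from erable.tree import PhyloTree


def dense_kkt_solve(internals, config: SolverConfig = SolverConfig()):
    """Solve the full Lagrangian stationarity system directly.

    Rows: 2 H b - 2 sum_k alpha_k u_k = 0 (B rows);
          -2 u_k^T b + 2 S_k alpha_k + Z_k lambda = 0 (m rows);
          sum_k Z_k alpha_k = rhs (1 row).
    Returns (b, alpha, lambda).
    """
    B, m = internals.B, internals.m
    A = np.zeros((B + m + 1, B + m + 1))
    rhs = np.zeros(B + m + 1)
    A[:B, :B] = 2.0 * internals.H
    A[:B, B:B + m] = -2.0 * internals.U.T
    A[B:B + m, :B] = -2.0 * internals.U
    A[B:B + m, B:B + m] = np.diag(2.0 * internals.S)
    A[B:B + m, B + m] = internals.Z
    A[B + m, B:B + m] = internals.Z
    rhs[B + m] = internals.rhs
    sol = np.linalg.solve(A, rhs)
    return sol[:B], sol[B:B + m], float(sol[B + m])


def random_instance(
    seed: int,
    n_max: int = 10,
    m_max: int = 10,
    noise: float = 0.05,
    full_overlap: bool = False,
) -> tuple[list[GeneMatrix], PhyloTree]:
    """A noisy proportional-model instance on a random topology.

    Distances are gene-scaled patristic values with multiplicative
    lognormal-ish noise (kept positive), over random taxon subsets of size
    >= 4 that always include a common core so the instance stays
    identifiable.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    m = int(rng.integers(2, m_max + 1))
    topo = random_base_tree(n, rng)
    taxa = sorted(topo.leaves)
    core = list(rng.choice(taxa, size=4, replace=False))
    genes = []
    for k in range(m):
        if full_overlap or k == 0:
            # gene 0 always covers every taxon so the instance stays
            # identifiable (every edge constrained by some pair)
            sub = taxa
        else:
            extra = [t for t in taxa if t not in core]
            take = rng.random(len(extra)) < 0.6
            sub = sorted(core + [t for t, keep in zip(extra, take) if keep])
        t_k = rng.uniform(0.4, 9.0)
        dm = topo.restrict(sub).patristic_matrix()
        vals = t_k * dm.values * np.exp(noise * rng.standard_normal(dm.values.shape))
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        genes.append(
            GeneMatrix(
                name=f"g{k}",
                n_sites=int(rng.integers(200, 601)),
                delta=DistanceMatrix(dm.taxa, vals),
            )
        )
    return genes, topo


def weighted_design_lstsq(delta: DistanceMatrix, weights, topology: PhyloTree):
    """Generic WLS oracle: explicit (pairs x edges) path-incidence design
    matrix, rows scaled by sqrt(w), solved with numpy lstsq."""
    pairs = list(delta.defined_pairs())
    X = np.zeros((len(pairs), topology.n_edges))
    y = np.zeros(len(pairs))
    for r, (i, j, d) in enumerate(pairs):
        w = float(weights[delta.index(i), delta.index(j)])
        sw = np.sqrt(w)
        X[r, list(topology.path_edges(i, j))] = sw
        y[r] = sw * d
    sol, *_ = np.linalg.lstsq(X, y, rcond=None)
    return sol
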