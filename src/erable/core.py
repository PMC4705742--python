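"""The constrained weighted-least-squares solver at the heart of the method.

Given a fixed unrooted topology with B edges and m per-gene distance
matrices delta^(k) over partially overlapping taxon sets L_k, we jointly
estimate branch lengths b and per-gene *scale factors* alpha_k (inverse
relative rates) by solving

    minimize    Q(alpha, b) = sum_k sum_{i<j in L_k} w_ij^(k)
                              (alpha_k * delta_ij^(k) - d_ij(b))^2
    subject to  sum_k Z_k alpha_k = rhs_scale * sum_k Z_k,

where d_ij(b) is the path-length sum between i and j on the topology.
The default weights are w_ij^(k) = N_k (alignment length) and the default
constraint coefficients Z_k = N_k * sum_ij delta_ij^(k), which guards
against over-estimating the scale factors of genes sampled only in small
sets of closely related taxa.

With S_k = sum w (delta)^2, u_k[e] = sum over pairs whose path uses e of
w*delta, and H = sum over all pairs of w * x x^T (x the 0/1 path-incidence
vector), Lagrange stationarity eliminates the alpha_k through the Schur
complement M = H - sum_k u_k u_k^T / S_k, leaving the augmented linear
system

    [ M   -v ] [b ]   [0]           v = sum_k (Z_k/S_k) u_k,
    [ v^T  z ] [mu] = [R],          z = sum_k Z_k^2/S_k,  R = rhs * sum Z_k,

after which alpha_k = (u_k^T b + mu Z_k)/S_k and lambda = -2 mu. The
augmented form is preferred over solving M b0 = v directly because M is
singular on every exactly proportional (noise-free) input, where the
optimum is nonetheless unique; the augmented matrix is singular precisely
when the optimizer has multiple solutions, which makes its rank the
authoritative identifiability test. Pairs with undefined distances carry
weight zero everywhere.

Finally the raw solution is rescaled by c = (1/N) sum_k N_k / alpha_k
(N = sum N_k) so the reported rates r_k = 1/(c*alpha_k) have
sequence-length-weighted mean one, and the reported branch lengths c*b
are on the corresponding scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .distmat import DistanceMatrix
from .errors import DegenerateSystemError, GeneRejectedError, TreeError
from .tree import PhyloTree

__all__ = [
    "GeneMatrix",
    "SolverConfig",
    "SolverInternals",
    "ErableResult",
    "IdentifiabilityReport",
    "pair_weight",
    "z_value",
    "assemble",
    "solve_constrained",
    "rescale",
    "check_identifiability",
    "wls_single",
    "run",
]

WeightMode = Literal["flat", "seqlen", "custom"]
ZMode = Literal["unit", "seqlen", "seqlen_distsum"]


@dataclass(frozen=True)
class GeneMatrix:
    """One gene's evidence: a distance matrix plus its alignment length.

    ``n_sites`` (N_k) enters both the default pair weights and the default
    constraint coefficient. ``custom_weights`` (optional, symmetric,
    positive, aligned with ``delta.taxa``) is only consulted in the
    ``custom`` weighting mode.
    """

    name: str
    n_sites: int
    delta: DistanceMatrix
    custom_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.n_sites < 1:
            raise GeneRejectedError(f"gene {self.name!r}: n_sites must be >= 1")
        if len(self.delta) < 2:
            raise GeneRejectedError(f"gene {self.name!r}: fewer than two taxa")

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.delta.taxa


@dataclass(frozen=True)
class SolverConfig:
    """Tunable solver behaviour (defaults follow the published method)."""

    weight_mode: WeightMode = "seqlen"
    z_mode: ZMode = "seqlen_distsum"
    rhs_scale: float = 1.0
    singular_tol: float = 1e-10
    clamp_negative_lengths: bool = False

    def __post_init__(self):
        if self.weight_mode not in ("flat", "seqlen", "custom"):
            raise ValueError(f"invalid weight_mode {self.weight_mode!r}")
        if self.z_mode not in ("unit", "seqlen", "seqlen_distsum"):
            raise ValueError(f"invalid z_mode {self.z_mode!r}")
        if self.rhs_scale <= 0:
            raise ValueError("rhs_scale must be positive")


@dataclass
class SolverInternals:
    """Assembled quadratic system and, once solved, the raw solution."""

    topology: PhyloTree
    gene_names: list[str]
    n_sites: np.ndarray          # (m,)
    H: np.ndarray                # (B, B)
    U: np.ndarray                # (m, B): row k is u_k
    S: np.ndarray                # (m,)
    Z: np.ndarray                # (m,)
    M: np.ndarray                # (B, B) Schur complement
    v: np.ndarray                # (B,)
    rhs: float                   # rhs_scale * sum Z_k
    b_hat: np.ndarray | None = None
    alpha_hat: np.ndarray | None = None
    mu: float | None = None
    lam: float | None = None
    Q_value: float | None = None
    rank_deficient: bool = False
    null_space: np.ndarray | None = None  # (B+1, d) basis if rank-deficient

    @property
    def m(self) -> int:
        return len(self.gene_names)

    @property
    def B(self) -> int:
        return self.topology.n_edges


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Uniqueness diagnostics for a dataset on a topology.

    ``non_cooccurring_pairs`` (taxon pairs never observed together in any
    gene) is a necessary-but-not-sufficient symptom of multiplicity; the
    authoritative test is ``rank_deficient``. ``null_space_edges`` lists
    edges whose length is not pinned down when solutions are multiple.
    """

    non_cooccurring_pairs: tuple[tuple[str, str], ...]
    rank_deficient: bool
    null_space_edges: tuple[int, ...]

    @property
    def unique(self) -> bool:
        return not self.rank_deficient


@dataclass
class ErableResult:
    """Final rescaled estimates."""

    gene_names: list[str]
    n_sites: np.ndarray
    rates: np.ndarray            # r_hat_k = 1/(c * alpha_hat_k)
    alpha_hat: np.ndarray
    c: float
    tree: PhyloTree              # topology carrying final lengths c * b_hat
    raw_lengths: np.ndarray
    Q_value: float
    unique: bool
    warnings: list[str] = field(default_factory=list)
    identifiability: IdentifiabilityReport | None = None
    internals: SolverInternals | None = None


# ---------------------------------------------------------------------------

def pair_weight(gene: GeneMatrix, mode: WeightMode = "seqlen") -> np.ndarray:
    """Symmetric weight matrix over the gene's taxa; undefined-distance
    pairs get weight zero (excluded from every sum) regardless of mode."""
    n = len(gene.delta)
    if mode == "flat":
        w = np.ones((n, n))
    elif mode == "seqlen":
        w = np.full((n, n), float(gene.n_sites))
    elif mode == "custom":
        if gene.custom_weights is None:
            raise ValueError(f"gene {gene.name!r}: custom weights missing")
        w = np.array(gene.custom_weights, dtype=float)
        if w.shape != (n, n) or not np.allclose(w, w.T):
            raise ValueError(f"gene {gene.name!r}: custom weights must be "
                             f"symmetric {n}x{n}")
        off = ~np.eye(n, dtype=bool)
        if (w[off] <= 0).any():
            raise ValueError(f"gene {gene.name!r}: custom weights must be positive")
    else:
        raise ValueError(f"invalid weight mode {mode!r}")
    w[np.isnan(gene.delta.values)] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def z_value(gene: GeneMatrix, mode: ZMode = "seqlen_distsum") -> float:
    """Constraint coefficient Z_k of one gene."""
    if mode == "unit":
        return 1.0
    if mode == "seqlen":
        return float(gene.n_sites)
    if mode == "seqlen_distsum":
        tot = sum(d for _, _, d in gene.delta.defined_pairs())
        if tot <= 0:
            raise GeneRejectedError(
                f"gene {gene.name!r}: all defined distances are zero; its "
                f"scale factor is unconstrained under seqlen_distsum"
            )
        return float(gene.n_sites) * tot
    raise ValueError(f"invalid z mode {mode!r}")


def _path_cache(topology: PhyloTree):
    cache: dict[tuple[str, str], np.ndarray] = {}

    def get(i: str, j: str) -> np.ndarray:
        key = (i, j) if i < j else (j, i)
        if key not in cache:
            cache[key] = np.fromiter(
                topology.path_edges(*key), dtype=np.intp
            )
        return cache[key]

    return get


def assemble(
    genes: Sequence[GeneMatrix],
    topology: PhyloTree,
    config: SolverConfig = SolverConfig(),
) -> SolverInternals:
    """Accumulate H, u_k, S_k, Z_k and the Schur complement M, v."""
    if not genes:
        raise GeneRejectedError("no gene matrices supplied")
    B = topology.n_edges
    leaves = topology.leaves
    paths = _path_cache(topology)
    H = np.zeros((B, B))
    U = np.zeros((len(genes), B))
    S = np.zeros(len(genes))
    Z = np.zeros(len(genes))
    for k, gene in enumerate(genes):
        missing = set(gene.taxa) - leaves
        if missing:
            raise TreeError(
                f"gene {gene.name!r}: taxa not in topology: {sorted(missing)}"
            )
        w = pair_weight(gene, config.weight_mode)
        any_pair = False
        for i, j, d in gene.delta.defined_pairs():
            wij = w[gene.delta.index(i), gene.delta.index(j)]
            if wij == 0.0:
                continue
            any_pair = True
            e = paths(i, j)
            S[k] += wij * d * d
            U[k, e] += wij * d
            H[np.ix_(e, e)] += wij
        if not any_pair or S[k] <= 0.0:
            raise GeneRejectedError(
                f"gene {gene.name!r}: no defined pair with positive distance"
            )
        Z[k] = z_value(gene, config.z_mode)
    M = H - (U.T / S) @ U
    M = (M + M.T) / 2.0
    v = (Z / S) @ U
    return SolverInternals(
        topology=topology,
        gene_names=[g.name for g in genes],
        n_sites=np.array([g.n_sites for g in genes], dtype=float),
        H=H, U=U, S=S, Z=Z, M=M, v=v,
        rhs=float(config.rhs_scale * Z.sum()),
    )


def solve_constrained(
    internals: SolverInternals, config: SolverConfig = SolverConfig()
) -> SolverInternals:
    """Complete ``internals`` with the optimum of the constrained problem.

    Solves the augmented (B+1)-system in (b, mu); if it is rank-deficient at
    ``config.singular_tol`` the minimum-norm representative is returned and
    ``rank_deficient`` is set (the solution set is then an affine subspace).
    """
    B = internals.B
    A = np.zeros((B + 1, B + 1))
    A[:B, :B] = internals.M
    A[:B, B] = -internals.v
    A[B, :B] = internals.v
    A[B, B] = float(np.sum(internals.Z ** 2 / internals.S))
    rhs_vec = np.zeros(B + 1)
    rhs_vec[B] = internals.rhs
    # rank via SVD of the (square, generally non-symmetric) augmented matrix
    svals = np.linalg.svd(A, compute_uv=False)
    smax = svals[0] if len(svals) else 0.0
    deficient = smax == 0.0 or bool(svals[-1] < config.singular_tol * smax)
    if deficient:
        sol, *_ = np.linalg.lstsq(A, rhs_vec, rcond=config.singular_tol)
        # keep a null-space basis for diagnostics
        _, s, vt = np.linalg.svd(A)
        null = vt[s < config.singular_tol * smax].T if smax > 0 else np.eye(B + 1)
        internals.null_space = null
        internals.rank_deficient = True
    else:
        sol = np.linalg.solve(A, rhs_vec)
    b = sol[:B]
    mu = float(sol[B])
    resid = abs(float(internals.v @ b + A[B, B] * mu) - internals.rhs)
    if resid > 1e-8 * max(abs(internals.rhs), 1.0):
        raise DegenerateSystemError(
            "constraint cannot be met: the assembled system is degenerate "
            f"(residual {resid:.3e})"
        )
    alpha = (internals.U @ b + mu * internals.Z) / internals.S
    q = float(
        np.sum(internals.S * alpha ** 2)
        - 2.0 * np.sum(alpha * (internals.U @ b))
        + b @ internals.H @ b
    )
    internals.b_hat = b
    internals.mu = mu
    internals.lam = -2.0 * mu
    internals.alpha_hat = alpha
    internals.Q_value = max(q, 0.0)
    return internals


def rescale(
    internals: SolverInternals, config: SolverConfig = SolverConfig()
) -> ErableResult:
    """Apply the correction factor c so rates have N-weighted mean one."""
    if internals.alpha_hat is None or internals.b_hat is None:
        raise ValueError("solve_constrained must run before rescale")
    alpha = internals.alpha_hat
    N = internals.n_sites
    warnings_: list[str] = []
    if (alpha == 0).any():
        bad = [n for n, a in zip(internals.gene_names, alpha) if a == 0]
        raise DegenerateSystemError(
            f"zero scale factor for gene(s) {bad}: rates are undefined"
        )
    if (alpha < 0).any():
        bad = [n for n, a in zip(internals.gene_names, alpha) if a < 0]
        warnings_.append(
            f"negative scale factor for gene(s) {bad}; the corresponding "
            f"reported rates are negative"
        )
    c = float(np.sum(N / alpha) / N.sum())
    rates = 1.0 / (c * alpha)
    final = c * internals.b_hat
    if (final < 0).any():
        n_neg = int((final < 0).sum())
        if config.clamp_negative_lengths:
            final = np.where(final < 0, 0.0, final)
            warnings_.append(f"{n_neg} negative branch length(s) clamped to 0")
        else:
            warnings_.append(f"{n_neg} negative branch length(s) retained")
    return ErableResult(
        gene_names=list(internals.gene_names),
        n_sites=N.copy(),
        rates=rates,
        alpha_hat=alpha.copy(),
        c=c,
        tree=internals.topology.with_lengths(final),
        raw_lengths=internals.b_hat.copy(),
        Q_value=float(internals.Q_value),
        unique=not internals.rank_deficient,
        warnings=warnings_,
        internals=internals,
    )


def check_identifiability(
    genes: Sequence[GeneMatrix],
    topology: PhyloTree,
    config: SolverConfig = SolverConfig(),
    internals: SolverInternals | None = None,
) -> IdentifiabilityReport:
    """Non-co-occurring taxon pairs, rank deficiency, and the edges whose
    lengths the data leave free."""
    covered: set[frozenset[str]] = set()
    for gene in genes:
        for i, j, _ in gene.delta.defined_pairs():
            covered.add(frozenset((i, j)))
    missing = tuple(
        (i, j)
        for i, j in itertools.combinations(sorted(topology.leaves), 2)
        if frozenset((i, j)) not in covered
    )
    if internals is None:
        internals = solve_constrained(assemble(genes, topology, config), config)
    elif internals.b_hat is None:
        internals = solve_constrained(internals, config)
    edges: tuple[int, ...] = ()
    if internals.rank_deficient and internals.null_space is not None:
        B = internals.B
        support = np.abs(internals.null_space[:B]).max(axis=1) > 1e-8
        edges = tuple(int(e) for e in np.flatnonzero(support))
    return IdentifiabilityReport(
        non_cooccurring_pairs=missing,
        rank_deficient=internals.rank_deficient,
        null_space_edges=edges,
    )


def wls_single(
    delta: DistanceMatrix,
    weights: np.ndarray,
    topology: PhyloTree,
) -> np.ndarray:
    """Classic weighted-least-squares branch lengths for a single matrix:
    the unconstrained minimizer of sum w_ij (delta_ij - d_ij(b))^2 via the
    normal equations H b = u. Oracle for the single-gene reduction."""
    if set(delta.taxa) != topology.leaves:
        raise TreeError("distance matrix taxa must equal the topology's leaves")
    B = topology.n_edges
    paths = _path_cache(topology)
    H = np.zeros((B, B))
    u = np.zeros(B)
    for i, j, d in delta.defined_pairs():
        wij = float(weights[delta.index(i), delta.index(j)])
        if wij == 0.0:
            continue
        e = paths(i, j)
        u[e] += wij * d
        H[np.ix_(e, e)] += wij
    svals = np.linalg.svd(H, compute_uv=False)
    if svals[0] == 0 or svals[-1] < 1e-10 * svals[0]:
        raise DegenerateSystemError("singular normal equations: branch "
                                    "lengths are not identifiable")
    return np.linalg.solve(H, u)


def run(
    genes: Sequence[GeneMatrix],
    topology: PhyloTree,
    config: SolverConfig = SolverConfig(),
) -> ErableResult:
    """End-to-end: assemble, solve, rescale, attach identifiability report.

    Deterministic for fixed inputs.
    """
    internals = assemble(genes, topology, config)
    solve_constrained(internals, config)
    result = rescale(internals, config)
    result.identifiability = check_identifiability(
        genes, topology, config, internals=internals
    )
    if result.identifiability.non_cooccurring_pairs:
        result.warnings.append(
            f"{len(result.identifiability.non_cooccurring_pairs)} taxon "
            f"pair(s) never co-occur in any gene"
        )
    if not result.unique:
        result.warnings.append(
            "multiple optimal solutions exist; a minimum-norm representative "
            "is returned"
        )
    return result
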