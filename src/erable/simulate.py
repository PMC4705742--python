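"""Synthetic phylogenomic replicates with known branch lengths and rates.

A replicate mimics a multilocus data set evolving under the proportional
model: one normalized base tree (total branch length 1); m gene trees equal
to the base tree scaled by factors t_k ~ U[rate_low, rate_high]; per-gene
DNA alignments of length N_k ~ U{len_low..len_high} simulated under
K2P+Gamma (transition/transversion *rate* ratio kappa, continuous gamma
rates across sites); and per-gene taxon dropout with probability p drawn
uniformly per gene, floored at ``min_taxa`` surviving taxa. The ground
truth handed to evaluation is the *model tree* — per-edge sequence-length-
weighted average of the gene trees, restricted to the union of sampled
taxa — and the *model rates* r_k = t_k / F with F = (1/N) sum N_k t_k, so
that the N-weighted mean rate is exactly one.

Defaults (n=40 taxa, m=500 genes, rates on [0.4, 9], lengths on
[200, 600], kappa=4 i.e. an expected transition/transversion event ratio
R=2, gamma shape 1, floor of 4 taxa) are the study conditions this
generator is meant to emulate. Base-tree topologies come from random
sequential leaf addition with i.i.d. exponential branch lengths (mean 0.1
before normalization); inject your own tree if you need a different shape
distribution.

Randomness: one integer seed drives independent child streams (topology,
gene factors, sequence lengths, sequences, missingness), so e.g. skipping
sequence simulation does not change which taxa are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import GeneMatrix
from .distances import Alignment
from .errors import ErableError, TreeError
from .tree import PhyloTree

__all__ = [
    "ReplicateConfig",
    "Replicate",
    "random_base_tree",
    "make_gene_trees",
    "simulate_alignment",
    "apply_missingness",
    "model_tree",
    "model_rates",
    "kappa_from_event_ratio",
    "generate_replicate",
    "patristic_gene_matrices",
    "estimated_gene_matrices",
    "write_replicate",
]

_BASES = np.frombuffer(b"AGCT", dtype="S1")  # code order: transition = code^1


@dataclass(frozen=True)
class ReplicateConfig:
    """Simulation knobs; defaults are the emulated study conditions."""

    n: int = 40
    m: int = 500
    rate_low: float = 0.4
    rate_high: float = 9.0
    len_low: int = 200
    len_high: int = 600
    kappa: float = 4.0
    gamma_shape: float | None = 1.0
    min_taxa: int = 4
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.rate_low < self.rate_high):
            raise ValueError("need 0 < rate_low < rate_high")
        if self.len_low > self.len_high or self.len_low < 1:
            raise ValueError("need 1 <= len_low <= len_high")
        if self.min_taxa < 2:
            raise ValueError("min_taxa must be >= 2")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n < 4:
            raise ValueError("need at least 4 taxa")
        if self.m < 1:
            raise ValueError("need at least one gene")


@dataclass
class Replicate:
    """One simulated dataset plus its ground truth."""

    config: ReplicateConfig
    base_tree: PhyloTree                  # normalized, total length 1
    gene_factors: np.ndarray              # t_k
    gene_trees: list[PhyloTree]           # base scaled by t_k
    n_sites: np.ndarray                   # N_k (int)
    taxon_sets: list[tuple[str, ...]]     # L_k, sorted
    alignments: list[Alignment] | None    # rows restricted to L_k
    model_tree: PhyloTree                 # Eq-weighted average, restricted to L
    model_rates: np.ndarray               # r_k = t_k / F
    F: float

    @property
    def taxa_union(self) -> frozenset[str]:
        return frozenset(t for L in self.taxon_sets for t in L)


def kappa_from_event_ratio(R: float) -> float:
    """K2P rate-ratio kappa giving an expected transition/transversion
    *event* ratio of R under equal base frequencies (kappa = 2R): each base
    has one transition partner but two transversion partners."""
    if R <= 0:
        raise ValueError("R must be positive")
    return 2.0 * R


def random_base_tree(n: int, rng: np.random.Generator) -> PhyloTree:
    """Random binary unrooted topology on taxa t01..tNN via sequential leaf
    addition, i.i.d. exponential(mean 0.1) lengths, normalized to total
    branch length one."""
    if n < 4:
        raise TreeError("need at least 4 taxa for a base tree")
    width = max(2, len(str(n)))
    labels = [f"t{i + 1:0{width}d}" for i in range(n)]
    # node 0 = first internal node; leaves get fresh ids
    edges: list[tuple[int, int]] = [(0, 1), (0, 2), (0, 3)]
    leaf_labels = {1: labels[0], 2: labels[1], 3: labels[2]}
    next_node = 4
    for leaf_idx in range(3, n):
        eid = int(rng.integers(len(edges)))
        u, v = edges[eid]
        mid, leaf = next_node, next_node + 1
        next_node += 2
        edges[eid] = (u, mid)
        edges.append((mid, v))
        edges.append((mid, leaf))
        leaf_labels[leaf] = labels[leaf_idx]
    lengths = rng.exponential(0.1, size=len(edges))
    tree = PhyloTree(edges, lengths.tolist(), leaf_labels)
    return tree.normalized()


def make_gene_trees(
    base: PhyloTree,
    m: int,
    rate_low: float,
    rate_high: float,
    rng: np.random.Generator,
) -> tuple[list[PhyloTree], np.ndarray]:
    """Scale every branch of ``base`` by t_k ~ U[rate_low, rate_high]."""
    t = rng.uniform(rate_low, rate_high, size=m)
    lens = base.edge_lengths
    return [base.with_lengths(lens * tk) for tk in t], t


def simulate_alignment(
    tree: PhyloTree,
    n_sites: int,
    kappa: float = 4.0,
    gamma_shape: float | None = 1.0,
    rng: np.random.Generator | None = None,
    name: str = "sim",
) -> Alignment:
    """Evolve i.i.d. sites down ``tree`` under K2P (+ continuous gamma).

    The root sequence is uniform over {A,C,G,T}; per site a rate
    g ~ Gamma(shape=gamma_shape, mean 1) multiplies every branch length
    (``gamma_shape=None`` disables heterogeneity). The chain is rooted at
    an arbitrary internal node — K2P is reversible, so the choice does not
    affect the distribution of the leaves.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    lens = tree.edge_lengths
    if np.isnan(lens).any() or (lens < 0).any():
        raise TreeError("simulation requires non-negative lengths on all edges")
    if gamma_shape is None:
        g = np.ones(n_sites)
    else:
        g = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_sites)
    order = tree.edges_preorder()
    root = order[0][0] if order else next(iter(tree.leaf_nodes.values()))
    seqs: dict[int, np.ndarray] = {root: rng.integers(0, 4, size=n_sites)}
    for parent, child, eid in order:
        d = lens[eid] * g
        e1 = np.exp(-4.0 * d / (kappa + 2.0))
        e2 = np.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
        p_same = 0.25 + 0.25 * e1 + 0.5 * e2
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        u = rng.random(n_sites)
        tv = seqs[parent] ^ rng.integers(2, 4, size=n_sites)  # the two transversions
        out = np.where(
            u < p_same, seqs[parent], np.where(u < p_same + p_ts, seqs[parent] ^ 1, tv)
        )
        seqs[child] = out
    taxa = sorted(tree.leaves)
    label_node = tree.leaf_nodes
    rows = tuple(
        _BASES[seqs[label_node[t]]].tobytes().decode() for t in taxa
    )
    return Alignment(name, tuple(taxa), rows)


def apply_missingness(
    taxa: Sequence[str],
    min_taxa: int,
    rng: np.random.Generator,
    p: float | None = None,
) -> tuple[str, ...]:
    """Per-gene dropout: draw p ~ U[0,1] (unless given), keep each taxon
    with probability 1-p; if fewer than ``min_taxa`` survive, return
    ``min_taxa`` taxa drawn uniformly from the full set instead."""
    taxa = sorted(taxa)
    if len(taxa) < min_taxa:
        raise ValueError("fewer taxa than the floor")
    if p is None:
        p = float(rng.uniform())
    keep = [t for t, u in zip(taxa, rng.random(len(taxa))) if u >= p]
    if len(keep) < min_taxa:
        idx = rng.choice(len(taxa), size=min_taxa, replace=False)
        keep = [taxa[i] for i in sorted(idx)]
    return tuple(keep)


def model_tree(
    gene_trees: Sequence[PhyloTree],
    n_sites: Sequence[int],
    taxa_union: Sequence[str] | frozenset[str],
) -> PhyloTree:
    """Per-edge N_k-weighted average of topologically identical gene trees,
    restricted to the union of sampled taxa."""
    if len(gene_trees) != len(n_sites):
        raise ValueError("one sequence length per gene tree required")
    first = gene_trees[0]
    ref = first.bipartitions()
    order = {split: eid for eid, split in ref.items()}
    N = np.asarray(n_sites, dtype=float)
    avg = np.zeros(first.n_edges)
    for tree, nk in zip(gene_trees, N):
        bip = tree.bipartitions()
        if set(bip.values()) != set(order):
            raise TreeError("gene trees must share one topology")
        lens = tree.edge_lengths
        for eid, split in bip.items():
            avg[order[split]] += nk * lens[eid]
    avg /= N.sum()
    return first.with_lengths(avg).restrict(set(taxa_union))


def model_rates(t: Sequence[float], n_sites: Sequence[int]) -> np.ndarray:
    """r_k = t_k / F with F the N-weighted mean of the t_k, so the
    N-weighted mean of the r_k is one."""
    t = np.asarray(t, dtype=float)
    N = np.asarray(n_sites, dtype=float)
    if (t <= 0).any():
        raise ValueError("gene factors must be positive")
    F = float((N * t).sum() / N.sum())
    return t / F


def generate_replicate(
    config: ReplicateConfig, sequences: bool = True
) -> Replicate:
    """Compose the full pipeline; fully determined by ``config.seed``.

    ``sequences=False`` skips alignment simulation (for workflows that use
    exact patristic matrices); all other draws are unchanged.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_rates, rng_len, rng_seq, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    base = random_base_tree(config.n, rng_tree)
    gene_trees, t = make_gene_trees(
        base, config.m, config.rate_low, config.rate_high, rng_rates
    )
    n_sites = rng_len.integers(config.len_low, config.len_high + 1, size=config.m)
    taxa = sorted(base.leaves)
    taxon_sets = [
        apply_missingness(taxa, config.min_taxa, rng_miss) for _ in range(config.m)
    ]
    alignments: list[Alignment] | None = None
    if sequences:
        alignments = []
        for k in range(config.m):
            aln = simulate_alignment(
                gene_trees[k],
                int(n_sites[k]),
                kappa=config.kappa,
                gamma_shape=config.gamma_shape,
                rng=rng_seq,
                name=f"g{k + 1:04d}",
            )
            alignments.append(aln.subset(taxon_sets[k]))
    union = frozenset(tx for L in taxon_sets for tx in L)
    mtree = model_tree(gene_trees, n_sites, union)
    rates = model_rates(t, n_sites)
    F = float((n_sites * t).sum() / n_sites.sum())
    return Replicate(
        config=config,
        base_tree=base,
        gene_factors=t,
        gene_trees=gene_trees,
        n_sites=n_sites,
        taxon_sets=taxon_sets,
        alignments=alignments,
        model_tree=mtree,
        model_rates=rates,
        F=F,
    )


def patristic_gene_matrices(rep: Replicate) -> list[GeneMatrix]:
    """Exact patristic matrices of each gene tree restricted to its taxon
    set — the noise-free input under the proportional model."""
    out = []
    for k, (tree, L) in enumerate(zip(rep.gene_trees, rep.taxon_sets)):
        out.append(
            GeneMatrix(
                name=f"g{k + 1:04d}",
                n_sites=int(rep.n_sites[k]),
                delta=tree.restrict(L).patristic_matrix(),
            )
        )
    return out


def estimated_gene_matrices(
    rep: Replicate, model: str = "tn93", gamma_shape: float | None = 1.0
) -> list[GeneMatrix]:
    """Model-based distance matrices estimated from the simulated
    alignments (the realistic, noisy input)."""
    from .distances import estimate_matrix

    if rep.alignments is None:
        raise ErableError("replicate was generated without sequences")
    return [
        GeneMatrix(
            name=aln.name,
            n_sites=int(nk),
            delta=estimate_matrix(aln, model=model, gamma_shape=gamma_shape),
        )
        for aln, nk in zip(rep.alignments, rep.n_sites)
    ]


def write_replicate(rep: Replicate, outdir) -> None:
    """Serialize to a directory: trees (Newick), alignments (FASTA), truth
    table (TSV: gene, t_k, N_k, r_k, n_taxa) and a config echo (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "base_tree.nwk").write_text(rep.base_tree.to_newick() + "\n")
    (outdir / "model_tree.nwk").write_text(rep.model_tree.to_newick() + "\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene\tt_k\tN_k\tr_k\tn_taxa\n")
        for k in range(rep.config.m):
            fh.write(
                f"g{k + 1:04d}\t{rep.gene_factors[k]:.10g}\t{int(rep.n_sites[k])}"
                f"\t{rep.model_rates[k]:.10g}\t{len(rep.taxon_sets[k])}\n"
            )
    cfg = {k: getattr(rep.config, k) for k in (
        "n", "m", "rate_low", "rate_high", "len_low", "len_high",
        "kappa", "gamma_shape", "min_taxa", "seed")}
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    if rep.alignments is not None:
        adir = outdir / "alignments"
        adir.mkdir(exist_ok=True)
        for aln in rep.alignments:
            aln.to_fasta(adir / f"{aln.name}.fasta")
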