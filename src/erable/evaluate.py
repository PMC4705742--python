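"""Accuracy metrics for branch-length and rate estimates against truth.

Two conventions are fixed here and used throughout:

* fraction of variance unexplained (FVU):
  ``sum (est_i - true_i)^2 / sum (true_i - mean(true))^2`` — zero for a
  perfect fit, one for the constant mean predictor;
* mean absolute log-ratio (MALR): ``(1/m) sum |ln(est_k / true_k)|``
  (natural log) — symmetric in estimate and truth, appropriate for rates,
  which are inherently ratios.

Edges are matched across trees by leaf-set bipartition, never by edge id,
so estimates and truth may come from independently constructed trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ErableResult
from .errors import ErableError
from .simulate import Replicate

__all__ = [
    "fraction_variance_unexplained",
    "mean_abs_log_ratio",
    "ComparisonTable",
    "compare",
]


def fraction_variance_unexplained(true, est) -> float:
    true = np.asarray(true, dtype=float)
    est = np.asarray(est, dtype=float)
    if true.shape != est.shape or true.ndim != 1 or len(true) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    denom = float(np.sum((true - true.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("true vector is constant: FVU undefined")
    return float(np.sum((est - true) ** 2) / denom)


def mean_abs_log_ratio(true_rates, est_rates) -> float:
    true = np.asarray(true_rates, dtype=float)
    est = np.asarray(est_rates, dtype=float)
    if true.shape != est.shape or true.ndim != 1 or len(true) < 1:
        raise ValueError("need two equal-length non-empty vectors")
    if (true <= 0).any() or (est <= 0).any():
        raise ValueError("rates must be positive (filter negative estimates "
                         "upstream)")
    return float(np.mean(np.abs(np.log(est / true))))


@dataclass
class ComparisonTable:
    """Matched per-edge and per-gene records plus the two summary metrics."""

    bipartitions: list[frozenset[str]]
    b_true: np.ndarray
    b_est: np.ndarray
    gene_names: list[str]
    r_true: np.ndarray
    r_est: np.ndarray
    n_genes_dropped: int = 0      # genes excluded from MALR (non-positive est)

    @property
    def fvu(self) -> float:
        return fraction_variance_unexplained(self.b_true, self.b_est)

    @property
    def malr(self) -> float:
        keep = self.r_est > 0
        return mean_abs_log_ratio(self.r_true[keep], self.r_est[keep])

    @property
    def branch_errors(self) -> np.ndarray:
        """b_est - b_true, the quantity plotted against true lengths."""
        return self.b_est - self.b_true

    @property
    def rate_ratios(self) -> np.ndarray:
        """r_est / r_true, the quantity shown on log-log rate plots."""
        return self.r_est / self.r_true

    def write_tsv(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# summary\tFVU=%.10g\tMALR=%.10g\n" % (self.fvu, self.malr))
            fh.write("record\tkey\ttrue\testimate\n")
            for split, bt, be in zip(self.bipartitions, self.b_true, self.b_est):
                fh.write(f"edge\t{'|'.join(sorted(split))}\t{bt:.10g}\t{be:.10g}\n")
            for g, rt, re_ in zip(self.gene_names, self.r_true, self.r_est):
                fh.write(f"gene\t{g}\t{rt:.10g}\t{re_:.10g}\n")


def compare(result: ErableResult, replicate: Replicate) -> ComparisonTable:
    """Match the estimate against a replicate's ground truth."""
    return compare_trees_and_rates(
        result.tree.bipartitions(), result.tree.edge_lengths,
        replicate.model_tree.bipartitions(), replicate.model_tree.edge_lengths,
        result.gene_names, result.rates, replicate.model_rates,
    )


def compare_trees_and_rates(
    est_bip: dict[int, frozenset[str]],
    est_lengths: np.ndarray,
    true_bip: dict[int, frozenset[str]],
    true_lengths: np.ndarray,
    gene_names: Sequence[str],
    est_rates,
    true_rates,
) -> ComparisonTable:
    est_map = {split: est_lengths[eid] for eid, split in est_bip.items()}
    true_map = {split: true_lengths[eid] for eid, split in true_bip.items()}
    if set(est_map) != set(true_map):
        missing = sorted(
            "|".join(sorted(s)) for s in set(est_map) ^ set(true_map)
        )
        raise ErableError(f"bipartition mismatch between trees: {missing}")
    splits = sorted(true_map, key=lambda s: sorted(s))
    r_true = np.asarray(true_rates, dtype=float)
    r_est = np.asarray(est_rates, dtype=float)
    if r_true.shape != r_est.shape:
        raise ErableError("rate vectors differ in length")
    dropped = int((r_est <= 0).sum())
    if dropped:
        warnings.warn(
            f"{dropped} gene(s) with non-positive estimated rate excluded "
            f"from the mean absolute log-ratio", stacklevel=2,
        )
    return ComparisonTable(
        bipartitions=list(splits),
        b_true=np.array([true_map[s] for s in splits]),
        b_est=np.array([est_map[s] for s in splits]),
        gene_names=list(gene_names),
        r_true=r_true,
        r_est=r_est,
        n_genes_dropped=dropped,
    )
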