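"""Pairwise evolutionary distances under JC69, K2P and TN93, with an
optional continuous-gamma correction for rate heterogeneity across sites.

All three models have closed-form distance estimators built from pairwise
mismatch fractions. The gamma-corrected variants replace every logarithmic
term ``-ln(x)`` by ``a * (x**(-1/a) - 1)`` where ``a`` is the gamma shape
parameter; as ``a -> inf`` this recovers the log formula, and for fixed
counts the distance decreases monotonically in ``a``. Site pairs where
either sequence has a gap or ambiguity are dropped per pair (pairwise
deletion). Saturated pairs (a log/power argument <= 0) yield an *undefined*
distance (NaN) rather than an error: downstream code excludes such pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from Bio import AlignIO

from .distmat import DistanceMatrix
from .errors import InputFormatError, NoComparableSites

__all__ = [
    "Alignment",
    "PairCounts",
    "pair_counts",
    "model_distance",
    "estimate_matrix",
    "MODELS",
]

logger = logging.getLogger(__name__)

MODELS = ("jc69", "k2p", "tn93")
Model = Literal["jc69", "k2p", "tn93"]

# base codes: A=0, G=1, C=2, T=3 -- the transition partner is code ^ 1
_CODE = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"AGCT", range(4)):
    _CODE[_b] = _c
    _CODE[_b + 32] = _c  # lower case
_PURINE = (0, 1)


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment over the DNA alphabet {A,C,G,T,-,N}."""

    name: str
    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise InputFormatError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise InputFormatError(f"duplicate taxa in alignment {self.name!r}")
        if not self.rows or not self.rows[0]:
            raise InputFormatError("alignment must have at least one column")
        if len({len(r) for r in self.rows}) != 1:
            raise InputFormatError("all rows must have equal length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def subset(self, taxa) -> "Alignment":
        keep = [t for t in self.taxa if t in set(taxa)]
        return Alignment(
            self.name, tuple(keep), tuple(self.row(t) for t in keep)
        )

    @classmethod
    def from_file(cls, path, fmt: str = "fasta", name: str | None = None) -> "Alignment":
        """Read FASTA (``fmt="fasta"``) or sequential PHYLIP
        (``fmt="phylip"``) via Biopython."""
        biofmt = {"fasta": "fasta", "phylip": "phylip-sequential"}.get(fmt)
        if biofmt is None:
            raise InputFormatError(f"unsupported alignment format {fmt!r}")
        try:
            aln = AlignIO.read(str(path), biofmt)
        except Exception as exc:
            raise InputFormatError(f"cannot read {path}: {exc}") from exc
        return cls(
            name or Path(path).stem,
            tuple(rec.id for rec in aln),
            tuple(str(rec.seq) for rec in aln),
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")


@dataclass(frozen=True)
class PairCounts:
    """Mismatch summary for one sequence pair (pairwise deletion applied).

    Fractions are relative to ``valid_sites``; ``p = P + Q`` and
    ``P = P1 + P2`` (purine + pyrimidine transitions). ``freqs`` are the
    empirical base frequencies (A, G, C, T order) averaged over the two
    sequences at valid sites.
    """

    valid_sites: int
    p: float
    P: float
    Q: float
    P1: float
    P2: float
    freqs: tuple[float, float, float, float]


def pair_counts(row_i: str, row_j: str) -> PairCounts:
    """Count mismatch classes between two aligned rows of equal length."""
    if len(row_i) != len(row_j):
        raise InputFormatError("rows must have equal length")
    a = _CODE[np.frombuffer(row_i.encode(), dtype=np.uint8)]
    b = _CODE[np.frombuffer(row_j.encode(), dtype=np.uint8)]
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        raise NoComparableSites("no site where both sequences are determinate")
    a, b = a[ok].astype(np.int64), b[ok].astype(np.int64)
    diff = a != b
    ts = diff & ((a >> 1) == (b >> 1))  # same purine/pyrimidine class
    p1 = int((ts & (a <= 1)).sum())
    p2 = int((ts & (a >= 2)).sum())
    q = int((diff & ~ts).sum())
    counts = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    freqs = tuple((counts / (2.0 * n)).tolist())
    return PairCounts(
        valid_sites=n,
        p=(p1 + p2 + q) / n,
        P=(p1 + p2) / n,
        Q=q / n,
        P1=p1 / n,
        P2=p2 / n,
        freqs=freqs,  # type: ignore[arg-type]
    )


def _nlog(x: float, a: float | None) -> float:
    """-ln(x), or its continuous-gamma analogue a*(x^(-1/a)-1); NaN if x<=0."""
    if x <= 0.0:
        return np.nan
    if a is None:
        return -float(np.log(x))
    return float(a * (x ** (-1.0 / a) - 1.0))


def model_distance(
    counts: PairCounts, model: Model = "tn93", gamma_shape: float | None = None
) -> float:
    """Closed-form distance for one pair; NaN when saturated.

    ``gamma_shape=None`` gives the plain (no rate heterogeneity) formula.
    """
    if model not in MODELS:
        raise InputFormatError(f"unknown model {model!r}")
    if gamma_shape is not None and gamma_shape <= 0:
        raise InputFormatError("gamma_shape must be positive")
    a = gamma_shape
    if model == "jc69":
        return 0.75 * _nlog(1.0 - 4.0 * counts.p / 3.0, a)
    if model == "k2p":
        return 0.5 * _nlog(1.0 - 2.0 * counts.P - counts.Q, a) + 0.25 * _nlog(
            1.0 - 2.0 * counts.Q, a
        )
    # TN93 with empirical base frequencies (averaged over the two sequences)
    pA, pG, pC, pT = counts.freqs
    pR, pY = pA + pG, pC + pT
    P1, P2, Q = counts.P1, counts.P2, counts.Q
    eps = 1e-12
    if pR < eps or pY < eps:
        return np.nan  # single-class composition: transversion term undefined
    total = 0.0
    # purine-transition term
    if pA * pG > eps:
        total += (2.0 * pA * pG / pR) * _nlog(
            1.0 - pR * P1 / (2.0 * pA * pG) - Q / (2.0 * pR), a
        )
    elif P1 > 0:
        return np.nan  # transitions observed within an absent frequency class
    # pyrimidine-transition term
    if pC * pT > eps:
        total += (2.0 * pC * pT / pY) * _nlog(
            1.0 - pY * P2 / (2.0 * pC * pT) - Q / (2.0 * pY), a
        )
    elif P2 > 0:
        return np.nan
    # transversion term
    coeff = 2.0 * (pR * pY - pA * pG * pY / pR - pC * pT * pR / pY)
    if abs(coeff) > eps:
        total += coeff * _nlog(1.0 - Q / (2.0 * pR * pY), a)
    return float(total)


def estimate_matrix(
    aln: Alignment,
    model: Model = "tn93",
    gamma_shape: float | None = 1.0,
    max_distance: float | None = None,
) -> DistanceMatrix:
    """Distance matrix over all unordered taxon pairs of ``aln``.

    Saturated or non-comparable pairs become undefined entries; a summary
    is logged, and a fully-undefined matrix triggers a ``UserWarning``.
    ``max_distance``, when set, additionally marks estimates above that
    ceiling as undefined: gamma-corrected estimators have rapidly exploding
    variance near saturation, and a handful of effectively saturated pairs
    can otherwise dominate downstream least-squares fits.
    """
    if len(aln.taxa) < 2:
        raise InputFormatError("need at least two taxa")
    n = len(aln.taxa)
    vals = np.zeros((n, n))
    n_undef = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = model_distance(pair_counts(aln.rows[i], aln.rows[j]),
                                   model, gamma_shape)
            except NoComparableSites:
                d = np.nan
            if max_distance is not None and d > max_distance:
                d = np.nan
            if np.isnan(d):
                n_undef += 1
            vals[i, j] = vals[j, i] = d
    if n_undef:
        logger.warning(
            "alignment %s: %d of %d pairs undefined (saturated or no "
            "comparable sites)", aln.name, n_undef, n * (n - 1) // 2,
        )
    if n_undef == n * (n - 1) // 2:
        warnings.warn(
            f"alignment {aln.name!r}: every pairwise distance is undefined",
            stacklevel=2,
        )
    return DistanceMatrix(aln.taxa, vals)
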