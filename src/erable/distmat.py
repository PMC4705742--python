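"""Distance matrices with support for undefined (missing) entries.

Entries are stored as floats with ``NaN`` meaning *undefined*: a pair for
which no distance could be estimated (saturation, no comparable sites).
Undefined pairs are first-class citizens here because the solver is designed
for partially overlapping, imperfect data and simply excludes such pairs
from its sums.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import InputFormatError

__all__ = ["DistanceMatrix"]

_SYM_TOL = 1e-9


class DistanceMatrix:
    """Symmetric, hollow matrix of evolutionary distances over labelled taxa.

    Parameters
    ----------
    taxa:
        Ordered taxon labels (unique, non-empty).
    values:
        Square array-like; ``NaN`` marks undefined entries. Must be symmetric
        to within 1e-9 (symmetrized by averaging) with a zero diagonal, and
        defined entries must be finite and non-negative.
    """

    __slots__ = ("taxa", "values", "_index")

    def __init__(self, taxa: Sequence[str], values) -> None:
        taxa = tuple(str(t) for t in taxa)
        if len(set(taxa)) != len(taxa) or any(not t for t in taxa):
            raise InputFormatError("taxon labels must be unique and non-empty")
        vals = np.array(values, dtype=float)
        n = len(taxa)
        if vals.shape != (n, n):
            raise InputFormatError(
                f"expected a {n}x{n} matrix, got shape {vals.shape}"
            )
        both = ~np.isnan(vals) & ~np.isnan(vals.T)
        if both.any() and np.nanmax(np.abs(vals - vals.T)[both], initial=0.0) > _SYM_TOL:
            raise InputFormatError("matrix is not symmetric (tolerance 1e-9)")
        if (np.isnan(vals) != np.isnan(vals.T)).any():
            raise InputFormatError("undefined entries must be symmetric")
        vals = (vals + vals.T) / 2.0  # exact symmetry
        if np.abs(np.diag(vals)).max(initial=0.0) > _SYM_TOL:
            raise InputFormatError("diagonal entries must be zero")
        np.fill_diagonal(vals, 0.0)
        off = ~np.eye(n, dtype=bool)
        defined = off & ~np.isnan(vals)
        if defined.any():
            d = vals[defined]
            if not np.isfinite(d).all() or (d < 0).any():
                raise InputFormatError("defined distances must be finite and >= 0")
        self.taxa = taxa
        self.values = vals
        self._index = {t: i for i, t in enumerate(taxa)}

    # -- basic container protocol ------------------------------------------

    def __len__(self) -> int:
        return len(self.taxa)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.values[self._index[i], self._index[j]])

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DistanceMatrix(n={len(self)}, taxa={self.taxa[:4]}...)"

    def index(self, taxon: str) -> int:
        return self._index[taxon]

    # -- queries ------------------------------------------------------------

    def is_defined(self, i: str, j: str) -> bool:
        return not np.isnan(self.values[self._index[i], self._index[j]])

    def defined_pairs(self) -> Iterator[tuple[str, str, float]]:
        """Yield (taxon_i, taxon_j, distance) over defined unordered pairs."""
        n = len(self.taxa)
        for a in range(n):
            for b in range(a + 1, n):
                v = self.values[a, b]
                if not np.isnan(v):
                    yield self.taxa[a], self.taxa[b], float(v)

    def n_undefined(self) -> int:
        n = len(self.taxa)
        iu = np.triu_indices(n, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def subset(self, taxa: Iterable[str]) -> "DistanceMatrix":
        keep = [t for t in self.taxa if t in set(taxa)]
        idx = [self._index[t] for t in keep]
        return DistanceMatrix(keep, self.values[np.ix_(idx, idx)])

    def drop_all_undefined_taxa(self) -> "DistanceMatrix":
        """Remove taxa whose every off-diagonal entry is undefined."""
        n = len(self.taxa)
        off = ~np.eye(n, dtype=bool)
        has_any = [(~np.isnan(self.values[i][off[i]])).any() for i in range(n)]
        keep = [t for t, ok in zip(self.taxa, has_any) if ok]
        return self.subset(keep)
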