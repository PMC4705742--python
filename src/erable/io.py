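"""File formats tying the pieces into a tool.

The central exchange format is the *multi-matrix* file: a plain-text
container for m per-gene distance matrices with their sequence lengths.
Grammar (whitespace-separated, blank lines between blocks allowed)::

    file      := m_count block{m}
    m_count   := INT                        # number of gene blocks
    block     := name N_k NEWLINE p NEWLINE row{p}
    row       := taxon x_1 ... x_p          # full square matrix row
    x         := REAL | "NA"                # NA = undefined entry

Matrices must be symmetric to 1e-9 (symmetrized by averaging, with a
warning beyond machine noise) with a zero diagonal; reals are written back
with 10 significant digits.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ErableResult, GeneMatrix
from .distmat import DistanceMatrix
from .errors import InputFormatError
from .tree import PhyloTree, parse_newick

__all__ = [
    "read_multimatrix",
    "write_multimatrix",
    "read_topology",
    "write_result",
    "read_truth_table",
]


def read_multimatrix(path) -> list[GeneMatrix]:
    """Parse a multi-matrix file into :class:`GeneMatrix` records."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0

    def next_tokens(what: str) -> tuple[int, list[str]]:
        nonlocal pos
        while pos < len(lines):
            toks = lines[pos].split()
            pos += 1
            if toks:
                return pos, toks
        raise InputFormatError(
            f"{path}: unexpected end of file while reading {what}"
        )

    lineno, toks = next_tokens("the gene count")
    if len(toks) != 1 or not toks[0].isdigit():
        raise InputFormatError(f"{path}:{lineno}: expected a single gene count")
    m = int(toks[0])
    genes: list[GeneMatrix] = []
    for g in range(m):
        lineno, toks = next_tokens(f"header of gene {g + 1}")
        if len(toks) != 2:
            raise InputFormatError(
                f"{path}:{lineno}: expected 'name N_k', got {len(toks)} token(s)"
            )
        name, nk_s = toks
        try:
            nk = int(nk_s)
        except ValueError:
            raise InputFormatError(
                f"{path}:{lineno}: sequence length {nk_s!r} is not an integer"
            ) from None
        lineno, toks = next_tokens(f"taxon count of gene {name!r}")
        if len(toks) != 1 or not toks[0].isdigit():
            raise InputFormatError(f"{path}:{lineno}: expected a taxon count")
        p = int(toks[0])
        taxa: list[str] = []
        rows = np.zeros((p, p))
        for r in range(p):
            lineno, toks = next_tokens(f"row {r + 1} of gene {name!r}")
            if len(toks) != p + 1:
                raise InputFormatError(
                    f"{path}:{lineno}: expected taxon + {p} values, got "
                    f"{len(toks) - 1}"
                )
            taxon = toks[0]
            if taxon in taxa:
                raise InputFormatError(
                    f"{path}:{lineno}: duplicate taxon {taxon!r} in gene {name!r}"
                )
            taxa.append(taxon)
            for c, cell in enumerate(toks[1:]):
                if cell.upper() == "NA":
                    rows[r, c] = np.nan
                else:
                    try:
                        rows[r, c] = float(cell)
                    except ValueError:
                        raise InputFormatError(
                            f"{path}:{lineno}: non-numeric cell {cell!r}"
                        ) from None
        asym = np.nanmax(np.abs(rows - rows.T), initial=0.0)
        if asym > 1e-9:
            raise InputFormatError(
                f"{path}: gene {name!r}: matrix asymmetry {asym:.3g} exceeds 1e-9"
            )
        if asym > 0:
            warnings.warn(
                f"gene {name!r}: matrix symmetrized by averaging "
                f"(max asymmetry {asym:.3g})", stacklevel=2,
            )
        try:
            dm = DistanceMatrix(taxa, rows)
            genes.append(GeneMatrix(name=name, n_sites=nk, delta=dm))
        except Exception as exc:
            raise InputFormatError(f"{path}: gene {name!r}: {exc}") from exc
    # anything non-blank left over means the declared count was wrong
    while pos < len(lines):
        if lines[pos].split():
            raise InputFormatError(
                f"{path}:{pos + 1}: trailing content after the {m} declared genes"
            )
        pos += 1
    return genes


def write_multimatrix(genes: Sequence[GeneMatrix], path) -> None:
    """Inverse of :func:`read_multimatrix` (10 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{len(genes)}\n\n")
        for gene in genes:
            p = len(gene.delta)
            fh.write(f"{gene.name} {gene.n_sites}\n{p}\n")
            for i, taxon in enumerate(gene.delta.taxa):
                cells = [
                    "NA" if np.isnan(x) else f"{x:.10g}"
                    for x in gene.delta.values[i]
                ]
                fh.write(taxon + " " + " ".join(cells) + "\n")
            fh.write("\n")


def read_topology(path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_result(
    result: ErableResult,
    out_tree=None,
    out_rates=None,
    out_summary=None,
    precision: int = 10,
) -> None:
    """Emit the Newick tree, the TSV rate table and the JSON summary."""
    if out_tree is not None:
        Path(out_tree).write_text(result.tree.to_newick(precision) + "\n")
    if out_rates is not None:
        with open(out_rates, "w") as fh:
            fh.write("gene\tN_k\talpha_hat\trate\n")
            for g, nk, a, r in zip(
                result.gene_names, result.n_sites, result.alpha_hat, result.rates
            ):
                fh.write(f"{g}\t{int(nk)}\t{a:.10g}\t{r:.10g}\n")
    if out_summary is not None:
        summary = {
            "Q": result.Q_value,
            "c": result.c,
            "unique": result.unique,
            "n_genes": len(result.gene_names),
            "n_taxa": result.tree.n_leaves,
            "warnings": list(result.warnings),
        }
        if result.identifiability is not None:
            summary["non_cooccurring_pairs"] = [
                list(p) for p in result.identifiability.non_cooccurring_pairs
            ]
        Path(out_summary).write_text(json.dumps(summary, indent=2) + "\n")


def read_truth_table(path) -> dict[str, dict[str, float]]:
    """Read a simulation truth table (gene, t_k, N_k, r_k, n_taxa)."""
    out: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if header[:1] != ["gene"]:
            raise InputFormatError(f"{path}: not a truth table")
        for lineno, line in enumerate(fh, start=2):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != len(header):
                raise InputFormatError(f"{path}:{lineno}: malformed row")
            out[toks[0]] = {
                key: float(val) for key, val in zip(header[1:], toks[1:])
            }
    return out
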