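"""Pathway gene sets and the gene–pathway biadjacency matrix.

The first layer of the network is not learned freely: gene→pathway
connections exist only where a pathway database says the gene is a member
of the pathway.  That membership is encoded as a binary biadjacency matrix
``A`` (pathways × genes, ``a_ij = 1`` iff gene *j* belongs to pathway *i*),
built here from a GMT file intersected with the measured genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike

import numpy as np

__all__ = [
    "PathwayCollection",
    "BiadjacencyMatrix",
    "GMTParseError",
    "EmptyModelError",
    "parse_gmt",
    "build_biadjacency",
]


class GMTParseError(ValueError):
    """Raised for a malformed GMT line or a duplicate pathway name."""


class EmptyModelError(ValueError):
    """Raised when filtering leaves no pathways or no genes."""


@dataclass
class PathwayCollection:
    """Ordered pathway gene sets, as read from a GMT file.

    ``entries`` is an ordered list of ``(pathway_name, gene_symbols)``
    pairs; names are unique and every gene set is non-empty.
    """

    entries: list[tuple[str, set[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [name for name, _ in self.entries]


@dataclass
class BiadjacencyMatrix:
    """Binary pathway × gene incidence matrix with its name lists.

    Rows follow ``pathway_names``, columns follow ``gene_names``.  After
    construction every row sums to at least the size filter and every
    column sums to at least one.
    """

    matrix: np.ndarray
    pathway_names: list[str]
    gene_names: list[str]

    @property
    def n_pathways(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.matrix, index=self.pathway_names, columns=self.gene_names
        )

    def write_tsv(self, path: str | PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t")


def parse_gmt(path: str | PathLike) -> PathwayCollection:
    """Read a GMT file (Broad dialect).

    One pathway per line, tab-separated: name, description, then gene
    symbols.  The description is discarded; duplicate symbols within a
    line collapse.  A line with fewer than three fields, or a repeated
    pathway name, raises :class:`GMTParseError` naming the line number.
    """
    entries: list[tuple[str, set[str]]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in seen:
                raise GMTParseError(f"line {lineno}: duplicate pathway name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise GMTParseError(f"line {lineno}: pathway {name!r} has no genes")
            seen.add(name)
            entries.append((name, genes))
    return PathwayCollection(entries)


def build_biadjacency(
    pathways: PathwayCollection,
    measured_genes: list[str],
    min_pathway_size: int = 10,
) -> BiadjacencyMatrix:
    """Build the filtered biadjacency matrix ``A``.

    Filtering follows the modelling rule that a pathway is usable only
    through its measured genes: each pathway is first intersected with
    ``measured_genes``; pathways with fewer than ``min_pathway_size``
    measured genes are dropped; finally, genes belonging to no retained
    pathway are dropped (their column would be all-zero and the gene could
    never reach the pathway layer).  Gene columns keep the order of
    ``measured_genes``; pathway rows keep GMT order.  Matching of gene
    symbols is exact and case-sensitive.
    """
    if min_pathway_size < 1:
        raise ValueError("min_pathway_size must be >= 1")
    if len(set(measured_genes)) != len(measured_genes):
        raise ValueError("measured_genes contains duplicates")

    measured = set(measured_genes)
    kept: list[tuple[str, set[str]]] = []
    for name, genes in pathways.entries:
        usable = genes & measured
        if len(usable) >= min_pathway_size:
            kept.append((name, usable))
    if not kept:
        raise EmptyModelError(
            f"no pathway retains >= {min_pathway_size} measured genes"
        )

    covered = set().union(*(g for _, g in kept))
    gene_names = [g for g in measured_genes if g in covered]
    if not gene_names:
        raise EmptyModelError("no measured gene belongs to a retained pathway")

    col = {g: j for j, g in enumerate(gene_names)}
    A = np.zeros((len(kept), len(gene_names)), dtype=np.int8)
    for i, (_, genes) in enumerate(kept):
        for g in genes:
            A[i, col[g]] = 1
    return BiadjacencyMatrix(A, [name for name, _ in kept], gene_names)
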