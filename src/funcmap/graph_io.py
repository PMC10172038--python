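"""Reading, writing and filtering of gene networks and gene annotations.

Networks are undirected simple graphs over opaque gene-identifier strings.
A :class:`Network` carries an explicit, lexicographically sorted node order:
this order fixes the row/column order of every matrix derived downstream
(adjacency, PPMI, factor matrices), so results are independent of the line
order of the input files.

Annotations (e.g. Gene Ontology Biological Process terms) are kept as a set
of (annotation id, gene id) pairs in an :class:`AnnotationTable` and turned
into a binary annotation x gene incidence matrix with
:func:`annotation_matrix`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "ParseError",
    "DataError",
    "Network",
    "AnnotationTable",
    "AnnotationMatrix",
    "read_edge_list",
    "write_edge_list",
    "read_gene_list",
    "build_tissue_network",
    "read_annotations",
    "write_annotations",
    "annotation_matrix",
]


class ParseError(ValueError):
    """A file could not be parsed under the declared format."""


class DataError(ValueError):
    """Inputs are syntactically valid but scientifically unusable."""


def _canon_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Network:
    """Undirected simple graph with a stable (sorted) node order.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node, and ``nodes`` is sorted lexicographically.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise DataError("duplicate node identifiers")
        if list(self.nodes) != sorted(self.nodes):
            raise DataError("node order must be lexicographically sorted")
        for u, v in self.edges:
            if u == v:
                raise DataError(f"self-loop on {u!r}")
            if (u, v) != _canon_edge(u, v):
                raise DataError("edges must be canonically ordered pairs")
            if u not in node_set or v not in node_set:
                raise DataError(f"edge endpoint not in node list: {u!r}-{v!r}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] | None = None
    ) -> "Network":
        """Build a network from an edge iterable, dropping self-loops.

        When ``nodes`` is omitted the node set is the set of endpoints of
        the retained edges (isolated nodes cannot arise from an edge list).
        """
        canon = {_canon_edge(u, v) for u, v in edges if u != v}
        if nodes is None:
            node_tuple = tuple(sorted({n for e in canon for n in e}))
        else:
            node_tuple = tuple(sorted(set(nodes)))
        return cls(nodes=node_tuple, edges=frozenset(canon))

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        net = cls.from_edges(g.edges(), nodes=g.nodes())
        return net

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        # sorted: adjacency-list order must not depend on set hash order,
        # or seeded algorithms downstream (e.g. edge swaps) lose determinism
        g.add_edges_from(sorted(self.edges))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix in node order."""
        idx = self.index()
        a = np.zeros((self.n_nodes, self.n_nodes))
        for u, v in self.edges:
            a[idx[u], idx[v]] = 1.0
            a[idx[v], idx[u]] = 1.0
        return a

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1)


def read_edge_list(path: str | Path, delimiter: str | None = None) -> Network:
    """Read an undirected edge list (two id columns per line).

    ``delimiter=None`` splits on any whitespace (covers both TSV and
    space-separated files). Lines starting with ``#`` and blank lines are
    ignored; extra columns beyond the first two are ignored. Self-loops are
    dropped and duplicate edges (in either orientation) collapse to one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 fields, got {len(fields)}")
            edges.append((fields[0], fields[1]))
    return Network.from_edges(edges)


def write_edge_list(network: Network, path: str | Path, delimiter: str = "\t") -> None:
    """Write the edge list (sorted for reproducibility) plus a node manifest."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}{delimiter}{v}\n")
    manifest = path.with_suffix(path.suffix + ".manifest.json")
    manifest.write_text(
        json.dumps({"nodes": list(network.nodes), "n_edges": network.n_edges}, indent=1)
    )


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-gene-per-line list (e.g. tissue-expressed genes)."""
    path = Path(path)
    genes = {
        line.strip() for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    if not genes:
        raise DataError(f"{path}: no gene identifiers found")
    return genes


def build_tissue_network(generic: Network, expressed: set[str]) -> Network:
    """Induce the subnetwork on expressed genes, dropping isolated genes.

    Mirrors tissue-specific network construction: keep a gene only if it is
    expressed in the tissue *and* retains at least one interaction after
    induction.
    """
    if not expressed:
        raise DataError("expressed gene set is empty")
    keep = expressed & set(generic.nodes)
    if not keep:
        raise DataError("no expressed gene appears in the generic network")
    edges = [(u, v) for u, v in generic.edges if u in keep and v in keep]
    if not edges:
        raise DataError("induced tissue network has no interactions")
    # isolated-after-induction genes vanish because nodes derive from edges
    return Network.from_edges(edges)


@dataclass(frozen=True)
class AnnotationTable:
    """Deduplicated (annotation id, gene id) pairs with sorted id lists."""

    pairs: frozenset[tuple[str, str]]
    annotation_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationTable":
        pset = frozenset(pairs)
        if not pset:
            raise DataError("annotation table has no pairs")
        return cls(
            pairs=pset,
            annotation_ids=tuple(sorted({a for a, _ in pset})),
            gene_ids=tuple(sorted({g for _, g in pset})),
        )

    def genes_of(self, annotation: str) -> set[str]:
        return {g for a, g in self.pairs if a == annotation}

    def annotations_of(self, gene: str) -> set[str]:
        return {a for a, g in self.pairs if g == gene}


# column layout of GAF 2.x: 1=DB, 2=object id, 3=symbol, 4=qualifier,
# 5=GO id, ... 9=aspect (P/F/C)
_GAF_GO_COL = 4
_GAF_ASPECT_COL = 8
_GAF_SYMBOL_COL = 2


def read_annotations(path: str | Path, dialect: str = "two-column-tsv") -> AnnotationTable:
    """Read gene annotations.

    ``two-column-tsv``: annotation id <tab> gene id. ``gaf``: GAF 2.x rows,
    keeping only aspect ``P`` (biological process) and using the object
    symbol column as the gene id.
    """
    path = Path(path)
    if dialect not in {"two-column-tsv", "gaf"}:
        raise ParseError(f"unknown annotation dialect: {dialect!r}")
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "!")):
                continue
            fields = line.split("\t")
            if dialect == "two-column-tsv":
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
                pairs.append((fields[0].strip(), fields[1].strip()))
            else:
                if len(fields) <= _GAF_ASPECT_COL:
                    raise ParseError(f"{path}:{lineno}: truncated GAF row")
                if fields[_GAF_ASPECT_COL].strip() != "P":
                    continue
                pairs.append(
                    (fields[_GAF_GO_COL].strip(), fields[_GAF_SYMBOL_COL].strip())
                )
    if not pairs:
        raise DataError(f"{path}: no annotation pairs retained")
    return AnnotationTable.from_pairs(pairs)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for a, g in sorted(table.pairs):
            fh.write(f"{a}\t{g}\n")


@dataclass(frozen=True)
class AnnotationMatrix:
    """Binary annotation x gene incidence matrix A with aligned id lists."""

    values: np.ndarray
    annotation_order: tuple[str, ...]
    gene_order: tuple[str, ...]

    def __post_init__(self) -> None:
        m, n = self.values.shape
        if m != len(self.annotation_order) or n != len(self.gene_order):
            raise DataError("annotation matrix shape does not match id lists")


def annotation_matrix(
    table: AnnotationTable,
    gene_order: Iterable[str],
    min_genes: int = 1,
) -> AnnotationMatrix:
    """Build the binary incidence matrix A over a fixed gene order.

    Annotations annotating fewer than ``min_genes`` genes of ``gene_order``
    are dropped (default 1, i.e. only annotations absent from the network
    are dropped).
    """
    gene_order = tuple(gene_order)
    if not gene_order:
        raise DataError("gene_order is empty")
    gidx = {g: i for i, g in enumerate(gene_order)}
    rows: list[tuple[str, np.ndarray]] = []
    for ann in table.annotation_ids:
        row = np.zeros(len(gene_order))
        count = 0
        for g in table.genes_of(ann):
            if g in gidx:
                row[gidx[g]] = 1.0
                count += 1
        if count >= min_genes:
            rows.append((ann, row))
    if not rows:
        raise DataError("no annotation survives the min_genes filter")
    order = tuple(a for a, _ in rows)
    values = np.vstack([r for _, r in rows])
    return AnnotationMatrix(values=values, annotation_order=order, gene_order=gene_order)
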