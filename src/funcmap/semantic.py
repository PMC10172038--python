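"""Ontology handling and Lin's semantic similarity.

Terms live in a directed acyclic graph of ``is_a`` links (e.g. the Gene
Ontology restricted to one namespace). The information content (IC) of a
term is derived from an annotation corpus after propagating every gene's
annotations to all ancestors:

    p(t)  = (number of genes annotated to t or any of its descendants)
            / (number of genes annotated to t's namespace root)
    IC(t) = -ln p(t)

so the root has IC 0 and IC grows towards the leaves. Lin's similarity of
two terms is

    sim(t1, t2) = 2 IC(MICA) / (IC(t1) + IC(t2))

where MICA is the common ancestor with maximal IC; terms with no common
ancestor (different namespaces) have similarity 0, as do pairs whose
denominator is 0 (both terms as general as the root).

Only ``is_a`` links are traversed; other relations (part_of, regulates)
are ignored, and obsolete terms are dropped on parse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import obonet

from .graph_io import AnnotationTable, DataError

__all__ = ["Ontology", "ICTable", "information_content", "lin_similarity", "mean_pairwise_lin"]


@dataclass(frozen=True)
class Ontology:
    """Acyclic is_a hierarchy with per-term namespaces."""

    parents: dict  # term -> frozenset of direct is_a parents
    namespace: dict  # term -> namespace string

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise DataError(f"parent {p!r} of {child!r} is not a term")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise DataError("is_a graph contains a cycle")

    @property
    def terms(self) -> frozenset:
        return frozenset(self.parents)

    @property
    def roots(self) -> frozenset:
        return frozenset(t for t, ps in self.parents.items() if not ps)

    def ancestors(self, term: str) -> set:
        """All is_a ancestors of a term, including the term itself."""
        if term not in self.parents:
            raise DataError(f"unknown term {term!r}")
        out: set = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.parents[t])
        return out

    def namespace_root(self, term: str) -> str:
        ns = self.namespace.get(term)
        roots = [r for r in self.ancestors(term) if not self.parents[r]]
        same_ns = [r for r in roots if self.namespace.get(r) == ns]
        return sorted(same_ns or roots)[0]

    @classmethod
    def from_edges(
        cls, is_a_edges: list[tuple[str, str]], namespace: dict | None = None
    ) -> "Ontology":
        """Build from (child, parent) is_a pairs; parents without rows become roots."""
        parents: dict = {}
        for child, parent in is_a_edges:
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
        parents = {t: frozenset(ps) for t, ps in parents.items()}
        ns = dict(namespace or {})
        return cls(parents=parents, namespace=ns)

    @classmethod
    def from_obo(cls, path: str | Path) -> "Ontology":
        """Parse an OBO 1.2/1.4 file (obsolete terms are skipped by the parser)."""
        graph = obonet.read_obo(str(path))
        parents: dict = {}
        namespace: dict = {}
        for term, data in graph.nodes(data=True):
            ps = {
                parent
                for _, parent, key in graph.out_edges(term, keys=True)
                if key == "is_a"
            }
            parents[term] = frozenset(ps)
            namespace[term] = data.get("namespace", "default")
        return cls(parents=parents, namespace=namespace)

    def to_obo(self, path: str | Path) -> None:
        """Write a minimal OBO 1.2 file (id, namespace, is_a only)."""
        lines = ["format-version: 1.2", "ontology: funcmap-toy", ""]
        for term in sorted(self.parents):
            lines.append("[Term]")
            lines.append(f"id: {term}")
            lines.append(f"name: {term}")
            ns = self.namespace.get(term)
            if ns:
                lines.append(f"namespace: {ns}")
            for p in sorted(self.parents[term]):
                lines.append(f"is_a: {p} ! {p}")
            lines.append("")
        Path(path).write_text("\n".join(lines))


@dataclass(frozen=True)
class ICTable:
    """Information content per term plus the size of the annotated corpus."""

    ic: dict  # term -> non-negative float
    corpus_size: int  # number of distinct annotated genes after propagation


def information_content(ont: Ontology, table: AnnotationTable) -> ICTable:
    """Corpus-based information content with ancestor propagation.

    Terms in the table but absent from the ontology are dropped with a
    warning; an empty overlap is an error.
    """
    known = ont.terms
    unknown = {a for a, _ in table.pairs} - known
    if unknown:
        warnings.warn(f"{len(unknown)} annotation terms absent from the ontology; dropped")
    gene_terms: dict = {}
    for a, g in table.pairs:
        if a in known:
            gene_terms.setdefault(g, set()).add(a)
    if not gene_terms:
        raise DataError("no annotation term overlaps the ontology")
    counts: dict = {}
    for g, terms in gene_terms.items():
        propagated: set = set()
        for t in terms:
            propagated |= ont.ancestors(t)
        for t in propagated:
            counts[t] = counts.get(t, 0) + 1
    ic: dict = {}
    for t, c in counts.items():
        root = ont.namespace_root(t)
        root_count = counts.get(root, 0)
        if root_count == 0:
            continue
        ic[t] = -math.log(c / root_count)
    return ICTable(ic=ic, corpus_size=len(gene_terms))


def lin_similarity(t1: str, t2: str, ic: ICTable, ont: Ontology) -> float:
    """Lin's similarity 2 IC(MICA) / (IC(t1) + IC(t2)), in [0, 1]."""
    for t in (t1, t2):
        if t not in ic.ic:
            raise DataError(f"term {t!r} has no information content")
    common = ont.ancestors(t1) & ont.ancestors(t2)
    common = {t for t in common if t in ic.ic}
    if not common:
        return 0.0
    # ties on IC broken lexicographically; the value is identical either way
    mica = min(common, key=lambda t: (-ic.ic[t], t))
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0:
        return 0.0
    return float(2.0 * ic.ic[mica] / denom)


def mean_pairwise_lin(
    set_a: set | list, set_b: set | list, ic: ICTable, ont: Ontology
) -> float:
    """Mean Lin similarity over the cross product of two term sets.

    When the two sets are identical, self-pairs are excluded; if that
    leaves no pairs, an error is raised.
    """
    a = sorted(set(set_a))
    b = sorted(set(set_b))
    if not a or not b:
        raise DataError("term sets must be non-empty")
    same = set(a) == set(b)
    vals = [
        lin_similarity(t1, t2, ic, ont)
        for t1 in a
        for t2 in b
        if not (same and t1 == t2)
    ]
    if not vals:
        raise DataError("no term pairs to average over")
    return float(sum(vals) / len(vals))
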