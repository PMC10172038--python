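"""Shared fixtures: small deterministic networks, ontologies and scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from funcmap.graph_io import AnnotationTable, Network
from funcmap.semantic import Ontology, information_content
from funcmap.synthetic import make_scenario


@pytest.fixture(scope="session")
def scenario():
    """One full control/case scenario reused by the slower integration tests."""
    return make_scenario(seed=11)


@pytest.fixture()
def path_graph():
    """A - B - C path."""
    return Network.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture()
def toy_dag():
    """root -> {a, b}; genes g1,g2 -> a, g3 -> b."""
    ont = Ontology.from_edges(
        [("a", "root"), ("b", "root")],
        namespace={"root": "bp", "a": "bp", "b": "bp"},
    )
    table = AnnotationTable.from_pairs([("a", "g1"), ("a", "g2"), ("b", "g3")])
    return ont, table


@pytest.fixture()
def toy_ic(toy_dag):
    ont, table = toy_dag
    return information_content(ont, table)


def nonneg_orthonormal(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Random non-negative column-orthonormal matrix (disjoint column supports)."""
    rng = np.random.default_rng(seed)
    cols = rng.integers(0, k, size=n)
    # make sure every column owns at least one row
    cols[:k] = np.arange(k)
    q = np.zeros((n, k))
    q[np.arange(n), cols] = rng.uniform(0.5, 2.0, size=n)
    q /= np.linalg.norm(q, axis=0, keepdims=True)
    return q
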