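"""Synthetic desk-scale scenarios with the structure the method assumes.

Real inputs to this kind of analysis are a tissue-specific protein
interaction network, its condition-specific (e.g. cancer) twin, and Gene
Ontology annotations. The generator emulates their load-bearing features:

* a modular control network (planted-partition / stochastic block model,
  connected by construction);
* annotation terms that preferentially annotate the genes of one module,
  under a toy two-level ontology (one root, one mid-level parent per
  module, terms as leaves) so Lin similarity has non-trivial structure:
  same-module terms share a parent and are semantically similar,
  cross-module terms only meet at the root;
* a degree-preserving rewired null twin (for "no functional organization"
  baselines);
* a perturbed case twin in which the edges incident to selected target
  modules are rewired by degree-preserving swaps while the internal edges
  of all other modules are left untouched — the annotations of the target
  modules are the ground-truth "shifted" functions and their genes the
  ground-truth condition-related genes.

All randomness flows from one integer seed; each stage derives its own
substream as ``seed + stage offset``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_io import AnnotationTable, DataError, Network
from .semantic import Ontology

__all__ = [
    "CORPUS_ANNOTATIONS",
    "planted_partition_network",
    "module_annotations",
    "rewire_network",
    "perturb_case",
    "SyntheticScenario",
    "make_scenario",
]

# Annotation regimes. The default (dense) regime emulates coherent cellular
# processes: few terms per module, each annotating most of the module -- the
# setting of the perturbation-recovery scenario. CORPUS_ANNOTATIONS emulates
# a genome-wide annotation corpus: many small terms partitioning each module
# with little redundancy -- the setting for functional-organization baselines
# (a degree-preserving rewired network must score fold ~= 1 there, which
# requires that related terms not share most of their genes).
CORPUS_ANNOTATIONS = {"terms_per_module": 10, "coverage": 0.1, "leak": 0.02}

# per-stage seed offsets (documented splitting rule: stage_seed = seed + offset)
_SEED_NETWORK = 0
_SEED_ANNOTATIONS = 1
_SEED_PERTURB = 2
_SEED_REWIRE = 3


def planted_partition_network(
    n_modules: int = 5,
    module_size: int = 30,
    p_in: float = 0.3,
    p_out: float = 0.01,
    seed: int = 0,
) -> tuple[Network, dict]:
    """Planted-partition (stochastic block model) network with a module map.

    Within-module edges appear with probability ``p_in``, between-module
    edges with ``p_out`` (0 <= p_out < p_in <= 1). Connectivity is
    guaranteed by adding a spanning cycle over modules and attaching any
    isolated gene to a random module mate. Returns the network and a
    gene -> module-index map.
    """
    if not (0 <= p_out < p_in <= 1):
        raise DataError("need 0 <= p_out < p_in <= 1")
    if n_modules < 2 or module_size < 2:
        raise DataError("need at least 2 modules of at least 2 genes")
    rng = np.random.default_rng(seed)
    n = n_modules * module_size
    genes = [f"g{i:04d}" for i in range(n)]
    module_of = {g: i // module_size for i, g in enumerate(genes)}
    edges: set = set()
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if module_of[genes[i]] == module_of[genes[j]] else p_out
            if rng.random() < p:
                edges.add((genes[i], genes[j]))
    # spanning cycle over modules keeps the graph in one component
    for m in range(n_modules):
        a = genes[m * module_size]
        b = genes[((m + 1) % n_modules) * module_size]
        edges.add(tuple(sorted((a, b))))
    # attach any isolated gene to a random gene of its own module
    touched = {g for e in edges for g in e}
    for g in genes:
        if g not in touched:
            mates = [h for h in genes if module_of[h] == module_of[g] and h != g]
            partner = mates[int(rng.integers(len(mates)))]
            edges.add(tuple(sorted((g, partner))))
    return Network.from_edges(edges, nodes=genes), module_of


def module_annotations(
    module_of: dict,
    terms_per_module: int = 4,
    coverage: float = 0.75,
    leak: float = 0.05,
    seed: int = 0,
) -> tuple[AnnotationTable, Ontology, dict]:
    """Module-aligned annotation terms under a toy two-level ontology.

    Each term annotates a fraction ``coverage`` of one module's genes plus
    a fraction ``leak`` of the remaining genes. Same-module terms draw
    their genes from a common shuffled pool without replacement, so their
    gene sets are disjoint whenever ``terms_per_module * coverage <= 1``:
    semantic relatedness between same-module terms is then expressed only
    through the network (their genes interact), not through shared gene
    identity — a randomized network must wash it out, as in a real
    annotation corpus. The ontology has a single root, one mid-level
    parent per module, and the terms as leaves, so same-module terms have
    a more informative common ancestor than cross-module terms. Returns
    (table, ontology, term -> module map).
    """
    if not (0 < coverage <= 1):
        raise DataError("coverage must be in (0, 1]")
    if not (0 <= leak < 1):
        raise DataError("leak must be in [0, 1)")
    rng = np.random.default_rng(seed)
    modules = sorted(set(module_of.values()))
    genes_by_module = {m: sorted(g for g, mm in module_of.items() if mm == m) for m in modules}
    pairs: list[tuple[str, str]] = []
    term_module: dict = {}
    edges: list[tuple[str, str]] = []
    namespace: dict = {"ROOT": "biological_process"}
    for m in modules:
        parent = f"MOD:{m:02d}"
        edges.append((parent, "ROOT"))
        namespace[parent] = "biological_process"
        own = genes_by_module[m]
        others = sorted(g for g in module_of if module_of[g] != m)
        n_own = max(1, round(coverage * len(own)))
        n_leak = round(leak * len(others))
        # corpus-like regime: when a module's terms fit side by side, carve
        # them as disjoint slices of one shuffled pool (no gene shared by
        # two same-module terms); otherwise sample each term independently
        disjoint = terms_per_module * n_own <= len(own)
        if disjoint:
            pool = [own[i] for i in rng.permutation(len(own))]
        for t in range(terms_per_module):
            term = f"TERM:{m:02d}:{t:02d}"
            term_module[term] = m
            edges.append((term, parent))
            namespace[term] = "biological_process"
            if disjoint:
                picked = pool[t * n_own : (t + 1) * n_own]
            else:
                chosen = rng.choice(len(own), size=n_own, replace=False)
                picked = [own[i] for i in chosen]
            pairs.extend((term, g) for g in picked)
            if n_leak:
                chosen_out = rng.choice(len(others), size=n_leak, replace=False)
                pairs.extend((term, others[i]) for i in chosen_out)
    table = AnnotationTable.from_pairs(pairs)
    ontology = Ontology.from_edges(edges, namespace=namespace)
    return table, ontology, term_module


def rewire_network(network: Network, n_swaps: int | None = None, seed: int = 0) -> Network:
    """Degree-preserving double-edge-swap randomization.

    Default ``n_swaps`` is 10x the edge count. If no further swap can be
    found (e.g. complete graphs), the partially rewired network is
    returned with a warning. The degree sequence is preserved exactly.
    """
    g = network.to_networkx()
    if network.n_edges < 2:
        raise DataError("need at least 2 edges to rewire")
    if n_swaps is None:
        n_swaps = 10 * network.n_edges
    try:
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed)
    except nx.NetworkXError as exc:
        warnings.warn(f"partial rewiring only: {exc}")
    except nx.NetworkXAlgorithmError as exc:
        warnings.warn(f"partial rewiring only: {exc}")
    return Network.from_networkx(g)


def perturb_case(
    network: Network,
    module_of: dict,
    target_modules: set | list,
    intensity: float = 0.75,
    seed: int = 0,
) -> Network:
    """Rewire a fraction of the edges incident to the target modules.

    Degree-preserving double-edge swaps pair a target-incident edge with
    an inter-module edge, so target-internal edges are genuinely re-routed
    to random positions elsewhere in the network (not merely shuffled
    inside the module) while the internal edges of every untouched module
    stay bit-identical between control and case. ``intensity`` is the
    fraction of target-incident edges rewired.
    """
    targets = set(target_modules)
    unknown = targets - set(module_of.values())
    if not targets:
        raise DataError("target_modules is empty")
    if unknown:
        raise DataError(f"unknown target modules: {sorted(unknown)}")
    if not (0 < intensity <= 1):
        raise DataError("intensity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    edges = set(network.edges)

    def in_target(g: str) -> bool:
        return module_of.get(g) in targets

    def is_cross(e: tuple[str, str]) -> bool:
        return module_of.get(e[0]) != module_of.get(e[1])

    # sorted: edge-set iteration order must not leak into the rng stream
    incident = sorted(e for e in edges if in_target(e[0]) or in_target(e[1]))
    cross = sorted(e for e in edges if is_cross(e))
    if len(incident) < 2:
        raise DataError("fewer than 2 edges incident to the target modules")
    n_swaps = max(1, round(intensity * len(incident) / 2))
    done = 0
    attempts = 0
    max_attempts = 200 * n_swaps
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        e1 = incident[int(rng.integers(len(incident)))]
        e2 = cross[int(rng.integers(len(cross)))]
        if e1 == e2 or e1 not in edges or e2 not in edges:
            incident = sorted(e for e in edges if in_target(e[0]) or in_target(e[1]))
            cross = sorted(e for e in edges if is_cross(e))
            continue
        a, b = e1 if in_target(e1[0]) else (e1[1], e1[0])
        c, d = e2 if rng.random() < 0.5 else (e2[1], e2[0])
        if len({a, b, c, d}) < 4:
            continue
        new1, new2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        # new1 touches the target via a; new2 must not become internal to
        # an untouched module (c and b both outside, same module)
        if new1 in edges or new2 in edges:
            continue
        if not (in_target(c) or in_target(b) or is_cross(new2)):
            continue
        edges -= {e1, e2}
        edges |= {new1, new2}
        for pool, pred in ((incident, lambda e: in_target(e[0]) or in_target(e[1])),
                           (cross, is_cross)):
            for e in (e1, e2):
                if e in pool:
                    pool.remove(e)
            for e in (new1, new2):
                if pred(e) and e not in pool:
                    pool.append(e)
        done += 1
    if done < n_swaps:
        warnings.warn(f"only {done} of {n_swaps} perturbation swaps succeeded")
    return Network.from_edges(edges, nodes=network.nodes)


@dataclass(frozen=True)
class SyntheticScenario:
    """A control/case network pair with annotations and ground truth."""

    control: Network
    case: Network
    annotations: AnnotationTable
    ontology: Ontology
    module_of: dict  # gene -> module index
    term_module: dict  # term -> module index
    perturbed_modules: tuple[int, ...]
    seed: int

    @property
    def perturbed_terms(self) -> frozenset:
        return frozenset(t for t, m in self.term_module.items() if m in self.perturbed_modules)

    @property
    def perturbed_genes(self) -> frozenset:
        return frozenset(g for g, m in self.module_of.items() if m in self.perturbed_modules)


def make_scenario(
    seed: int = 0,
    n_modules: int = 5,
    module_size: int = 30,
    p_in: float = 0.3,
    p_out: float = 0.01,
    terms_per_module: int = 4,
    coverage: float = 0.75,
    leak: float = 0.05,
    n_perturbed_modules: int = 1,
    intensity: float = 0.75,
) -> SyntheticScenario:
    """Full control/case scenario, reproducible from the seed alone."""
    control, module_of = planted_partition_network(
        n_modules, module_size, p_in, p_out, seed=seed + _SEED_NETWORK
    )
    table, ontology, term_module = module_annotations(
        module_of, terms_per_module, coverage, leak, seed=seed + _SEED_ANNOTATIONS
    )
    targets = tuple(range(n_perturbed_modules))
    case = perturb_case(
        control, module_of, set(targets), intensity=intensity, seed=seed + _SEED_PERTURB
    )
    return SyntheticScenario(
        control=control,
        case=case,
        annotations=table,
        ontology=ontology,
        module_of=module_of,
        term_module=term_module,
        perturbed_modules=targets,
        seed=seed,
    )
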