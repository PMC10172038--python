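"""Synthetic scenario generators: planted structure, rewiring, perturbation."""

import numpy as np
import pytest

from funcmap.graph_io import DataError, Network
from funcmap.semantic import information_content, mean_pairwise_lin
from funcmap.synthetic import (
    CORPUS_ANNOTATIONS,
    make_scenario,
    module_annotations,
    perturb_case,
    planted_partition_network,
    rewire_network,
)


class TestPlantedPartition:
    def test_extreme_probabilities_give_near_cliques(self):
        net, module_of = planted_partition_network(
            n_modules=2, module_size=4, p_in=1.0, p_out=0.0, seed=0
        )
        by_mod = {0: [], 1: []}
        for g, m in module_of.items():
            by_mod[m].append(g)
        for genes in by_mod.values():
            for i, u in enumerate(genes):
                for v in genes[i + 1 :]:
                    assert tuple(sorted((u, v))) in net.edges

    def test_seed_reproducibility(self):
        a, _ = planted_partition_network(seed=9)
        b, _ = planted_partition_network(seed=9)
        assert a.edges == b.edges

    def test_expected_edge_count(self):
        n_modules, size, p_in, p_out = 4, 25, 0.3, 0.02
        counts = []
        for s in range(5):
            net, _ = planted_partition_network(n_modules, size, p_in, p_out, seed=s)
            counts.append(net.n_edges)
        n_in = n_modules * size * (size - 1) / 2
        n_out = (n_modules * size) ** 2 / 2 - n_modules * size**2 / 2
        expect = n_in * p_in + n_out * p_out
        sd = np.sqrt(n_in * p_in * (1 - p_in) + n_out * p_out * (1 - p_out))
        # spanning cycle / isolation fixes add only a handful of edges
        assert abs(np.mean(counts) - expect) < 3 * sd + n_modules

    def test_connected_and_no_isolates(self):
        net, _ = planted_partition_network(p_in=0.15, p_out=0.0, seed=3)
        assert net.degrees().min() >= 1
        import networkx as nx

        assert nx.is_connected(net.to_networkx())

    def test_invalid_probabilities(self):
        with pytest.raises(DataError):
            planted_partition_network(p_in=0.2, p_out=0.3)


class TestModuleAnnotations:
    @pytest.fixture()
    def module_map(self):
        _, module_of = planted_partition_network(n_modules=3, module_size=10, seed=1)
        return module_of

    def test_leak_zero_terms_are_module_pure(self, module_map):
        table, _, term_module = module_annotations(module_map, leak=0.0, seed=2)
        for term, mod in term_module.items():
            for g in table.genes_of(term):
                assert module_map[g] == mod

    def test_full_coverage_row_sums(self, module_map):
        table, _, _ = module_annotations(module_map, coverage=1.0, leak=0.0, seed=3)
        for ann in table.annotation_ids:
            assert len(table.genes_of(ann)) == 10

    def test_same_module_terms_more_similar_than_cross_module(self, module_map):
        table, ont, term_module = module_annotations(module_map, seed=4)
        ic = information_content(ont, table)
        by_mod = {}
        for t, m in term_module.items():
            by_mod.setdefault(m, []).append(t)
        intra = mean_pairwise_lin(set(by_mod[0]), set(by_mod[0]), ic, ont)
        inter = mean_pairwise_lin(set(by_mod[0]), set(by_mod[1]), ic, ont)
        assert intra > inter

    def test_corpus_regime_partitions_modules(self, module_map):
        table, _, term_module = module_annotations(
            module_map, terms_per_module=5, coverage=0.2, leak=0.0, seed=5
        )
        for mod in range(3):
            terms = [t for t, m in term_module.items() if m == mod]
            gene_sets = [table.genes_of(t) for t in terms]
            for i, a in enumerate(gene_sets):
                for b in gene_sets[i + 1 :]:
                    assert not a & b  # disjoint slices

    def test_invalid_parameters(self, module_map):
        with pytest.raises(DataError):
            module_annotations(module_map, coverage=0.0)
        with pytest.raises(DataError):
            module_annotations(module_map, leak=1.0)


class TestRewireNetwork:
    def test_degree_sequence_preserved(self):
        net, _ = planted_partition_network(seed=6)
        rw = rewire_network(net, seed=7)
        assert sorted(net.degrees()) == sorted(rw.degrees())
        assert rw.nodes == net.nodes

    def test_complete_graph_unchanged_with_warning(self):
        import itertools

        k4 = Network.from_edges(itertools.combinations("ABCD", 2))
        with pytest.warns(UserWarning, match="partial"):
            rw = rewire_network(k4, seed=0)
        assert rw.edges == k4.edges

    def test_seed_reproducibility(self):
        net, _ = planted_partition_network(seed=8)
        assert rewire_network(net, seed=5).edges == rewire_network(net, seed=5).edges

    def test_actually_randomizes(self):
        net, _ = planted_partition_network(seed=10)
        rw = rewire_network(net, seed=11)
        assert len(rw.edges & net.edges) < 0.5 * net.n_edges


class TestPerturbCase:
    def test_untouched_module_internals_identical(self, scenario):
        tg = scenario.perturbed_genes
        mod = scenario.module_of

        def internal_untouched(net):
            return {
                e
                for e in net.edges
                if e[0] not in tg and e[1] not in tg and mod[e[0]] == mod[e[1]]
            }

        assert internal_untouched(scenario.control) == internal_untouched(scenario.case)

    def test_degree_sequence_preserved(self, scenario):
        assert sorted(scenario.control.degrees()) == sorted(scenario.case.degrees())

    def test_target_module_rewired(self, scenario):
        tg = scenario.perturbed_genes
        ctrl = {e for e in scenario.control.edges if e[0] in tg or e[1] in tg}
        case = {e for e in scenario.case.edges if e[0] in tg or e[1] in tg}
        assert len(ctrl & case) < len(ctrl)

    def test_unknown_module_errors(self):
        net, module_of = planted_partition_network(seed=12)
        with pytest.raises(DataError):
            perturb_case(net, module_of, {99})

    def test_minimal_intensity_changes_little(self):
        net, module_of = planted_partition_network(seed=13)
        case = perturb_case(net, module_of, {0}, intensity=0.01, seed=14)
        assert len(case.edges & net.edges) > 0.95 * net.n_edges


class TestScenario:
    def test_reproducible_from_seed(self):
        a = make_scenario(seed=3)
        b = make_scenario(seed=3)
        assert a.control.edges == b.control.edges
        assert a.case.edges == b.case.edges
        assert a.annotations.pairs == b.annotations.pairs

    def test_ground_truth_consistency(self, scenario):
        assert scenario.perturbed_terms == {
            t for t, m in scenario.term_module.items() if m in scenario.perturbed_modules
        }
        assert all(
            scenario.module_of[g] in scenario.perturbed_modules
            for g in scenario.perturbed_genes
        )

    def test_artifact_round_trip(self, tmp_path, scenario):
        from funcmap.graph_io import read_annotations, read_edge_list, write_annotations, write_edge_list
        from funcmap.semantic import Ontology

        write_edge_list(scenario.control, tmp_path / "c.tsv")
        write_annotations(scenario.annotations, tmp_path / "a.tsv")
        scenario.ontology.to_obo(tmp_path / "o.obo")
        assert read_edge_list(tmp_path / "c.tsv").edges == scenario.control.edges
        assert read_annotations(tmp_path / "a.tsv").pairs == scenario.annotations.pairs
        assert Ontology.from_obo(tmp_path / "o.obo").parents == scenario.ontology.parents

    def test_corpus_regime_constant_is_wired(self):
        sc = make_scenario(seed=4, **CORPUS_ANNOTATIONS)
        assert len(sc.annotations.annotation_ids) == 50  # 5 modules x 10 terms
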