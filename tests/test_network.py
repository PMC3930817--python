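"""Reaction-graph construction and PPI integration."""

import itertools

import networkx as nx
import pytest
from hypothesis import given
from hypothesis import strategies as st

from empath import (
    FixtureSpec,
    PpiRecord,
    build_reaction_graph,
    integrate_ppi,
    read_ppi_table,
    write_graphml,
    write_sif,
)
from empath.simulate import make_toy_model


def brute_force_edges(model, excluded):
    """O(n^2) pairwise shared-metabolite oracle."""
    from empath.model import metabolite_base_id

    def mets(rid):
        return {
            m for m in model.metabolites_of(rid)
            if m not in excluded and metabolite_base_id(m) not in excluded
        }

    edges = set()
    for a, b in itertools.combinations(model.reaction_ids, 2):
        if mets(a) & mets(b):
            edges.add(frozenset((a, b)))
    return edges


class TestReactionGraph:
    def test_chain_example(self, toy_model):
        # A->B, B->C share B; C->F shares C with B->C; D->E isolated
        net = build_reaction_graph(toy_model)
        edges = {frozenset(e) for e in net.graph.edges()}
        assert edges == {frozenset(("R1", "R2")), frozenset(("R2", "R4"))}
        assert net.graph.degree("R3") == 0

    def test_shared_metabolites_recorded_on_edge(self, toy_model):
        net = build_reaction_graph(toy_model)
        assert net.graph["R1"]["R2"]["metabolic"]["shared"] == frozenset({"B[c]"})

    def test_excluding_the_shared_metabolite_removes_edges(self, toy_model):
        net = build_reaction_graph(toy_model, {"B[c]", "C"})
        assert net.graph.number_of_edges() == 0

    def test_compartment_free_exclusion_matches_all_compartments(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tequation\tlower\tupper\trule\n"
                     "R1\tA[c] -> X[c]\t0\t10\t\n"
                     "R2\tX[c] -> B[c]\t0\t10\t\n"
                     "R3\tA[m] -> X[m]\t0\t10\t\n"
                     "R4\tX[m] -> B[m]\t0\t10\t\n")
        from empath import read_model

        model = read_model(p, "tabular")
        assert build_reaction_graph(model, {"X"}).graph.number_of_edges() == 0
        # compartment-qualified id only hits its own pool
        assert build_reaction_graph(model, {"X[c]"}).graph.number_of_edges() == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        spec = FixtureSpec(seed=seed, n_reactions=20, n_metabolites=24, n_cofactors=2,
                           planted_path_length=None)
        model, exclusion = make_toy_model(spec)
        net = build_reaction_graph(model, set(exclusion))
        got = {frozenset(e) for e in net.graph.edges()}
        assert got == brute_force_edges(model, set(exclusion))

    @pytest.mark.parametrize("seed", range(5))
    def test_exclusion_monotonicity(self, seed):
        spec = FixtureSpec(seed=seed, n_reactions=25, n_metabolites=28, n_cofactors=3,
                           planted_path_length=None)
        model, _ = make_toy_model(spec)
        mets = list(model.metabolites)
        counts = []
        for cut in range(0, len(mets) + 1, max(len(mets) // 4, 1)):
            net = build_reaction_graph(model, set(mets[:cut]))
            counts.append(net.graph.number_of_edges())
        assert counts == sorted(counts, reverse=True)

    def test_empty_model_gives_empty_network(self):
        from empath import MetabolicModel

        net = build_reaction_graph(MetabolicModel(reactions=[], metabolites=[]))
        assert len(net) == 0


def _two_reaction_net():
    from empath import read_model
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "m.tsv"
        p.write_text("id\tequation\tlower\tupper\trule\n"
                     "R1\tA -> B\t0\t10\tg1\n"
                     "R2\tC -> D\t0\t10\tg2\n")
        model = read_model(p, "tabular")
    return build_reaction_graph(model)


class TestIntegratePpi:
    def test_score_above_threshold_adds_edge(self):
        net = integrate_ppi(_two_reaction_net(), [PpiRecord("g1", "g2", 901)], 900)
        assert net.edge_kinds("R1", "R2") == {"ppi"}

    def test_score_at_threshold_dropped(self):
        net = integrate_ppi(_two_reaction_net(), [PpiRecord("g1", "g2", 900)], 900)
        assert net.graph.number_of_edges() == 0

    def test_kinase_phosphatase_bypasses_score_filter(self):
        rec = PpiRecord("g1", "g2", 0, source="kinase-phosphatase")
        net = integrate_ppi(_two_reaction_net(), [rec], 900)
        assert net.edge_kinds("R1", "R2") == {"ppi"}
        assert net.graph["R1"]["R2"]["ppi"]["provenance"] == "KPI"

    def test_unmatched_gene_becomes_protein_node(self):
        net = integrate_ppi(_two_reaction_net(), [PpiRecord("g1", "kin1", 950)], 900)
        assert "kin1" in net.graph
        assert net.node_kind("kin1") == "protein"
        assert net.edge_kinds("R1", "kin1") == {"ppi"}

    def test_record_with_both_genes_unmatched_is_dropped(self, caplog):
        net = integrate_ppi(_two_reaction_net(), [PpiRecord("x1", "x2", 950)], 900)
        assert "x1" not in net.graph and "x2" not in net.graph

    def test_one_gene_pair_connects_all_catalyzed_reaction_pairs(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tequation\tlower\tupper\trule\n"
                     "R1\tA -> B\t0\t10\tg1\n"
                     "R2\tC -> D\t0\t10\tg1\n"
                     "R3\tE -> F\t0\t10\tg2\n")
        from empath import read_model

        net = build_reaction_graph(read_model(p, "tabular"))
        net = integrate_ppi(net, [PpiRecord("g1", "g2", 950)], 900)
        assert net.edge_kinds("R1", "R3") == {"ppi"}
        assert net.edge_kinds("R2", "R3") == {"ppi"}
        assert net.edge_kinds("R1", "R2") == set()

    def test_infinite_threshold_leaves_metabolic_subgraph_unchanged(self, small_bundle):
        base = build_reaction_graph(small_bundle.model, set(small_bundle.exclusion))
        out = integrate_ppi(base, small_bundle.ppi, score_threshold=10**9)
        kpi_only = [e for e in out.graph.edges(keys=True) if e[2] == "ppi"]
        scored = [r for r in small_bundle.ppi if r.source != "kinase-phosphatase"]
        assert all(out.graph.edges[e]["provenance"] == "KPI" for e in kpi_only)
        assert len(out.edges_of_kind("metabolic")) == len(base.edges_of_kind("metabolic"))
        assert scored  # the fixture does produce scored records

    def test_input_network_not_mutated(self):
        base = _two_reaction_net()
        before = base.graph.number_of_edges()
        integrate_ppi(base, [PpiRecord("g1", "g2", 950)], 900)
        assert base.graph.number_of_edges() == before

    def test_no_self_edges_and_symmetry(self, small_bundle):
        net = small_bundle.network
        assert all(u != v for u, v in net.graph.edges())
        for u, v in list(net.graph.edges())[:200]:
            assert net.edge_kinds(u, v) == net.edge_kinds(v, u)

    def test_parallel_metabolic_and_ppi_edges_coexist(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tequation\tlower\tupper\trule\n"
                     "R1\tA -> B\t0\t10\tg1\n"
                     "R2\tB -> C\t0\t10\tg2\n")
        from empath import read_model

        net = build_reaction_graph(read_model(p, "tabular"))
        net = integrate_ppi(net, [PpiRecord("g1", "g2", 950)], 900)
        assert net.edge_kinds("R1", "R2") == {"metabolic", "ppi"}


class TestIo:
    def test_ppi_table_roundtrip(self, tmp_path, small_bundle):
        from empath.network import write_ppi_table

        p = tmp_path / "ppi.tsv"
        write_ppi_table(small_bundle.ppi, p)
        assert read_ppi_table(p) == small_bundle.ppi

    def test_graphml_export_parses_back(self, tmp_path, small_bundle):
        p = tmp_path / "net.graphml"
        write_graphml(small_bundle.network, p)
        g = nx.read_graphml(str(p))
        assert g.number_of_nodes() == small_bundle.network.graph.number_of_nodes()
        kinds = nx.get_node_attributes(g, "kind")
        assert set(kinds.values()) <= {"reaction", "protein"}

    def test_sif_export_lists_every_edge(self, tmp_path, small_bundle):
        p = tmp_path / "net.sif"
        write_sif(small_bundle.network, p)
        lines = [l for l in p.read_text().splitlines() if l]
        assert len(lines) == small_bundle.network.graph.number_of_edges()
        assert all(len(l.split("\t")) == 3 for l in lines)


@given(st.integers(min_value=0, max_value=10**6))
def test_ppi_record_rejects_self_interactions(score):
    with pytest.raises(ValueError):
        PpiRecord("g1", "g1", score)
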