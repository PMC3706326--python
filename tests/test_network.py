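import networkx as nx
import pytest

from bimodules import (
    FormatError,
    MetabolicNetwork,
    UnknownNodeError,
    ValidationError,
    connected_components,
    load_reaction_table,
    write_reaction_table,
)
from bimodules.network import write_graphml, write_sif


def _write(tmp_path, text, name="net.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadReactionTable:
    def test_two_row_file(self, tmp_path):
        p = _write(
            tmp_path,
            "reaction_id\tmetabolite_ids\tgene_ids\nR1\tA;B\tg1\nR2\tB\t\n",
        )
        net = load_reaction_table(p)
        assert net.reactions == {"R1", "R2"}
        assert net.metabolites == {"A", "B"}
        assert len(net.edges) == 3
        assert net.gene_map["R1"] == {"g1"}
        assert net.gene_map["R2"] == frozenset()

    def test_duplicate_metabolite_collapses_to_one_edge(self, tmp_path):
        p = _write(tmp_path, "reaction_id\tmetabolite_ids\tgene_ids\nR1\tA;A\tg1\n")
        net = load_reaction_table(p)
        assert net.edges == {("R1", "A")}

    def test_header_only_gives_empty_network(self, tmp_path):
        p = _write(tmp_path, "reaction_id\tmetabolite_ids\tgene_ids\n")
        net = load_reaction_table(p)
        assert not net.reactions and not net.metabolites

    def test_na_gene_field_means_no_genes(self, tmp_path):
        p = _write(tmp_path, "reaction_id\tmetabolite_ids\tgene_ids\nR1\tA\tNA\n")
        assert load_reaction_table(p).gene_map["R1"] == frozenset()

    def test_missing_column_names_the_column(self, tmp_path):
        p = _write(tmp_path, "reaction_id\tmetabolite_ids\nR1\tA\n")
        with pytest.raises(FormatError, match="gene_ids"):
            load_reaction_table(p)

    def test_conflicting_duplicate_reaction_rows(self, tmp_path):
        p = _write(
            tmp_path,
            "reaction_id\tmetabolite_ids\tgene_ids\nR1\tA\tg1\nR1\tB\tg1\n",
        )
        with pytest.raises(ValidationError, match="R1"):
            load_reaction_table(p)

    def test_bipartite_after_load(self, tmp_path):
        p = _write(
            tmp_path,
            "reaction_id\tmetabolite_ids\tgene_ids\nR1\tA;B\tg1\nR2\tB;C\t\nR3\tC\tg3\n",
        )
        g = load_reaction_table(p).to_networkx()
        assert nx.is_bipartite(g)

    def test_round_trip(self, tmp_path, hub_network):
        p = tmp_path / "out.tsv"
        write_reaction_table(hub_network, p)
        again = load_reaction_table(p)
        assert again.reactions == hub_network.reactions
        assert again.metabolites == hub_network.metabolites
        assert again.edges == hub_network.edges
        assert dict(again.gene_map) == dict(hub_network.gene_map)


class TestNetworkInvariants:
    def test_overlapping_ids_rejected(self):
        with pytest.raises(ValidationError):
            MetabolicNetwork(
                reactions=frozenset({"X"}),
                metabolites=frozenset({"X"}),
                edges=frozenset(),
                gene_map={},
            )

    def test_edge_to_unknown_node_rejected(self):
        with pytest.raises(ValidationError):
            MetabolicNetwork(
                reactions=frozenset({"R1"}),
                metabolites=frozenset(),
                edges=frozenset({("R1", "A")}),
                gene_map={},
            )


class TestMetaboliteDegree:
    def test_hub_metabolite_of_twelve_reactions(self, hub_network):
        assert hub_network.metabolite_degree("HUB") == 12

    def test_linear_chain_inner_metabolite(self, chain_network):
        assert chain_network.metabolite_degree("A") == 2

    def test_isolated_metabolite(self):
        net = MetabolicNetwork(
            reactions=frozenset({"R1"}),
            metabolites=frozenset({"A", "LONE"}),
            edges=frozenset({("R1", "A")}),
            gene_map={},
        )
        assert net.metabolite_degree("LONE") == 0

    def test_unknown_id(self, chain_network):
        with pytest.raises(UnknownNodeError):
            chain_network.metabolite_degree("nope")


class TestConnectedComponents:
    def test_chain_subset_single_component(self, chain_network):
        comps = connected_components(chain_network, {"R1", "A", "R2"})
        assert len(comps) == 1
        assert comps[0].composition == (2, 1)

    def test_disconnected_reactions_are_singletons(self, chain_network):
        comps = connected_components(chain_network, {"R1", "R3"})
        assert [c.composition for c in comps] == [(1, 0), (1, 0)]
        assert comps[0].reaction_ids == {"R1"}  # deterministic lexicographic order

    def test_empty_subset(self, chain_network):
        assert connected_components(chain_network, set()) == []

    def test_unknown_node(self, chain_network):
        with pytest.raises(UnknownNodeError):
            connected_components(chain_network, {"R1", "ghost"})

    def test_partition_property(self, hub_network, rng):
        nodes = sorted(hub_network.nodes)
        for _ in range(20):
            take = {n for n in nodes if rng.random() < 0.5}
            comps = connected_components(hub_network, take)
            union = set()
            total = 0
            for c in comps:
                assert not (union & c.nodes), "components must be disjoint"
                union |= c.nodes
                total += len(c)
            assert union == take and total == len(take)


class TestGraphExports:
    def test_graphml_round_trip(self, tmp_path, chain_network):
        p = tmp_path / "net.graphml"
        write_graphml(chain_network, p)
        g = nx.read_graphml(p)
        assert set(g.nodes) == chain_network.nodes
        assert {frozenset(e) for e in g.edges} == {
            frozenset(e) for e in chain_network.edges
        }
        assert g.nodes["R1"]["node_type"] == "reaction"
        assert g.nodes["A"]["node_type"] == "metabolite"

    def test_sif_lists_edges_and_isolated_nodes(self, tmp_path, chain_network):
        p = tmp_path / "net.sif"
        write_sif(chain_network, p, nodes={"R1", "A", "R3"})
        lines = p.read_text().strip().splitlines()
        assert "R1\trm\tA" in lines
        assert "R3" in lines  # isolated within the chosen subset


@pytest.fixture(scope="module")
def sbml_file(tmp_path_factory):
    cobra = pytest.importorskip("cobra")
    model = cobra.Model("toy")
    a = cobra.Metabolite("A", compartment="c")
    b = cobra.Metabolite("B", compartment="c")
    rxn = cobra.Reaction("R1")
    rxn.add_metabolites({a: -1, b: 1})
    rxn.gene_reaction_rule = "g1 or g2"
    model.add_reactions([rxn])
    path = tmp_path_factory.mktemp("sbml") / "toy.xml"
    cobra.io.write_sbml_model(model, str(path))
    return path


class TestSbmlImport:
    def test_one_reaction_two_metabolites_two_edges(self, sbml_file):
        from bimodules import import_sbml

        net = import_sbml(sbml_file)
        assert net.reactions == {"R1"}
        assert net.metabolites == {"A", "B"}
        assert net.edges == {("R1", "A"), ("R1", "B")}
        assert net.gene_map["R1"] == {"g1", "g2"}

    def test_reversibility_is_ignored(self, sbml_file, tmp_path):
        import cobra

        from bimodules import import_sbml

        model = cobra.io.read_sbml_model(str(sbml_file))
        model.reactions[0].bounds = (-1000, 1000)  # make reversible
        rev = tmp_path / "rev.xml"
        cobra.io.write_sbml_model(model, str(rev))
        a, b = import_sbml(sbml_file), import_sbml(rev)
        assert a.edges == b.edges and a.reactions == b.reactions

    def test_unparseable_file_raises_format_error(self, tmp_path):
        from bimodules import import_sbml

        bad = tmp_path / "bad.xml"
        bad.write_text("this is not SBML")
        with pytest.raises(FormatError):
            import_sbml(bad)
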