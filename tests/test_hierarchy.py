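import numpy as np
import pytest

from pathsparse import hierarchy as hy
from pathsparse import simulate as sim
from pathsparse.errors import ConfigurationError, ParseError, StructuralError


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParseRelations:
    def test_species_filter(self, tmp_path):
        p = write(
            tmp_path,
            "rel.tsv",
            "R-HSA-A\tR-HSA-B\nR-HSA-A\tR-HSA-C\nR-MMU-X\tR-MMU-Y\n",
        )
        dag = hy.parse_relations(p)
        assert dag.nodes == {"R-HSA-A", "R-HSA-B", "R-HSA-C"}
        assert dag.edges == {("R-HSA-A", "R-HSA-B"), ("R-HSA-A", "R-HSA-C")}

    def test_custom_species_tag(self, tmp_path):
        p = write(tmp_path, "rel.tsv", "R-MMU-X\tR-MMU-Y\n")
        dag = hy.parse_relations(p, species="MMU")
        assert len(dag.edges) == 1

    def test_empty_file(self, tmp_path):
        dag = hy.parse_relations(write(tmp_path, "rel.tsv", ""))
        assert dag.nodes == set() and dag.edges == set()

    def test_cycle_detected(self, tmp_path):
        p = write(tmp_path, "rel.tsv", "R-HSA-A\tR-HSA-B\nR-HSA-B\tR-HSA-A\n")
        with pytest.raises(StructuralError, match="cycle"):
            hy.parse_relations(p)

    def test_malformed_line_reports_number(self, tmp_path):
        p = write(tmp_path, "rel.tsv", "R-HSA-A\tR-HSA-B\nonly-one-field\n")
        with pytest.raises(ParseError, match=":2"):
            hy.parse_relations(p)

    def test_self_edge(self, tmp_path):
        p = write(tmp_path, "rel.tsv", "R-HSA-A\tR-HSA-A\n")
        with pytest.raises(StructuralError, match="self-edge"):
            hy.parse_relations(p)


class TestParseGmt:
    def test_dedup_within_line(self, tmp_path):
        gs = hy.parse_gmt(write(tmp_path, "s.gmt", "P1\tdesc\tTP53\tJAK2\tTP53\n"))
        assert gs.entries["P1"]["genes"] == {"TP53", "JAK2"}

    def test_duplicate_id(self, tmp_path):
        p = write(tmp_path, "s.gmt", "P1\td\tA\nP1\td\tB\n")
        with pytest.raises(ParseError, match="duplicate"):
            hy.parse_gmt(p)

    def test_too_few_fields(self, tmp_path):
        with pytest.raises(ParseError, match=":1"):
            hy.parse_gmt(write(tmp_path, "s.gmt", "P1\tdesc\n"))

    def test_generated_fixture_matches_manifest(self, tmp_path):
        manifest = sim.FixtureManifest(seed=3, roots=1, depth=5, branching=2)
        fixture = sim.generate_hierarchy(manifest, tmp_path)
        gs = hy.parse_gmt(fixture.gmt_path)
        # every leaf's annotation equals the generator's planted gene list
        for leaf, genes in fixture.leaf_genes.items():
            assert gs.entries[leaf]["genes"] == set(genes)
        assert len(gs) == fixture.n_pathways  # all pathways annotated


class TestParseNames:
    def test_roundtrip(self, tmp_path):
        p = write(tmp_path, "names.tsv", "R-HSA-1\tCell Cycle\tHomo sapiens\n")
        names = hy.parse_names(p)
        assert names["R-HSA-1"] == {"name": "Cell Cycle", "species": "Homo sapiens"}

    def test_bad_columns(self, tmp_path):
        with pytest.raises(ParseError):
            hy.parse_names(write(tmp_path, "names.tsv", "a\tb\n"))


class TestAssignLayers:
    def test_chain(self):
        dag = hy.PathwayDAG(nodes={"A", "B", "C"}, edges={("A", "B"), ("B", "C")})
        layered = hy.assign_layers(dag)
        assert layered.layers == [["A"], ["B"], ["C"]]
        assert not layered.copies

    def test_diamond_longest_path(self):
        dag = hy.PathwayDAG(
            nodes={"A", "B", "C", "D"},
            edges={("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")},
        )
        layered = hy.assign_layers(dag)
        assert layered.layers == [["A"], ["B", "C"], ["D"]]

    def test_empty_dag(self):
        with pytest.raises(StructuralError):
            hy.assign_layers(hy.PathwayDAG(nodes=set(), edges=set()))

    def test_skip_edge_inserts_copy_chain(self):
        # A->B->C->D plus skip edge A->D spanning two layers
        dag = hy.PathwayDAG(
            nodes={"A", "B", "C", "D"},
            edges={("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")},
        )
        layered = hy.assign_layers(dag)
        assert len(layered.copies) == 2  # copies of A at layers 2 and 3
        assert all(orig == "A" for orig in layered.copies.values())
        for parent, child in layered.edges:
            assert layered.node_layer[child] == layered.node_layer[parent] + 1

    def test_adjacency_invariant_on_generated_dag(self, tmp_path):
        fixture = sim.generate_hierarchy(sim.FixtureManifest(seed=11, n_cross_edges=5), tmp_path)
        layered = hy.assign_layers(hy.parse_relations(fixture.relations_path))
        for parent, child in layered.edges:
            assert layered.node_layer[child] == layered.node_layer[parent] + 1
        placed = [n for layer in layered.layers for n in layer]
        assert len(placed) == len(set(placed))


def diamond_selected():
    dag = hy.PathwayDAG(
        nodes={"A", "B", "C", "D"},
        edges={("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")},
    )
    layered = hy.assign_layers(dag)
    gene_sets = hy.PathwayGeneSets(
        entries={
            "B": {"name": "b", "genes": {"g1"}},
            "C": {"name": "c", "genes": {"g1", "g2"}},
        }
    )
    return hy.select_sublayers(layered, gene_sets, k=2)


class TestSelectSublayers:
    def test_diamond_k2_masks(self):
        selected = diamond_selected()
        assert selected.pathway_layers == [["B", "C"], ["A"]]
        assert selected.gene_list == ["g1", "g2"]
        adj = selected.masks[0].to_dense()
        np.testing.assert_array_equal(adj, [[1, 0], [1, 1]])  # rows B, C
        np.testing.assert_array_equal(selected.masks[1].to_dense(), [[1, 1]])

    def test_index_reversal_five_layers(self, tmp_path):
        fixture = sim.generate_hierarchy(sim.FixtureManifest(seed=5), tmp_path)
        layered = hy.assign_layers(hy.parse_relations(fixture.relations_path))
        gene_sets = hy.parse_gmt(fixture.gmt_path)
        selected = hy.select_sublayers(layered, gene_sets, k=4)
        assert selected.n_layers == 4
        # pathway layer 1 nodes live in DAG layer 4
        layer4 = set(layered.layers[3])
        assert set(selected.pathway_layers[0]) <= layer4
        # network layer k corresponds to DAG layer 1 (roots)
        assert set(selected.pathway_layers[3]) <= set(layered.layers[0])

    def test_k_out_of_range(self):
        dag = hy.PathwayDAG(nodes={"A", "B"}, edges={("A", "B")})
        layered = hy.assign_layers(dag)
        gs = hy.PathwayGeneSets(entries={"B": {"name": "", "genes": {"g"}}})
        with pytest.raises(ConfigurationError):
            hy.select_sublayers(layered, gs, k=3)
        with pytest.raises(ConfigurationError):
            hy.select_sublayers(layered, gs, k=0)

    def test_geneless_node_pruned(self):
        dag = hy.PathwayDAG(
            nodes={"A", "B", "C"}, edges={("A", "B"), ("A", "C")}
        )
        layered = hy.assign_layers(dag)
        gs = hy.PathwayGeneSets(entries={"B": {"name": "", "genes": {"g1"}}})
        selected = hy.select_sublayers(layered, gs, k=2)
        assert selected.pathway_layers[0] == ["B"]  # C had no genes
        assert all(mask.to_dense().sum(axis=1).min() >= 1 for mask in selected.masks)

    def test_nnz_equals_restricted_gene_set_sizes(self, tmp_path):
        fixture = sim.generate_hierarchy(sim.FixtureManifest(seed=9), tmp_path)
        layered = hy.assign_layers(hy.parse_relations(fixture.relations_path))
        gene_sets = hy.parse_gmt(fixture.gmt_path)
        selected = hy.select_sublayers(layered, gene_sets, k=4)
        gene_pool = set(selected.gene_list)
        expected = 0
        for node in selected.pathway_layers[0]:
            orig = selected.copies.get(node, node)
            expected += len(gene_sets.genes_of(orig) & gene_pool)
        assert selected.masks[0].nnz == expected

    def test_binary_entries(self):
        selected = diamond_selected()
        for mask in selected.masks:
            assert set(np.unique(mask.to_dense())) <= {0.0, 1.0}


class TestSerialization:
    def test_roundtrip_identical_masks(self, tmp_path):
        selected = diamond_selected()
        hy.write_selected(selected, tmp_path / "out")
        back = hy.read_selected(tmp_path / "out")
        assert back.pathway_layers == selected.pathway_layers
        assert back.gene_list == selected.gene_list
        for a, b in zip(selected.masks, back.masks):
            np.testing.assert_array_equal(a.to_dense(), b.to_dense())

    def test_deterministic_serialization(self, tmp_path):
        fixture = sim.generate_hierarchy(sim.FixtureManifest(seed=13), tmp_path / "h")
        layered = hy.assign_layers(hy.parse_relations(fixture.relations_path))
        gene_sets = hy.parse_gmt(fixture.gmt_path)
        for i, out in enumerate(("a", "b")):
            selected = hy.select_sublayers(layered, gene_sets, k=4)
            hy.write_selected(selected, tmp_path / out)
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
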