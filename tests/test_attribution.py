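import numpy as np
import pytest

from conftest import chain_hierarchy, random_selected_hierarchy
from pathsparse import attribution as at
from pathsparse import model as mm
from pathsparse.errors import ConfigurationError


def positive_chain_model():
    """1-gene chain with all-positive hand-set weights (monotone path)."""
    model = mm.init_model(chain_hierarchy(1), mm.ModelConfig(seed=0))
    model.gene_layer.W[:] = [[0.8, 0.5, 0.3]]
    model.gene_layer.b[:] = 0.0
    for layer in model.pathway_layers:
        layer.W[:] = 0.9 * layer.M
        layer.b[:] = 0.0
    for head in model.heads:
        head.w[:] = 0.7
        head.b = 0.0
    return model


class TestReferenceActivations:
    def test_zero_reference_zero_biases(self):
        model = positive_chain_model()
        ref = at.reference_activations(model)
        for a in ref["a"]:
            np.testing.assert_array_equal(a, 0.0)
        np.testing.assert_allclose(ref["head_p"], 0.5)
        assert ref["combined"] == pytest.approx(0.5)

    def test_reference_equals_plain_forward_with_biases(self):
        model = positive_chain_model()
        model.gene_layer.b[:] = 0.4
        ref = at.reference_activations(model)
        probs, hiddens = mm.forward(model, np.zeros(model.n_inputs))
        for a, b in zip(ref["a"], hiddens):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ref["head_p"], probs)

    def test_sample_equal_to_reference_gives_zero_delta(self):
        model = positive_chain_model()
        x = np.array([1.0, 0.0, 1.0])
        report = at.deeplift_scores(model, x[None, :], x0=x)
        np.testing.assert_allclose(report.delta_t, 0.0, atol=1e-12)
        for layer in report.layers:
            np.testing.assert_allclose(layer["contributions"], 0.0, atol=1e-12)


class TestDeepliftScores:
    def test_linear_rule_closed_form(self):
        """All-identity activations, single-head target: input contributions
        equal (delta p / delta z) * w_chain_i * delta x_i computed by hand."""
        model = positive_chain_model()
        model.gene_layer.activation = "linear"
        for layer in model.pathway_layers:
            layer.activation = "linear"
        x = np.array([[1.0, 0.0, 1.0]])
        report = at.deeplift_scores(model, x, target=4)

        # hand chain: gene weights through four 0.9 links and head weight 0.7
        w_chain = np.array([0.8, 0.5, 0.3]) * 0.9**4 * 0.7
        z = float(w_chain @ x[0])
        delta_p = 1 / (1 + np.exp(-z)) - 0.5
        expected = (delta_p / z) * w_chain * x[0]
        np.testing.assert_allclose(report.layers[0]["contributions"][0], expected, atol=1e-12)
        assert report.max_cut_error() < 1e-12

    def test_single_path_attributes_everything_to_active_node(self):
        model = positive_chain_model()
        x = np.array([[1.0, 0.0, 0.0]])
        # last-head target: the whole delta flows through the one active path
        report = at.deeplift_scores(model, x, target=4)
        delta_t = report.delta_t[0]
        for layer in report.layers[1:]:
            assert layer["contributions"][0].sum() == pytest.approx(delta_t, abs=1e-10)
        # brute-force forward difference on that head agrees
        p_x, _ = mm.forward(model, x)
        p_0, _ = mm.forward(model, np.zeros_like(x))
        assert delta_t == pytest.approx(p_x[0, 4] - p_0[0, 4], abs=1e-12)

    def test_perturbation_sign_agreement_monotone(self):
        model = positive_chain_model()
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, (8, 3)).astype(float)
        report = at.deeplift_scores(model, x)
        contrib = report.layers[0]["contributions"]
        for i in range(x.shape[0]):
            for j in range(3):
                if x[i, j] == 0:
                    assert contrib[i, j] == 0.0
                    continue
                x_off = x[i].copy()
                x_off[j] = 0.0
                brute = mm.predict_proba(model, x[i][None]) - mm.predict_proba(model, x_off[None])
                assert np.sign(contrib[i, j]) == np.sign(brute[0])

    @pytest.mark.parametrize("seed", range(4))
    def test_cut_sums_equal_delta_random_models(self, seed):
        rng = np.random.default_rng(seed)
        h = random_selected_hierarchy(rng, n_genes=int(rng.integers(3, 9)))
        model = mm.init_model(h, mm.ModelConfig(seed=seed))
        x = rng.integers(0, 2, (25, model.n_inputs)).astype(float)
        report = at.deeplift_scores(model, x)
        assert report.max_cut_error() < 1e-10

    def test_single_head_target_sums_plainly(self):
        rng = np.random.default_rng(1)
        model = mm.init_model(random_selected_hierarchy(rng), mm.ModelConfig(seed=1))
        x = rng.integers(0, 2, (10, model.n_inputs)).astype(float)
        report = at.deeplift_scores(model, x, target=4)
        # last-head target: no bypass, plain per-layer sums match delta
        for i, layer in enumerate(report.layers):
            np.testing.assert_allclose(
                layer["contributions"].sum(axis=1), report.delta_t, atol=1e-10
            )

    def test_trained_model_cut_sums(self, trained_fixture, fixture_data):
        best, _, _ = trained_fixture
        x = fixture_data.features.values[:50]
        report = at.deeplift_scores(best, x)
        assert report.max_cut_error() < 1e-5


def toy_report(scores_by_sample, node_ids):
    scores = np.asarray(scores_by_sample, dtype=float)
    layer = {"name": "genes", "node_ids": list(node_ids), "contributions": scores}
    return at.AttributionReport(
        layers=[layer],
        head_contributions=np.zeros((scores.shape[0], 1)),
        delta_t=scores.sum(axis=1),
        target="combined",
        reference_activations=[],
        reference_output=0.5,
    )


class TestRankNodes:
    def test_absolute_ordering(self):
        report = toy_report([[0.5, -0.9, 0.1]], ["n1", "n2", "n3"])
        assert [n for n, _ in at.rank_nodes(report, "genes")] == ["n2", "n1", "n3"]

    def test_opposite_scores_cancel(self):
        report = toy_report([[0.7, 0.2], [-0.7, 0.1]], ["a", "b"])
        ranked = at.rank_nodes(report, "genes")
        assert ranked[-1] == ("a", pytest.approx(0.0))

    def test_tie_broken_lexicographically(self):
        report = toy_report([[0.5, -0.5]], ["zz", "aa"])
        assert [n for n, _ in at.rank_nodes(report, "genes")] == ["aa", "zz"]

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(6, 4))
        ids = ["w", "x", "y", "z"]
        a = at.rank_nodes(toy_report(scores, ids), "genes")
        b = at.rank_nodes(toy_report(np.ascontiguousarray(scores[::-1]), ids), "genes")
        assert [n for n, _ in a] == [n for n, _ in b]
        np.testing.assert_allclose([s for _, s in a], [s for _, s in b], atol=1e-12)

    def test_unknown_layer(self):
        with pytest.raises(Exception):
            at.rank_nodes(toy_report([[1.0]], ["a"]), "nope")


class TestExportSankey:
    def make(self):
        rng = np.random.default_rng(2)
        h = random_selected_hierarchy(rng, n_genes=4, sizes=(3, 2, 2, 1))
        model = mm.init_model(h, mm.ModelConfig(seed=2))
        x = rng.integers(0, 2, (10, model.n_inputs)).astype(float)
        return model, at.deeplift_scores(model, x)

    def test_no_filtering_link_count(self):
        model, report = self.make()
        big_k = max(len(l["node_ids"]) for l in report.layers)
        sankey = at.export_sankey(model, report, top_k=big_k)
        mask_nnz = sum(int(l.M.sum()) for l in model.pathway_layers)
        diagonal_links = 3 * len(model.gene_list)
        assert len(sankey["links"]) == mask_nnz + diagonal_links

    def test_node_set_is_union_of_top_k(self):
        model, report = self.make()
        sankey = at.export_sankey(model, report, top_k=2)
        expected = set()
        for i in range(len(report.layers)):
            expected |= {n for n, _ in at.rank_nodes(report, i)[:2]}
        assert {n["id"] for n in sankey["nodes"]} == expected

    def test_feature_type_totals_present(self):
        model, report = self.make()
        sankey = at.export_sankey(model, report, top_k=3)
        assert set(sankey["feature_type_totals"]) == {"mutation", "amplification", "deletion"}

    def test_top_k_validation(self):
        model, report = self.make()
        with pytest.raises(ConfigurationError):
            at.export_sankey(model, report, top_k=0)

    def test_color_weights_normalized(self):
        model, report = self.make()
        sankey = at.export_sankey(model, report, top_k=3)
        assert all(0.0 <= n["color_weight"] <= 1.0 for n in sankey["nodes"])
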