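import numpy as np
import pytest

from pathsparse import hierarchy as hy
from pathsparse import model as mm
from pathsparse import pipeline as pl
from pathsparse import simulate as sim
from scipy import sparse


def make_mask(row_ids, col_ids, pairs):
    return hy.MaskMatrix.from_triplets(list(row_ids), list(col_ids), pairs)


def chain_hierarchy(n_genes: int = 1) -> hy.SelectedHierarchy:
    """Single-path blueprint: genes -> p1 -> p2 -> p3 -> p4, all fully wired."""
    genes = [f"g{i}" for i in range(n_genes)]
    layers = [["p1"], ["p2"], ["p3"], ["p4"]]
    masks = [make_mask(["p1"], genes, [("p1", g) for g in genes])]
    for i in range(1, 4):
        masks.append(make_mask(layers[i], layers[i - 1], [(layers[i][0], layers[i - 1][0])]))
    return hy.SelectedHierarchy(pathway_layers=layers, gene_list=genes, masks=masks)


def random_selected_hierarchy(rng: np.random.Generator, n_genes=6, sizes=(4, 3, 2, 2)) -> hy.SelectedHierarchy:
    """Random small blueprint with every mask row non-empty."""
    genes = [f"g{i}" for i in range(n_genes)]
    layers = [[f"L{li}N{i}" for i in range(sz)] for li, sz in enumerate(sizes)]
    masks = []
    cols = genes
    for li, layer in enumerate(layers):
        pairs = []
        for node in layer:
            k = int(rng.integers(1, len(cols) + 1))
            chosen = rng.choice(len(cols), size=k, replace=False)
            pairs.extend((node, cols[j]) for j in chosen)
        masks.append(make_mask(layer, cols, pairs))
        cols = layer
    return hy.SelectedHierarchy(pathway_layers=layers, gene_list=genes, masks=masks)


@pytest.fixture(scope="session")
def fixture_data(tmp_path_factory):
    """One deterministic end-to-end fixture cohort, shared across tests."""
    manifest = pl.recovery_manifest(seed=7, n_samples=400)
    return pl.build_fixture_data(manifest, tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def trained_fixture(fixture_data):
    """A short fixture training run (best model, final model, history)."""
    best, final, history = pl.train_fixture_model(
        fixture_data,
        training_config=pl.recovery_training_config(seed=7, epochs=150),
    )
    return best, final, history
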