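"""End-to-end fixture pipeline helpers.

Bundles the generate -> parse -> encode -> split -> train -> attribute chain
on synthetic fixtures, so tests, the acceptance report, and exploratory runs
exercise one code path.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

from pathsparse import attribution, features as ft, hierarchy as hy, model as mm, simulate as sim, trainer as tr


DEFAULT_SIGNAL = {
    "G0001": {"mutation": 3.0},
    "G0010": {"mutation": 3.0},
    "G0050": {"amplification": 3.0},
}


def recovery_manifest(seed: int, signal: dict | None = None, n_samples: int = 1000) -> sim.FixtureManifest:
    """Fixture settings under which planted signal is reliably recoverable."""
    return sim.FixtureManifest(
        seed=seed,
        n_samples=n_samples,
        signal=DEFAULT_SIGNAL if signal is None else signal,
        class_balance=0.5,
        mutation_rate=0.10,
        amp_rate=0.08,
        del_rate=0.05,
    )


def recovery_training_config(seed: int, epochs: int = 600) -> tr.TrainingConfig:
    return tr.TrainingConfig(
        epochs=epochs,
        seed=seed,
        batch_size=32,
        base_learning_rate=5e-3,
        schedule_period=max(epochs // 4, 1),
    )


def recovery_model_config(seed: int) -> mm.ModelConfig:
    return mm.ModelConfig(seed=seed, gene_dropout=0.3, pathway_dropout=0.05)


@dataclass
class FixtureData:
    manifest: sim.FixtureManifest
    selected: hy.SelectedHierarchy
    features: ft.FeatureMatrix
    labels: ft.CohortLabels
    split: ft.DataSplit
    truth: dict


def build_fixture_data(
    manifest: sim.FixtureManifest, work_dir: Path | None = None, split_seed: int | None = None
) -> FixtureData:
    """Generate fixture files and run them through the real readers/encoders."""
    work_dir = Path(work_dir) if work_dir is not None else Path(tempfile.mkdtemp(prefix="pathsparse_"))
    hier = sim.generate_hierarchy(manifest, work_dir / "hierarchy")
    cohort = sim.generate_cohort(manifest, hier.gene_universe, work_dir / "cohort")

    dag = hy.parse_relations(hier.relations_path)
    layered = hy.assign_layers(dag)
    gene_sets = hy.parse_gmt(hier.gmt_path)
    selected = hy.select_sublayers(layered, gene_sets, k=4)

    clinical = ft.read_clinical(cohort.paths["clinical"])
    samples = sorted(clinical["sample"])
    mut = ft.binarize_mutations(ft.read_maf_lite(cohort.paths["mutations"]), selected.gene_list, samples)
    cnv = ft.read_gene_sample_matrix(cohort.paths["cnv"])
    amp, dele = ft.encode_cnv(cnv.reindex(index=selected.gene_list, columns=samples, fill_value=0))
    matrix = ft.assemble_features(mut, amp, dele, selected.gene_list, samples)
    labels = ft.label_survival(clinical)
    split = ft.split_dataset(labels, seed=manifest.seed if split_seed is None else split_seed)
    return FixtureData(
        manifest=manifest,
        selected=selected,
        features=matrix,
        labels=labels,
        split=split,
        truth=cohort.truth,
    )


def train_fixture_model(
    data: FixtureData,
    model_config: mm.ModelConfig | None = None,
    training_config: tr.TrainingConfig | None = None,
):
    """Initialize and train a model on fixture data; returns (best, final, history)."""
    seed = data.manifest.seed
    net = mm.init_model(data.selected, model_config or recovery_model_config(seed))
    best, history = tr.train(
        net, data.features, data.labels, data.split, training_config or recovery_training_config(seed)
    )
    return best, net, history


def planted_gene_ranks(model: mm.SparseModel, data: FixtureData) -> dict[str, int]:
    """1-based attribution rank of each planted signal gene in the gene layer."""
    report = attribution.deeplift_scores(model, data.features)
    ranked = [g for g, _ in attribution.rank_nodes(report, "genes")]
    return {g: ranked.index(g) + 1 for g in data.manifest.signal}
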