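"""Self-contained synthetic fixtures: a toy pathway hierarchy written in the
same dialects as the real download, and a cohort with planted gene-outcome
signal drawn from a logistic model.

The hierarchy is a rooted forest (configurable roots/depth/branching) plus a
few cross-depth edges so the copy-chain layerization logic is exercised.
Every leaf pathway carries genes; internal pathways are annotated with the
union of their descendants' genes, as in the real gene-set file.  The cohort
draws background alterations independently per gene and then an outcome from
``logit = intercept + sum(effect * feature)`` over the planted signal genes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pathsparse.errors import ConfigurationError, ValidationError


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class FixtureManifest:
    """Fully determines both fixtures given the seed."""

    seed: int = 0
    # hierarchy shape
    roots: int = 2
    depth: int = 5
    branching: int = 2
    genes_per_leaf: int = 5
    overlap_genes_per_leaf: int = 2
    n_cross_edges: int = 3
    # cohort shape
    n_samples: int = 400
    class_balance: float | None = None  # target positive (short-term) rate
    intercept: float = 0.0
    censor_fraction: float = 0.0
    # planted signal: gene id -> {"mutation"|"amplification"|"deletion": log-odds}
    signal: dict = field(default_factory=dict)
    # background alteration rates
    mutation_rate: float = 0.05
    amp_rate: float = 0.02
    del_rate: float = 0.02
    low_level_cnv_rate: float = 0.05

    def __post_init__(self):
        for rate in (self.mutation_rate, self.amp_rate, self.del_rate, self.low_level_cnv_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"rate {rate} outside [0, 1]")
        if self.depth < 5:
            raise ConfigurationError("depth must be >= 5 to exercise a 4-layer selection")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        return cls(**json.loads(text))


@dataclass
class HierarchyFixture:
    pathways_by_depth: list[list[str]]  # depth 1 = roots
    edges: list[tuple[str, str]]  # tree + cross edges, parent -> child
    cross_edges: list[tuple[str, str]]
    leaf_genes: dict[str, list[str]]
    gene_universe: list[str]
    gmt_path: Path | None = None
    relations_path: Path | None = None
    names_path: Path | None = None

    @property
    def n_pathways(self) -> int:
        return sum(len(layer) for layer in self.pathways_by_depth)


@dataclass
class CohortFixture:
    mutations: pd.DataFrame  # MAF-lite records: sample, gene, variant_class
    cnv: pd.DataFrame  # gene x sample, values in {-2,-1,0,1,2}
    clinical: pd.DataFrame  # sample, months, status
    truth: dict  # realized labels, intercept, planted genes
    paths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# hierarchy generation
# ---------------------------------------------------------------------------


def generate_hierarchy(manifest: FixtureManifest, out_dir=None) -> HierarchyFixture:
    """Build the toy DAG and optionally write the three dialect files.

    Cross edges connect a node to one at least two levels deeper (distinct
    source nodes), so each produces exactly one copy chain at layerization.
    Refuses to generate more than 10^4 pathways.
    """
    rng = np.random.default_rng(manifest.seed)
    b, depth = manifest.branching, manifest.depth
    n_nodes = manifest.roots * (b**depth - 1) // (b - 1) if b > 1 else manifest.roots * depth
    if n_nodes > 10_000:
        raise ConfigurationError(f"{n_nodes} pathways exceeds the 10^4 fixture cap")

    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"R-HSA-{counter:05d}"

    layers: list[list[str]] = [[new_id() for _ in range(manifest.roots)]]
    edges: list[tuple[str, str]] = []
    for _ in range(1, depth):
        nxt = []
        for parent in layers[-1]:
            for _ in range(b):
                child = new_id()
                nxt.append(child)
                edges.append((parent, child))
        layers.append(nxt)

    # cross-depth edges: distinct sources, target >= 2 levels deeper
    cross: list[tuple[str, str]] = []
    eligible_sources = [n for d in range(depth - 2) for n in layers[d]]
    rng.shuffle(eligible_sources)
    src_depth = {n: d for d, layer in enumerate(layers) for n in layer}
    for src in eligible_sources[: manifest.n_cross_edges]:
        tgt_depth = int(rng.integers(src_depth[src] + 2, depth))
        tgt = layers[tgt_depth][int(rng.integers(len(layers[tgt_depth])))]
        cross.append((src, tgt))
        edges.append((src, tgt))

    leaves = layers[-1]
    universe = [f"G{i:04d}" for i in range(len(leaves) * manifest.genes_per_leaf)]
    shuffled = list(universe)
    rng.shuffle(shuffled)
    leaf_genes: dict[str, list[str]] = {}
    for i, leaf in enumerate(leaves):
        own = shuffled[i * manifest.genes_per_leaf : (i + 1) * manifest.genes_per_leaf]
        extra = [universe[j] for j in rng.integers(0, len(universe), manifest.overlap_genes_per_leaf)]
        leaf_genes[leaf] = sorted(set(own) | set(extra))

    fixture = HierarchyFixture(
        pathways_by_depth=layers,
        edges=edges,
        cross_edges=cross,
        leaf_genes=leaf_genes,
        gene_universe=sorted(universe),
    )
    if out_dir is not None:
        _write_hierarchy_files(fixture, Path(out_dir))
    return fixture


def _descendant_genes(fixture: HierarchyFixture) -> dict[str, set[str]]:
    """Gene annotation per pathway: leaves own genes, ancestors the union."""
    children: dict[str, list[str]] = {}
    for p, c in fixture.edges:
        children.setdefault(p, []).append(c)
    memo: dict[str, set[str]] = {}

    def genes(node: str) -> set[str]:
        if node in memo:
            return memo[node]
        out = set(fixture.leaf_genes.get(node, ()))
        for c in children.get(node, ()):
            out |= genes(c)
        memo[node] = out
        return out

    for layer in fixture.pathways_by_depth:
        for n in layer:
            genes(n)
    return memo


def _write_hierarchy_files(fixture: HierarchyFixture, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    annotations = _descendant_genes(fixture)

    rel_lines = [f"{p}\t{c}" for p, c in sorted(fixture.edges)]
    (out_dir / "relations.tsv").write_text("\n".join(rel_lines) + "\n")

    gmt_lines = []
    for pid in sorted(annotations):
        genes = sorted(annotations[pid])
        if genes:
            gmt_lines.append("\t".join([pid, f"synthetic pathway {pid}"] + genes))
    (out_dir / "pathways.gmt").write_text("\n".join(gmt_lines) + "\n")

    name_lines = [
        f"{pid}\tPathway {pid}\tHomo sapiens" for layer in fixture.pathways_by_depth for pid in sorted(layer)
    ]
    (out_dir / "names.tsv").write_text("\n".join(sorted(name_lines)) + "\n")

    fixture.gmt_path = out_dir / "pathways.gmt"
    fixture.relations_path = out_dir / "relations.tsv"
    fixture.names_path = out_dir / "names.tsv"


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_FEATURE_KEYS = ("mutation", "amplification", "deletion")


def generate_cohort(
    manifest: FixtureManifest, gene_universe: list[str], out_dir=None
) -> CohortFixture:
    """Draw a cohort with planted logistic signal and write the three tables.

    When ``class_balance`` is set, the intercept is adjusted by bisection on
    the realized feature draws so the expected positive rate matches.
    Labels map onto survival: positives (short-term) die before the 60-month
    horizon, negatives survive past it; an optional ``censor_fraction`` adds
    alive-before-horizon samples the labeling step must exclude.
    """
    for gene, effects in manifest.signal.items():
        if gene not in gene_universe:
            raise ValidationError(f"signal gene {gene!r} not in the generated universe")
        for key in effects:
            if key not in _FEATURE_KEYS:
                raise ValidationError(f"unknown feature key {key!r} in the planted-signal map")

    rng = np.random.default_rng(manifest.seed + 1)
    genes = list(gene_universe)
    n_censored = int(round(manifest.censor_fraction * manifest.n_samples))
    n_total = manifest.n_samples + n_censored
    samples = [f"S{i:04d}" for i in range(n_total)]

    mut = (rng.random((len(genes), n_total)) < manifest.mutation_rate).astype(np.float64)
    amp = (rng.random((len(genes), n_total)) < manifest.amp_rate).astype(np.float64)
    dele = ((rng.random((len(genes), n_total)) < manifest.del_rate) & (amp == 0)).astype(np.float64)
    low = rng.random((len(genes), n_total))
    low_calls = np.where(
        (amp == 0) & (dele == 0) & (low < manifest.low_level_cnv_rate),
        np.where(rng.random((len(genes), n_total)) < 0.5, 1.0, -1.0),
        0.0,
    )
    cnv_values = 2.0 * amp - 2.0 * dele + low_calls

    gene_index = {g: i for i, g in enumerate(genes)}
    base_logit = np.zeros(n_total)
    feature_by_key = {"mutation": mut, "amplification": amp, "deletion": dele}
    for gene, effects in manifest.signal.items():
        gi = gene_index[gene]
        for key, effect in effects.items():
            base_logit += float(effect) * feature_by_key[key][gi]

    intercept = float(manifest.intercept)
    if manifest.class_balance is not None:
        lo, hi = -30.0, 30.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if _sigmoid(mid + base_logit[: manifest.n_samples]).mean() < manifest.class_balance:
                lo = mid
            else:
                hi = mid
        intercept = (lo + hi) / 2

    y = (rng.random(n_total) < _sigmoid(intercept + base_logit)).astype(int)

    months = np.where(
        y == 1,
        rng.uniform(2.0, 58.0, n_total),
        rng.uniform(62.0, 140.0, n_total),
    )
    status = np.where(y == 1, "dead", np.where(rng.random(n_total) < 0.3, "dead", "alive"))
    # censored tail: alive before the horizon, regardless of drawn outcome
    if n_censored:
        months[manifest.n_samples :] = rng.uniform(2.0, 58.0, n_censored)
        status[manifest.n_samples :] = "alive"

    clinical = pd.DataFrame(
        {"sample": samples, "months": np.round(months, 1), "status": status}
    )
    cnv = pd.DataFrame(cnv_values.astype(int), index=genes, columns=samples)
    gi_idx, sj_idx = np.nonzero(mut)
    mutations = pd.DataFrame(
        {
            "sample": [samples[j] for j in sj_idx],
            "gene": [genes[i] for i in gi_idx],
            "variant_class": "Missense_Mutation",
        }
    ).sort_values(["sample", "gene"], kind="mergesort").reset_index(drop=True)

    truth = {
        "labels": {s: int(v) for s, v in zip(samples[: manifest.n_samples], y[: manifest.n_samples])},
        "intercept": intercept,
        "signal": manifest.signal,
        "positive_rate": float(y[: manifest.n_samples].mean()),
        "censored_samples": samples[manifest.n_samples :],
        "mutation_matrix_checksum": int(mut.sum()),
    }

    fixture = CohortFixture(mutations=mutations, cnv=cnv, clinical=clinical, truth=truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mutations.to_csv(out_dir / "mutations.maf.tsv", sep="\t", index=False)
        cnv.to_csv(out_dir / "cnv.tsv", sep="\t")
        clinical.to_csv(out_dir / "clinical.csv", index=False)
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        (out_dir / "manifest.json").write_text(manifest.to_json())
        fixture.paths = {
            "mutations": out_dir / "mutations.maf.tsv",
            "cnv": out_dir / "cnv.tsv",
            "clinical": out_dir / "clinical.csv",
            "truth": out_dir / "truth.json",
            "manifest": out_dir / "manifest.json",
        }
    return fixture
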