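"""The sparse network core.

The model mirrors the selected hierarchy: a *diagonal* gene layer in which
each gene node reads only its own per-gene feature columns, followed by
mask-constrained pathway layers whose effective weights are ``W * M``
(elementwise), so connections absent from the hierarchy never influence the
output.  Every hidden layer additionally feeds a single-unit sigmoid output
head; the model prediction is a convex combination of the head
probabilities.

Implemented directly on NumPy arrays: the models are small (tens of
thousands of trainable entries) and an explicit forward pass keeps the
attribution machinery exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pathsparse.errors import ConfigurationError, StructuralError, ValidationError
from pathsparse.hierarchy import MaskMatrix, SelectedHierarchy


def tanh(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def identity(z: np.ndarray) -> np.ndarray:
    return z


ACTIVATIONS = {"tanh": tanh, "sigmoid": sigmoid, "linear": identity}


def activation_derivative(name: str, z: np.ndarray) -> np.ndarray:
    """Derivative of the activation evaluated at pre-activation z."""
    if name == "tanh":
        return 1.0 - np.tanh(z) ** 2
    if name == "sigmoid":
        s = sigmoid(z)
        return s * (1.0 - s)
    if name == "linear":
        return np.ones_like(z)
    raise ConfigurationError(f"unknown activation {name!r}")


@dataclass
class ModelConfig:
    features_per_gene: int = 3
    gene_dropout: float = 0.5
    pathway_dropout: float = 0.1
    hidden_activation: str = "tanh"
    head_weights: list[float] | None = None  # None -> uniform over heads
    seed: int = 0


@dataclass
class DiagonalLayer:
    """Gene layer: node g connects only to its own ``features_per_gene`` columns."""

    W: np.ndarray  # genes x features_per_gene
    b: np.ndarray  # genes
    activation: str = "tanh"
    dropout_rate: float = 0.5

    @property
    def n_genes(self) -> int:
        return self.W.shape[0]

    @property
    def features_per_gene(self) -> int:
        return self.W.shape[1]

    def pre_activation(self, x: np.ndarray) -> np.ndarray:
        """x: batch x (features_per_gene * genes), gene-major blocks."""
        m, f = self.n_genes, self.features_per_gene
        if x.shape[1] != m * f:
            raise StructuralError(f"input width {x.shape[1]} != {m * f}")
        return (x.reshape(-1, m, f) * self.W[None, :, :]).sum(axis=2) + self.b

    def dense_weight(self) -> np.ndarray:
        """The equivalent (genes x features) dense weight with off-block zeros."""
        m, f = self.n_genes, self.features_per_gene
        W = np.zeros((m, m * f))
        for g in range(m):
            W[g, g * f : (g + 1) * f] = self.W[g]
        return W

    def n_params(self) -> tuple[int, int]:
        return self.W.size, self.b.size


@dataclass
class SparseLayer:
    """Masked affine layer: effective weights are W * M elementwise."""

    W: np.ndarray  # targets x sources
    b: np.ndarray  # targets
    M: np.ndarray  # binary, same shape as W
    activation: str = "tanh"
    dropout_rate: float = 0.1

    def effective_weight(self) -> np.ndarray:
        return self.W * self.M

    def pre_activation(self, x: np.ndarray) -> np.ndarray:
        return x @ self.effective_weight().T + self.b

    def n_params(self) -> tuple[int, int]:
        return int(self.M.sum()), self.b.size


@dataclass
class Head:
    """Single-unit affine map followed by sigmoid."""

    w: np.ndarray  # sources
    b: float

    def probability(self, a: np.ndarray) -> np.ndarray:
        return sigmoid(a @ self.w + self.b)

    def n_params(self) -> int:
        return self.w.size + 1


@dataclass
class SparseModel:
    gene_layer: DiagonalLayer
    pathway_layers: list[SparseLayer]
    heads: list[Head]
    head_weights: np.ndarray
    gene_list: list[str]
    pathway_layer_ids: list[list[str]]
    config: ModelConfig = field(default_factory=ModelConfig)

    @property
    def hidden_sizes(self) -> list[int]:
        return [self.gene_layer.n_genes] + [l.W.shape[0] for l in self.pathway_layers]

    @property
    def n_inputs(self) -> int:
        return self.gene_layer.n_genes * self.gene_layer.features_per_gene

    def hidden_layers(self):
        return [self.gene_layer] + list(self.pathway_layers)

    # -- forward ----------------------------------------------------------

    def forward_cached(
        self, x: np.ndarray, train_mode: bool = False, rng: np.random.Generator | None = None
    ) -> dict:
        """Full forward pass returning every intermediate needed for
        backpropagation and attribution.

        Per hidden layer: pre-activation ``z``, activation ``a`` (what the
        heads read), dropout mask, and the dropped value fed downstream.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if not np.isfinite(x).all():
            raise ValidationError("non-finite values in model input")
        if train_mode and rng is None:
            raise ConfigurationError("train_mode requires an rng for dropout")

        cache = {"x": x, "z": [], "a": [], "drop": [], "u": []}
        u = x
        for layer in self.hidden_layers():
            cache["u"].append(u)
            z = layer.pre_activation(u)
            a = ACTIVATIONS[layer.activation](z)
            if train_mode and layer.dropout_rate > 0.0:
                keep = 1.0 - layer.dropout_rate
                mask = (rng.random(a.shape) < keep).astype(np.float64) / keep
            else:
                mask = np.ones_like(a)
            cache["z"].append(z)
            cache["a"].append(a)
            cache["drop"].append(mask)
            u = a * mask
        head_z = np.stack(
            [a @ h.w + h.b for a, h in zip(cache["a"], self.heads)], axis=1
        )  # batch x heads
        cache["head_z"] = head_z
        cache["head_p"] = sigmoid(head_z)
        cache["combined"] = cache["head_p"] @ self.head_weights
        return cache


def forward(
    model: SparseModel,
    x: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Run the model; returns (per-head probabilities, hidden activations)."""
    cache = model.forward_cached(x, train_mode=train_mode, rng=rng)
    return cache["head_p"], cache["a"]


def predict_proba(model: SparseModel, x: np.ndarray) -> np.ndarray:
    """Deterministic combined probability (evaluation mode, dropout off)."""
    cache = model.forward_cached(x, train_mode=False)
    return cache["combined"]


def combine_heads(head_probs, head_weights) -> np.ndarray:
    """Convex combination of head probabilities."""
    head_probs = np.asarray(head_probs, dtype=np.float64)
    w = np.asarray(head_weights, dtype=np.float64)
    if head_probs.shape[-1] != w.shape[0]:
        raise ValidationError(
            f"{head_probs.shape[-1]} head probabilities vs {w.shape[0]} weights"
        )
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("head weights must be non-negative and sum to 1")
    return head_probs @ w


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def init_model(h: SelectedHierarchy, config: ModelConfig | None = None) -> SparseModel:
    """Build a model from a selected hierarchy with seeded initialization.

    Weights draw from a symmetric uniform scaled by each node's unmasked
    fan-in; masked entries start (and stay) exactly zero; biases start zero.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(config.seed)

    for i, mask in enumerate(h.masks):
        expected_cols = len(h.gene_list) if i == 0 else len(h.pathway_layers[i - 1])
        if mask.shape != (len(h.pathway_layers[i]), expected_cols):
            raise StructuralError(
                f"mask {i} shape {mask.shape} inconsistent with layer sizes"
            )

    m = len(h.gene_list)
    f = config.features_per_gene
    lim = np.sqrt(6.0 / f)
    gene_layer = DiagonalLayer(
        W=rng.uniform(-lim, lim, size=(m, f)),
        b=np.zeros(m),
        activation=config.hidden_activation,
        dropout_rate=config.gene_dropout,
    )

    pathway_layers: list[SparseLayer] = []
    for mask in h.masks:
        M = mask.to_dense()
        n_t, n_s = M.shape
        W = np.zeros((n_t, n_s))
        fan_in = M.sum(axis=1)
        for i in range(n_t):
            cols = np.flatnonzero(M[i])
            if cols.size:
                lim_i = np.sqrt(6.0 / max(fan_in[i], 1.0))
                W[i, cols] = rng.uniform(-lim_i, lim_i, size=cols.size)
        pathway_layers.append(
            SparseLayer(
                W=W,
                b=np.zeros(n_t),
                M=M,
                activation=config.hidden_activation,
                dropout_rate=config.pathway_dropout,
            )
        )
    # no dropout after the last hidden layer
    if pathway_layers:
        pathway_layers[-1].dropout_rate = 0.0

    heads: list[Head] = []
    for size in [m] + [len(layer) for layer in h.pathway_layers]:
        lim_h = np.sqrt(6.0 / size)
        heads.append(Head(w=rng.uniform(-lim_h, lim_h, size=size), b=0.0))

    n_heads = len(heads)
    if config.head_weights is None:
        head_weights = np.full(n_heads, 1.0 / n_heads)
    else:
        head_weights = np.asarray(config.head_weights, dtype=np.float64)
        if head_weights.shape != (n_heads,):
            raise ConfigurationError(f"need {n_heads} head weights")
        if (head_weights < 0).any() or abs(head_weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError("head weights must be convex")

    return SparseModel(
        gene_layer=gene_layer,
        pathway_layers=pathway_layers,
        heads=heads,
        head_weights=head_weights,
        gene_list=list(h.gene_list),
        pathway_layer_ids=[list(layer) for layer in h.pathway_layers],
        config=config,
    )


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------


@dataclass
class ParamCountReport:
    """Trainable-parameter accounting, sparse vs dense-equivalent."""

    layers: list[dict]  # {"name", "weights", "biases", "total"}
    heads: list[dict]  # {"name", "total"}
    sparse_total: int
    dense_node_counts: list[int]
    dense_total: int

    @property
    def ratio(self) -> float:
        return self.sparse_total / self.dense_total

    def to_dict(self) -> dict:
        return {
            "layers": self.layers,
            "heads": self.heads,
            "sparse_total": self.sparse_total,
            "dense_node_counts": self.dense_node_counts,
            "dense_total": self.dense_total,
            "sparse_to_dense_ratio": self.ratio,
        }


def count_dense_params(node_counts: list[int]) -> int:
    """Dense-equivalent parameter count: sum of n_l * (n_{l-1} + 1)."""
    if len(node_counts) < 2:
        raise ValidationError("need at least an input and one layer")
    if any(n <= 0 for n in node_counts):
        raise ValidationError(f"non-positive layer size in {node_counts}")
    return sum(n_l * (n_prev + 1) for n_prev, n_l in zip(node_counts, node_counts[1:]))


def count_from_architecture(
    n_genes: int,
    features_per_gene: int,
    pathway_sizes: list[int],
    pathway_nnz: list[int],
) -> ParamCountReport:
    """Parameter report from architecture numbers alone (no weights needed)."""
    layers = [
        {
            "name": "h0 (diagonal)",
            "weights": n_genes * features_per_gene,
            "biases": n_genes,
            "total": n_genes * (features_per_gene + 1),
        }
    ]
    for i, (size, nnz) in enumerate(zip(pathway_sizes, pathway_nnz), start=1):
        layers.append({"name": f"h{i} (sparse)", "weights": nnz, "biases": size, "total": nnz + size})
    heads = []
    for i, size in enumerate([n_genes] + list(pathway_sizes), start=1):
        heads.append({"name": f"o_linear{i}", "total": size + 1})
    sparse_total = sum(l["total"] for l in layers) + sum(h["total"] for h in heads)
    node_counts = [n_genes * features_per_gene, n_genes] + list(pathway_sizes) + [1]
    return ParamCountReport(
        layers=layers,
        heads=heads,
        sparse_total=sparse_total,
        dense_node_counts=node_counts,
        dense_total=count_dense_params(node_counts),
    )


def count_sparse_params(model: SparseModel) -> ParamCountReport:
    """Parameter report for an instantiated model; nnz read from the masks."""
    return count_from_architecture(
        n_genes=model.gene_layer.n_genes,
        features_per_gene=model.gene_layer.features_per_gene,
        pathway_sizes=[l.W.shape[0] for l in model.pathway_layers],
        pathway_nnz=[int(l.M.sum()) for l in model.pathway_layers],
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: SparseModel, out_dir) -> None:
    """Write manifest.json + weights.npz + triplet mask files; reload is bit-exact."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "gene_list": model.gene_list,
        "pathway_layer_ids": model.pathway_layer_ids,
        "features_per_gene": model.gene_layer.features_per_gene,
        "hidden_activation": model.gene_layer.activation,
        "gene_dropout": model.gene_layer.dropout_rate,
        "pathway_dropouts": [l.dropout_rate for l in model.pathway_layers],
        "head_weights": model.head_weights.tolist(),
        "seed": model.config.seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    arrays = {"gene_W": model.gene_layer.W, "gene_b": model.gene_layer.b}
    for i, layer in enumerate(model.pathway_layers):
        arrays[f"W_{i}"] = layer.W
        arrays[f"b_{i}"] = layer.b
    for i, head in enumerate(model.heads):
        arrays[f"head_w_{i}"] = head.w
        arrays[f"head_b_{i}"] = np.array([head.b])
    np.savez(out_dir / "weights.npz", **arrays)
    for i, layer in enumerate(model.pathway_layers):
        row_ids = model.pathway_layer_ids[i]
        col_ids = model.gene_list if i == 0 else model.pathway_layer_ids[i - 1]
        mask = MaskMatrix(
            row_ids=row_ids,
            col_ids=col_ids,
            matrix=_to_csr(layer.M),
        )
        lines = [f"{r}\t{c}" for r, c in mask.triplets()]
        (out_dir / f"mask_{i}.tsv").write_text("\n".join(lines) + ("\n" if lines else ""))


def _to_csr(dense: np.ndarray):
    from scipy import sparse

    return sparse.csr_matrix(dense.astype(np.int8))


def load_model(in_dir) -> SparseModel:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    arrays = np.load(in_dir / "weights.npz")
    gene_list = manifest["gene_list"]
    pathway_layer_ids = manifest["pathway_layer_ids"]
    config = ModelConfig(
        features_per_gene=manifest["features_per_gene"],
        gene_dropout=manifest["gene_dropout"],
        hidden_activation=manifest["hidden_activation"],
        head_weights=manifest["head_weights"],
        seed=manifest.get("seed", 0),
    )
    gene_layer = DiagonalLayer(
        W=arrays["gene_W"],
        b=arrays["gene_b"],
        activation=manifest["hidden_activation"],
        dropout_rate=manifest["gene_dropout"],
    )
    pathway_layers = []
    for i, dropout in enumerate(manifest["pathway_dropouts"]):
        row_ids = pathway_layer_ids[i]
        col_ids = gene_list if i == 0 else pathway_layer_ids[i - 1]
        pairs = []
        for line in (in_dir / f"mask_{i}.tsv").read_text().splitlines():
            if line.strip():
                r, c = line.split("\t")
                pairs.append((r, c))
        mask = MaskMatrix.from_triplets(row_ids, col_ids, pairs)
        pathway_layers.append(
            SparseLayer(
                W=arrays[f"W_{i}"],
                b=arrays[f"b_{i}"],
                M=mask.to_dense(),
                activation=manifest["hidden_activation"],
                dropout_rate=dropout,
            )
        )
    heads = [
        Head(w=arrays[f"head_w_{i}"], b=float(arrays[f"head_b_{i}"][0]))
        for i in range(1 + len(pathway_layers))
    ]
    return SparseModel(
        gene_layer=gene_layer,
        pathway_layers=pathway_layers,
        heads=heads,
        head_weights=np.asarray(manifest["head_weights"], dtype=np.float64),
        gene_list=gene_list,
        pathway_layer_ids=pathway_layer_ids,
        config=config,
    )
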