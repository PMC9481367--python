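"""Difference-from-reference contribution propagation (DeepLIFT rescale rule).

Every node's contribution is the product of its difference-from-reference
activation and a multiplier propagated back from the target output: affine
(masked) maps use the linear rule, tanh/sigmoid nonlinearities use the
rescale rule (delta-out over delta-in, falling back to the derivative at
the reference when the input delta vanishes).

Because auxiliary heads branch off every hidden layer, completeness is
checked over graph *cuts*: for the cut through hidden layer l the node
contributions of that layer plus the contributions of the heads emitted
upstream of it sum to the target delta.  With a single-head target the
bypass terms vanish and the per-layer sums alone equal the delta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pathsparse.errors import ConfigurationError, ValidationError
from pathsparse.features import FEATURE_TYPES, FeatureMatrix
from pathsparse.model import SparseModel, activation_derivative

#: below this input delta the rescale ratio is replaced by the reference derivative
DELTA_TOL = 1e-9


@dataclass
class AttributionReport:
    """Per-layer, per-node, per-sample contributions and reference state.

    ``layers[i]`` is a dict with keys ``name``, ``node_ids`` and
    ``contributions`` (samples x nodes).  ``head_contributions[:, j]`` is the
    contribution of head j's output on any cut downstream of it.
    """

    layers: list[dict]
    head_contributions: np.ndarray  # samples x heads
    delta_t: np.ndarray  # samples
    target: str
    reference_activations: list[np.ndarray]
    reference_output: float
    n_samples: int = field(init=False)

    def __post_init__(self):
        self.n_samples = int(self.delta_t.shape[0])

    @property
    def layer_names(self) -> list[str]:
        return [l["name"] for l in self.layers]

    def layer_index(self, layer) -> int:
        if isinstance(layer, int):
            if not 0 <= layer < len(self.layers):
                raise ValidationError(f"no layer {layer}")
            return layer
        names = self.layer_names
        if layer not in names:
            raise ValidationError(f"unknown layer {layer!r}; have {names}")
        return names.index(layer)

    def cut_sum(self, layer) -> np.ndarray:
        """Total contribution across the cut through ``layer``, per sample."""
        i = self.layer_index(layer)
        total = self.layers[i]["contributions"].sum(axis=1)
        # heads attached strictly upstream of this cut bypass it
        n_bypass = max(0, i - 1)  # layer 0 = input, layer 1 = genes (head 0 reads genes)
        if n_bypass:
            total = total + self.head_contributions[:, :n_bypass].sum(axis=1)
        return total

    def max_cut_error(self) -> float:
        return max(
            float(np.abs(self.cut_sum(i) - self.delta_t).max()) for i in range(len(self.layers))
        )

    def aggregate(self, layer) -> np.ndarray:
        """Signed sum of contributions over samples, per node."""
        return self.layers[self.layer_index(layer)]["contributions"].sum(axis=0)


def reference_activations(model: SparseModel, x0: np.ndarray | None = None) -> dict:
    """Record every node's activation under the reference input.

    The default reference is the all-zero (no alteration) profile.
    Returns hidden activations, pre-activations, head probabilities and the
    combined output for the reference.
    """
    if x0 is None:
        x0 = np.zeros(model.n_inputs)
    x0 = np.asarray(x0, dtype=np.float64).reshape(1, -1)
    if not np.isfinite(x0).all():
        raise ValidationError("non-finite reference input")
    cache = model.forward_cached(x0, train_mode=False)
    return {
        "x0": x0,
        "z": cache["z"],
        "a": cache["a"],
        "head_z": cache["head_z"],
        "head_p": cache["head_p"],
        "combined": float(cache["combined"][0]),
    }


def _rescale(delta_out: np.ndarray, delta_in: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Rescale multiplier delta_out/delta_in with removable-singularity fallback."""
    small = np.abs(delta_in) < DELTA_TOL
    safe = np.where(small, 1.0, delta_in)
    return np.where(small, fallback, delta_out / safe)


def deeplift_scores(
    model: SparseModel,
    samples: FeatureMatrix | np.ndarray,
    x0: np.ndarray | None = None,
    target: str | int = "combined",
) -> AttributionReport:
    """Propagate difference-from-reference contributions through the model.

    ``target`` is ``"combined"`` (the convex head combination, default) or an
    integer head index for per-head attribution.
    """
    x = samples.values if isinstance(samples, FeatureMatrix) else np.asarray(samples, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    ref = reference_activations(model, x0)
    cache = model.forward_cached(x, train_mode=False)
    n_heads = len(model.heads)

    if target == "combined":
        m_head_p = model.head_weights.copy()
        t = cache["combined"]
        t0 = ref["combined"]
    else:
        j = int(target)
        if not 0 <= j < n_heads:
            raise ConfigurationError(f"head index {target} out of range")
        m_head_p = np.zeros(n_heads)
        m_head_p[j] = 1.0
        t = cache["head_p"][:, j]
        t0 = float(ref["head_p"][0, j])
    delta_t = t - t0

    # head sigmoid: rescale multiplier per head
    d_head_z = cache["head_z"] - ref["head_z"]  # batch x heads
    d_head_p = cache["head_p"] - ref["head_p"]
    fallback = activation_derivative("sigmoid", np.broadcast_to(ref["head_z"], d_head_z.shape))
    m_head_z = m_head_p[None, :] * _rescale(d_head_p, d_head_z, fallback)

    hidden = model.hidden_layers()
    n_hidden = len(hidden)
    delta_a = [cache["a"][l] - ref["a"][l] for l in range(n_hidden)]
    delta_z = [cache["z"][l] - ref["z"][l] for l in range(n_hidden)]

    # multipliers on the hidden activations, back to front
    m_a: list[np.ndarray | None] = [None] * n_hidden
    for l in range(n_hidden - 1, -1, -1):
        m = m_head_z[:, l][:, None] * model.heads[l].w[None, :]
        if l + 1 < n_hidden:
            layer_up = hidden[l + 1]
            fb = activation_derivative(layer_up.activation, np.broadcast_to(ref["z"][l + 1], delta_z[l + 1].shape))
            m_z_up = m_a[l + 1] * _rescale(delta_a[l + 1], delta_z[l + 1], fb)
            m = m + m_z_up @ layer_up.effective_weight()
        m_a[l] = m

    # through the diagonal gene layer down to the input features
    gene = model.gene_layer
    fb0 = activation_derivative(gene.activation, np.broadcast_to(ref["z"][0], delta_z[0].shape))
    m_z0 = m_a[0] * _rescale(delta_a[0], delta_z[0], fb0)
    m_x = (m_z0[:, :, None] * gene.W[None, :, :]).reshape(x.shape[0], -1)
    delta_x = x - ref["x0"]

    feature_ids = [f"{g}_{t_}" for g in model.gene_list for t_ in FEATURE_TYPES]
    layers = [{"name": "input", "node_ids": feature_ids, "contributions": m_x * delta_x}]
    layers.append({"name": "genes", "node_ids": list(model.gene_list), "contributions": m_a[0] * delta_a[0]})
    for i, ids in enumerate(model.pathway_layer_ids):
        layers.append(
            {
                "name": f"pathway_{i + 1}",
                "node_ids": list(ids),
                "contributions": m_a[i + 1] * delta_a[i + 1],
            }
        )
    head_contributions = m_head_p[None, :] * d_head_p
    return AttributionReport(
        layers=layers,
        head_contributions=head_contributions,
        delta_t=delta_t,
        target=str(target),
        reference_activations=[a[0] for a in ref["a"]],
        reference_output=t0,
    )


def rank_nodes(report: AttributionReport, layer) -> list[tuple[str, float]]:
    """Nodes of a layer ordered by |signed-sum aggregate|, descending.

    Ties break lexicographically by node id; invariant to sample order.
    """
    i = report.layer_index(layer)
    agg = report.aggregate(i)
    ids = report.layers[i]["node_ids"]
    order = sorted(range(len(ids)), key=lambda j: (-abs(agg[j]), ids[j]))
    return [(ids[j], float(agg[j])) for j in order]


def write_ranked_tsv(report: AttributionReport, layer, path, names: dict | None = None) -> None:
    ranked = rank_nodes(report, layer)
    lines = ["node_id\tname\taggregate_score\trank"]
    for rank, (node, score) in enumerate(ranked, start=1):
        name = (names or {}).get(node, "")
        lines.append(f"{node}\t{name}\t{score:.6g}\t{rank}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_sankey(model: SparseModel, report: AttributionReport, top_k: int) -> dict:
    """Sankey-ready JSON: top-k nodes per layer and the retained edges.

    Link values are the absolute effective weights; node colour weights are
    aggregate scores normalized to [0, 1] within each layer.  A feature-type
    summary (mutation vs amplification vs deletion) is included.
    """
    if top_k < 1:
        raise ConfigurationError("top_k must be >= 1")

    selected: list[list[str]] = []
    nodes = []
    for i, layer in enumerate(report.layers):
        ranked = rank_nodes(report, i)[:top_k]
        kept = [node for node, _ in ranked]
        selected.append(kept)
        scores = np.array([abs(s) for _, s in ranked])
        max_score = scores.max() if scores.size and scores.max() > 0 else 1.0
        for (node, score) in ranked:
            nodes.append(
                {
                    "id": node,
                    "layer": layer["name"],
                    "score": float(score),
                    "color_weight": float(abs(score) / max_score),
                }
            )

    links = []
    # input -> gene: diagonal connectivity
    gene = model.gene_layer
    kept_inputs, kept_genes = set(selected[0]), set(selected[1])
    for g_idx, g in enumerate(model.gene_list):
        if g not in kept_genes:
            continue
        for f_idx, t_ in enumerate(FEATURE_TYPES):
            fid = f"{g}_{t_}"
            if fid in kept_inputs:
                links.append(
                    {"source": fid, "target": g, "value": float(abs(gene.W[g_idx, f_idx]))}
                )
    # masked layers
    sources = [model.gene_list] + model.pathway_layer_ids[:-1]
    for li, layer in enumerate(model.pathway_layers):
        weff = layer.effective_weight()
        src_ids, tgt_ids = sources[li], model.pathway_layer_ids[li]
        kept_src, kept_tgt = set(selected[li + 1]), set(selected[li + 2])
        for ti, tgt in enumerate(tgt_ids):
            if tgt not in kept_tgt:
                continue
            for si in np.flatnonzero(layer.M[ti]):
                src = src_ids[si]
                if src in kept_src:
                    links.append({"source": src, "target": tgt, "value": float(abs(weff[ti, si]))})

    input_agg = report.aggregate(0)
    feature_totals = {}
    for f_idx, t_ in enumerate(FEATURE_TYPES):
        block = input_agg[f_idx::len(FEATURE_TYPES)]
        feature_totals[t_] = {
            "signed": float(block.sum()),
            "absolute": float(np.abs(block).sum()),
        }
    return {"nodes": nodes, "links": links, "feature_type_totals": feature_totals}


def write_sankey_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=1))
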