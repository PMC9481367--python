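"""Pathway hierarchy parsing, layerization, and connectivity-mask construction.

The hierarchy dialect is the Reactome download triplet:

* a two-column parent TAB child relation file,
* a GMT gene-set file (id, description, member gene symbols...),
* a three-column name file (id, name, species).

From the relation file a directed acyclic graph is built (edges point from
parent pathway to child pathway), every node is assigned to the depth layer
given by its longest path from any root, and skip-level edges are realized
with pass-through *copy* nodes so that every retained edge connects adjacent
layers.  A k-layer sub-hierarchy (default k=4) is then selected and reversed
into network order -- the deepest selected layer, whose nodes carry gene
annotations, becomes the first pathway layer of the model -- and the binary
connectivity masks between adjacent layers are emitted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import sparse

from pathsparse.errors import ConfigurationError, ParseError, StructuralError

logger = logging.getLogger(__name__)

#: separator used to derive copy-node ids; must not occur in pathway ids
COPY_SEP = "::copy"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PathwayGeneSets:
    """Mapping from pathway id to its name and (deduplicated) gene-symbol set."""

    entries: dict[str, dict]  # id -> {"name": str, "genes": set[str]}

    def genes_of(self, pathway_id: str) -> set[str]:
        entry = self.entries.get(pathway_id)
        return set() if entry is None else entry["genes"]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PathwayDAG:
    """Directed acyclic pathway graph; edges point parent -> child."""

    nodes: set[str]
    edges: set[tuple[str, str]]
    species_tag: str = "HSA"

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class LayeredHierarchy:
    """Depth-layered DAG with copy chains inserted for skip-level edges.

    ``layers[0]`` holds the roots (layer 1); every retained edge in ``edges``
    connects a node to one in the next layer.  ``copies`` maps each inserted
    pass-through node to the original pathway it duplicates.
    """

    layers: list[list[str]]
    node_layer: dict[str, int]  # node id -> 1-based layer index
    copies: dict[str, str]
    edges: set[tuple[str, str]]

    @property
    def depth(self) -> int:
        return len(self.layers)

    def original_of(self, node_id: str) -> str:
        return self.copies.get(node_id, node_id)


@dataclass
class MaskMatrix:
    """Binary connectivity between a source and a target layer.

    ``matrix`` has one row per target node and one column per source node;
    entry (i, j) is 1 iff target node i receives input from source node j.
    """

    row_ids: list[str]
    col_ids: list[str]
    matrix: sparse.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def nnz(self) -> int:
        return int(self.matrix.nnz)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense(), dtype=np.float64)

    def triplets(self) -> list[tuple[str, str]]:
        """(row-id, col-id) pairs of the nonzero entries, row-major sorted."""
        coo = self.matrix.tocoo()
        pairs = [(self.row_ids[i], self.col_ids[j]) for i, j in zip(coo.row, coo.col)]
        return sorted(pairs)

    @classmethod
    def from_triplets(
        cls, row_ids: list[str], col_ids: list[str], pairs: list[tuple[str, str]]
    ) -> "MaskMatrix":
        ri = {n: i for i, n in enumerate(row_ids)}
        ci = {n: i for i, n in enumerate(col_ids)}
        rows = [ri[r] for r, _ in pairs]
        cols = [ci[c] for _, c in pairs]
        mat = sparse.csr_matrix(
            (np.ones(len(pairs), dtype=np.int8), (rows, cols)),
            shape=(len(row_ids), len(col_ids)),
        )
        mat.sum_duplicates()
        mat.data = np.minimum(mat.data, 1).astype(np.int8)
        return cls(row_ids=row_ids, col_ids=col_ids, matrix=mat)


@dataclass
class SelectedHierarchy:
    """The network blueprint: ordered pathway layers, gene list, and masks.

    ``pathway_layers[0]`` is the *first* pathway layer in network order, i.e.
    the deepest selected DAG layer; its nodes carry the gene annotations that
    define ``gene_list``.  ``masks[0]`` is the gene -> pathway-layer-1
    adjacency; ``masks[i]`` (i >= 1) connects pathway layer i to layer i+1.
    """

    pathway_layers: list[list[str]]
    gene_list: list[str]
    masks: list[MaskMatrix]
    copies: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.pathway_layers)

    @property
    def layer_sizes(self) -> list[int]:
        return [len(layer) for layer in self.pathway_layers]


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------


def parse_relations(path, species: str = "HSA") -> PathwayDAG:
    """Read a two-column parent/child TSV and keep edges of one species.

    An edge is retained only when *both* ids contain ``species``.  Raises
    :class:`ParseError` on malformed lines and :class:`StructuralError` if the
    retained edges contain a cycle.
    """
    path = Path(path)
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(
                    f"expected 'parent<TAB>child', got {line!r}", path=path, line=lineno
                )
            parent, child = parts[0].strip(), parts[1].strip()
            if species not in parent or species not in child:
                continue
            if parent == child:
                raise StructuralError(f"self-edge on {parent!r} (line {lineno})")
            nodes.add(parent)
            nodes.add(child)
            edges.add((parent, child))

    g = nx.DiGraph()
    g.add_edges_from(edges)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        u, v = cycle[0][0], cycle[0][1]
        raise StructuralError(f"relation file contains a cycle through edge {u!r} -> {v!r}")
    return PathwayDAG(nodes=nodes, edges=edges, species_tag=species)


def parse_gmt(path) -> PathwayGeneSets:
    """Read a GMT file: ``id TAB description TAB gene TAB gene ...`` per line."""
    path = Path(path)
    entries: dict[str, dict] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"GMT line needs id, description and >=1 gene, got {len(parts)} fields",
                    path=path,
                    line=lineno,
                )
            pid, name = parts[0].strip(), parts[1].strip()
            if pid in entries:
                raise ParseError(f"duplicate pathway id {pid!r}", path=path, line=lineno)
            genes = {g.strip() for g in parts[2:] if g.strip()}
            if not genes:
                raise ParseError(f"pathway {pid!r} has an empty gene set", path=path, line=lineno)
            entries[pid] = {"name": name, "genes": genes}
    return PathwayGeneSets(entries=entries)


def parse_names(path) -> dict[str, dict]:
    """Read the three-column name TSV: id, human-readable name, species."""
    path = Path(path)
    out: dict[str, dict] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"expected 'id<TAB>name<TAB>species', got {len(parts)} fields",
                    path=path,
                    line=lineno,
                )
            out[parts[0].strip()] = {"name": parts[1].strip(), "species": parts[2].strip()}
    return out


# ---------------------------------------------------------------------------
# layer assignment
# ---------------------------------------------------------------------------


def assign_layers(dag: PathwayDAG) -> LayeredHierarchy:
    """Assign every node to 1 + its longest-path distance from any root.

    Roots (in-degree zero) form layer 1.  An edge spanning more than one layer
    is replaced by a chain of pass-through copies of the *parent*, one per
    intermediate layer, so the adjacency invariant layer(child) =
    layer(parent) + 1 holds for every retained edge.
    """
    if not dag.nodes:
        raise StructuralError("cannot layer an empty DAG")
    g = dag.to_networkx()
    order = list(nx.topological_sort(g))
    depth: dict[str, int] = {}
    for node in order:
        preds = list(g.predecessors(node))
        depth[node] = 1 if not preds else 1 + max(depth[p] for p in preds)

    copies: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    copy_at: dict[tuple[str, int], str] = {}  # (original, layer) -> copy id

    def copy_node(original: str, layer: int) -> str:
        key = (original, layer)
        if key not in copy_at:
            cid = f"{original}{COPY_SEP}{layer}"
            copy_at[key] = cid
            copies[cid] = original
            depth[cid] = layer
        return copy_at[key]

    for parent, child in dag.edges:
        span = depth[child] - depth[parent]
        if span == 1:
            edges.add((parent, child))
            continue
        # chain parent through copies at each intermediate layer
        prev = parent
        for layer in range(depth[parent] + 1, depth[child]):
            cur = copy_node(parent, layer)
            edges.add((prev, cur))
            prev = cur
        edges.add((prev, child))

    max_depth = max(depth.values())
    layers: list[list[str]] = [[] for _ in range(max_depth)]
    for node, d in depth.items():
        layers[d - 1].append(node)
    for layer in layers:
        layer.sort()
    return LayeredHierarchy(layers=layers, node_layer=dict(depth), copies=copies, edges=edges)


# ---------------------------------------------------------------------------
# sub-hierarchy selection
# ---------------------------------------------------------------------------


def select_sublayers(
    h: LayeredHierarchy,
    gene_sets: PathwayGeneSets,
    k: int = 4,
    names: dict[str, dict] | None = None,
) -> SelectedHierarchy:
    """Select DAG layers 1..k and reverse them into network order.

    The deepest selected DAG layer becomes pathway layer 1 of the network;
    its nodes' gene sets (copies resolve to their original pathway) define
    ``gene_list``.  Nodes without any gene support below them are pruned
    bottom-up so no mask row is all-zero.
    """
    if k < 1 or k > h.depth:
        raise ConfigurationError(f"k={k} outside [1, {h.depth}]")

    dag_layers = [list(layer) for layer in h.layers[:k]]

    def resolved_genes(node: str) -> set[str]:
        return gene_sets.genes_of(h.original_of(node))

    # children within the selection, per node
    children: dict[str, list[str]] = {n: [] for layer in dag_layers for n in layer}
    for parent, child in h.edges:
        if h.node_layer.get(parent, 0) <= k - 1 and h.node_layer.get(child, 0) <= k:
            if parent in children and child in children:
                children[parent].append(child)

    # bottom-up pruning: deepest layer keeps nodes with genes, upper layers
    # keep nodes with at least one kept child
    kept: list[set[str]] = [set() for _ in range(k)]
    for node in dag_layers[k - 1]:
        if resolved_genes(node):
            kept[k - 1].add(node)
        else:
            logger.warning("pruning %s: no gene annotation", node)
    for i in range(k - 2, -1, -1):
        for node in dag_layers[i]:
            if any(c in kept[i + 1] for c in children[node]):
                kept[i].add(node)
            else:
                logger.warning("pruning %s: no gene-supported descendant", node)

    for i, kept_layer in enumerate(kept):
        if not kept_layer:
            raise StructuralError(
                f"DAG layer {i + 1} empty after pruning; hierarchy cannot support {k} layers"
            )

    # network order: pathway layer 1 = DAG layer k, ..., pathway layer k = DAG layer 1
    pathway_layers = [sorted(kept[k - 1 - t]) for t in range(k)]

    gene_union: set[str] = set()
    for node in pathway_layers[0]:
        gene_union |= resolved_genes(node)
    gene_list = sorted(gene_union)

    masks: list[MaskMatrix] = []
    p1 = pathway_layers[0]
    gene_index = {g: j for j, g in enumerate(gene_list)}
    rows, cols = [], []
    for i, node in enumerate(p1):
        for gene in resolved_genes(node):
            rows.append(i)
            cols.append(gene_index[gene])
    adj = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(len(p1), len(gene_list))
    )
    masks.append(MaskMatrix(row_ids=list(p1), col_ids=list(gene_list), matrix=adj))

    for t in range(1, k):
        src = pathway_layers[t - 1]  # deeper DAG layer (children)
        tgt = pathway_layers[t]  # shallower DAG layer (parents)
        src_index = {n: j for j, n in enumerate(src)}
        rows, cols = [], []
        for i, parent in enumerate(tgt):
            for child in children[parent]:
                if child in src_index:
                    rows.append(i)
                    cols.append(src_index[child])
        mat = sparse.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(len(tgt), len(src))
        )
        masks.append(MaskMatrix(row_ids=list(tgt), col_ids=list(src), matrix=mat))

    name_map: dict[str, str] = {}
    if names:
        for layer in pathway_layers:
            for node in layer:
                orig = h.original_of(node)
                if orig in names:
                    name_map[node] = names[orig]["name"]
    copies_used = {
        n: orig
        for n, orig in h.copies.items()
        if any(n in layer for layer in pathway_layers)
    }
    return SelectedHierarchy(
        pathway_layers=pathway_layers,
        gene_list=gene_list,
        masks=masks,
        copies=copies_used,
        names=name_map,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_selected(selected: SelectedHierarchy, out_dir) -> None:
    """Write a selected hierarchy as layers.json + sparse triplet mask files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "pathway_layers": selected.pathway_layers,
        "gene_list": selected.gene_list,
        "copies": selected.copies,
        "names": selected.names,
        "n_masks": len(selected.masks),
    }
    (out_dir / "layers.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for i, mask in enumerate(selected.masks):
        lines = [f"{r}\t{c}" for r, c in mask.triplets()]
        (out_dir / f"mask_{i}.tsv").write_text("\n".join(lines) + ("\n" if lines else ""))


def read_selected(in_dir) -> SelectedHierarchy:
    """Inverse of :func:`write_selected`; reproduces identical masks."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "layers.json").read_text())
    pathway_layers = manifest["pathway_layers"]
    gene_list = manifest["gene_list"]
    masks: list[MaskMatrix] = []
    for i in range(manifest["n_masks"]):
        pairs = []
        text = (in_dir / f"mask_{i}.tsv").read_text()
        for line in text.splitlines():
            if line.strip():
                r, c = line.split("\t")
                pairs.append((r, c))
        if i == 0:
            row_ids, col_ids = pathway_layers[0], gene_list
        else:
            row_ids, col_ids = pathway_layers[i], pathway_layers[i - 1]
        masks.append(MaskMatrix.from_triplets(row_ids, col_ids, pairs))
    return SelectedHierarchy(
        pathway_layers=pathway_layers,
        gene_list=gene_list,
        masks=masks,
        copies=manifest.get("copies", {}),
        names=manifest.get("names", {}),
    )
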