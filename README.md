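# pathsparse

Pathway-structured sparse neural networks for binary survival
classification, with difference-from-reference (DeepLIFT-style)
interpretation.

The package builds a layered network blueprint from a pathway hierarchy
(gene-set GMT, parent–child relation TSV, name TSV in the Reactome
dialects), encodes per-sample somatic mutation and discrete copy-number
calls as binary features (mutation / amplification / deletion per gene),
trains a mask-constrained feed-forward model — a diagonal gene layer plus
four pathway layers, each with an auxiliary single-unit sigmoid head — and
ranks genes and pathways by propagated contribution scores.

Everything runs on NumPy/SciPy; no deep-learning framework is required.
A synthetic-fixture module generates a toy hierarchy and a cohort with
planted gene–outcome signal so the full pipeline is testable offline.

## CLI

All commands hang off a single entry point:

```bash
# generate synthetic inputs (hierarchy files + cohort tables)
pathsparse simulate --seed 1 --out work/sim

# parse the hierarchy and write the 4-layer blueprint (layers.json + masks)
pathsparse build-hierarchy \
    --relations work/sim/hierarchy/relations.tsv \
    --gmt work/sim/hierarchy/pathways.gmt \
    --names work/sim/hierarchy/names.tsv \
    --layers 4 --species HSA --out work/hier

# encode features, label survival at the 60-month horizon, split 80/10/10
pathsparse prepare \
    --mutations work/sim/cohort/mutations.maf.tsv \
    --cnv work/sim/cohort/cnv.tsv \
    --clinical work/sim/cohort/clinical.csv \
    --hierarchy work/hier --horizon 60 --seed 1 --out work/data

# train (Adam, stepped learning-rate decay, deep supervision)
pathsparse train --data work/data --hierarchy work/hier --seed 1 --out work/model

# metrics for the network and the five baseline families
pathsparse evaluate --model work/model --data work/data --out work/report.tsv

# contribution scores, per-layer rankings, Sankey JSON
pathsparse attribute --model work/model --data work/data --out work/attr

# parameter-count report (sparse vs dense-equivalent)
pathsparse inspect-model --model work/model --report params
```

## Layout

- `src/pathsparse/hierarchy.py` — dialect parsers, DAG layerization
  (longest-path depth with pass-through copy chains for skip-level edges),
  sub-hierarchy selection, connectivity masks.
- `src/pathsparse/features.py` — mutation/CNV binarization, survival
  labeling, stratified splitting.
- `src/pathsparse/model.py` — diagonal gene layer, masked pathway layers,
  heads, forward pass, parameter counting, serialization.
- `src/pathsparse/trainer.py` — BCE loss, learning-rate schedule, Adam
  loop with gradient masking and best-checkpoint selection.
- `src/pathsparse/attribution.py` — rescale-rule contribution propagation,
  node ranking, Sankey export.
- `src/pathsparse/evaluation.py` — metrics and the baseline harness.
- `src/pathsparse/simulate.py` — synthetic hierarchy and cohort fixtures.
- `src/pathsparse/pipeline.py` — end-to-end fixture pipeline helpers.
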