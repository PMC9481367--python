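"""Cohort feature assembly: mutation/CNV binarization, survival labels, splits.

Features are binary and laid out gene-major: for each gene in the hierarchy
gene list, three consecutive columns encode (mutation, amplification,
deletion).  Labels follow the survival-horizon rule: samples surviving past
the horizon are long-term survivors (label 0) regardless of vital status,
samples that died before the horizon are short-term (label 1), and samples
censored alive before the horizon are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pathsparse.errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("mutation", "amplification", "deletion")


@dataclass
class FeatureMatrix:
    """samples x (3 * genes) binary matrix with gene-major column blocks."""

    samples: list[str]
    genes: list[str]
    values: np.ndarray  # float64 in {0,1}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.samples), 3 * len(self.genes)):
            raise ValidationError(
                f"feature matrix shape {self.values.shape} != "
                f"({len(self.samples)}, {3 * len(self.genes)})"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValidationError("feature values must all be 0 or 1")

    @property
    def column_names(self) -> list[str]:
        return [f"{g}_{t}" for g in self.genes for t in FEATURE_TYPES]

    def rows_for(self, sample_ids: list[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.samples)}
        return self.values[[index[s] for s in sample_ids]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.column_names)


@dataclass
class CohortLabels:
    """sample id -> binary outcome; 1 = short-term survival (poor prognosis)."""

    labels: dict[str, int]
    excluded: list[str] = field(default_factory=list)

    def vector_for(self, sample_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[s] for s in sample_ids], dtype=np.float64)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class DataSplit:
    train: list[str]
    validation: list[str]
    test: list[str]
    fractions: tuple[float, float, float]
    seed: int

    def as_dict(self) -> dict:
        return {
            "train": self.train,
            "validation": self.validation,
            "test": self.test,
            "fractions": list(self.fractions),
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_maf_lite(path) -> pd.DataFrame:
    """Read a MAF-lite TSV with at least columns (sample, gene)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "gene" not in cols:
        raise ValidationError(f"MAF-lite file needs 'sample' and 'gene' columns, has {list(df.columns)}")
    return df.rename(columns={cols["sample"]: "sample", cols["gene"]: "gene"})


def read_gene_sample_matrix(path) -> pd.DataFrame:
    """Read a gene x sample matrix (TSV or CSV, genes as row index)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table with columns (sample, months, status)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    required = {"sample", "months", "status"}
    if not required.issubset(cols):
        raise ValidationError(f"clinical table needs columns {sorted(required)}, has {list(df.columns)}")
    return df.rename(columns={cols[c]: c for c in required})


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------


def binarize_mutations(mutations, genes: list[str], samples: list[str]) -> np.ndarray:
    """Collapse mutation evidence to 1 = at least one recorded mutation.

    ``mutations`` is either a MAF-lite DataFrame (columns sample, gene) or a
    gene x sample count matrix.  Symbols absent from ``genes`` are dropped
    with a logged count.  Returns a genes x samples {0,1} float array.
    """
    gene_index = {g: i for i, g in enumerate(genes)}
    sample_index = {s: j for j, s in enumerate(samples)}
    out = np.zeros((len(genes), len(samples)), dtype=np.float64)

    if isinstance(mutations, pd.DataFrame) and {"sample", "gene"}.issubset(mutations.columns):
        dropped = 0
        for gene, sample in zip(mutations["gene"], mutations["sample"]):
            gi = gene_index.get(gene)
            if gi is None:
                dropped += 1
                continue
            sj = sample_index.get(sample)
            if sj is None:
                logger.warning("mutation record for unknown sample %s retained until labeling", sample)
                continue
            out[gi, sj] = 1.0
        if dropped:
            logger.info("dropped %d mutation records with symbols outside the gene list", dropped)
        return out

    # matrix route: genes as rows, samples as columns, any positive count -> 1
    mat = pd.DataFrame(mutations)
    matched_genes = [g for g in mat.index if g in gene_index]
    dropped = len(mat.index) - len(matched_genes)
    if dropped:
        logger.info("dropped %d matrix rows with symbols outside the gene list", dropped)
    for g in matched_genes:
        for s in mat.columns:
            if s in sample_index and float(mat.loc[g, s]) > 0:
                out[gene_index[g], sample_index[s]] = 1.0
    return out


def encode_cnv(cnv: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split five-level CNV calls into (amplification, deletion) indicators.

    Only the extreme calls count: +2 -> amplification, -2 -> deletion;
    -1/0/1 yield (0, 0).  Any other value raises a validation error naming
    the offending gene and sample.
    """
    values = cnv.to_numpy()
    ok = np.isin(values, (-2, -1, 0, 1, 2))
    if not ok.all():
        gi, sj = np.argwhere(~ok)[0]
        raise ValidationError(
            f"CNV value {values[gi, sj]!r} for gene {cnv.index[gi]!r}, "
            f"sample {cnv.columns[sj]!r} not in {{-2,-1,0,1,2}}"
        )
    amp = (values == 2).astype(np.float64)
    dele = (values == -2).astype(np.float64)
    return amp, dele


def label_survival(clinical: pd.DataFrame, horizon_months: float = 60.0) -> CohortLabels:
    """Label samples by the survival horizon; censored-early samples excluded.

    months >= horizon -> 0 (long-term, independent of status); months <
    horizon and dead -> 1; months < horizon and alive -> excluded.  Records
    with missing months or status are excluded with a warning.
    """
    labels: dict[str, int] = {}
    excluded: list[str] = []
    for row in clinical.itertuples(index=False):
        sample = str(row.sample)
        months, status = row.months, row.status
        if pd.isna(months) or pd.isna(status) or str(status).lower() not in ("alive", "dead"):
            logger.warning("sample %s excluded: missing or invalid months/status", sample)
            excluded.append(sample)
            continue
        months = float(months)
        if months < 0:
            raise ValidationError(f"negative survival months for sample {sample}")
        if months >= horizon_months:
            labels[sample] = 0
        elif str(status).lower() == "dead":
            labels[sample] = 1
        else:
            excluded.append(sample)  # censored alive before the horizon
    return CohortLabels(labels=labels, excluded=excluded)


def assemble_features(
    mut: np.ndarray, amp: np.ndarray, dele: np.ndarray, gene_list: list[str], samples: list[str]
) -> FeatureMatrix:
    """Interleave the three indicator matrices into gene-major blocks."""
    if not gene_list:
        raise ValidationError("empty gene list")
    shapes = {np.shape(mut), np.shape(amp), np.shape(dele)}
    expected = (len(gene_list), len(samples))
    if shapes != {expected}:
        raise ValidationError(f"matrix shapes {shapes} do not all equal {expected}")
    stacked = np.stack([mut, amp, dele], axis=-1)  # genes x samples x 3
    values = stacked.transpose(1, 0, 2).reshape(len(samples), 3 * len(gene_list))
    return FeatureMatrix(samples=list(samples), genes=list(gene_list), values=values)


def align_omics(
    mut: np.ndarray,
    amp: np.ndarray,
    dele: np.ndarray,
    mut_samples: list[str],
    cnv_samples: list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Union-align the mutation and CNV sample sets, imputing missing omics as 0."""
    samples = sorted(set(mut_samples) | set(cnv_samples))
    n_genes = mut.shape[0]

    def expand(mat: np.ndarray, present: list[str]) -> np.ndarray:
        out = np.zeros((n_genes, len(samples)), dtype=np.float64)
        idx = {s: j for j, s in enumerate(present)}
        for j, s in enumerate(samples):
            if s in idx:
                out[:, j] = mat[:, idx[s]]
        return out

    missing_cnv = set(mut_samples) - set(cnv_samples)
    missing_mut = set(cnv_samples) - set(mut_samples)
    if missing_cnv:
        logger.info("imputing all-zero CNV for %d samples", len(missing_cnv))
    if missing_mut:
        logger.info("imputing all-zero mutations for %d samples", len(missing_mut))
    return expand(mut, mut_samples), expand(amp, cnv_samples), expand(dele, cnv_samples), samples


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_dataset(
    labels: CohortLabels,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DataSplit:
    """Stratified train/validation/test split with remainder-to-train rounding.

    Validation and test sizes are floor(fraction * N); the remainder goes to
    the training partition.  Within each partition the class proportions are
    preserved to within one sample.  Deterministic for a given seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions {fractions} do not sum to 1")
    ids = sorted(labels.labels)
    n = len(ids)
    by_class: dict[int, list[str]] = {}
    for s in ids:
        by_class.setdefault(labels.labels[s], []).append(s)
    if len(by_class) < 2:
        raise ValidationError("need at least one sample of each class")
    for cls, members in by_class.items():
        if len(members) < 3:
            logger.warning("class %d has only %d samples; stratification degenerates", cls, len(members))

    rng = np.random.default_rng(seed)
    for members in by_class.values():
        rng.shuffle(members)

    def quota(fraction: float) -> dict[int, int]:
        total = int(np.floor(fraction * n))
        floors = {c: int(np.floor(fraction * len(m))) for c, m in by_class.items()}
        rest = total - sum(floors.values())
        fracs = sorted(
            by_class,
            key=lambda c: (fraction * len(by_class[c])) - np.floor(fraction * len(by_class[c])),
            reverse=True,
        )
        for c in fracs[:rest]:
            floors[c] += 1
        return floors

    val_quota = quota(fractions[1])
    test_quota = quota(fractions[2])
    train, val, test = [], [], []
    for c, members in by_class.items():
        nv, nt = val_quota[c], test_quota[c]
        val.extend(members[:nv])
        test.extend(members[nv : nv + nt])
        train.extend(members[nv + nt :])
    return DataSplit(
        train=sorted(train),
        validation=sorted(val),
        test=sorted(test),
        fractions=tuple(fractions),
        seed=seed,
    )
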