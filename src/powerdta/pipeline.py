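"""Dataset handling, cross-validated training and the ablation harness.

The trainer minimizes mean squared error with adaptive-moment gradient
descent under five-fold cross-validation: indices are shuffled once with
the run seed and dealt round-robin into folds, each fold serving once as
the validation set.  Published-scale defaults (500 epochs, batch 512,
learning rate 5e-4, dropout 0.2, protein length 1000) are configurable
down to desk scale.  All randomness — weight init, batch order, dropout
— derives from the run seed, so runs are bit-reproducible
single-threaded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _autodiff as ad
from .chem_graph import (DEFAULT_FEATURE_SPEC, build_power_graph_set,
                         smiles_to_graph)
from .dta_model import DTANetwork, ModelConfig
from .metrics import EvaluationReport, evaluate_predictions, pkd_transform
from .protein_embed import (EmbeddingDictionary, embed_sequence,
                            one_hot_protein, train_embedding_dictionary,
                            AMINO_ACIDS)

logger = logging.getLogger(__name__)


class AffinityRecord(NamedTuple):
    smiles: str
    sequence: str
    affinity: float


@dataclass
class AffinityDataset:
    """A collection of (drug, protein, affinity) triples."""

    records: list[AffinityRecord]
    provenance: str = "generic"          # synthetic | davis-style | kiba-style
    affinity_scale: str = "pKd"          # pKd | KIBA score

    def __len__(self) -> int:
        return len(self.records)

    @property
    def affinities(self) -> np.ndarray:
        return np.array([r.affinity for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["compound_smiles", "target_sequence",
                                     "affinity"])


_SMILES_COLUMNS = {"compound_smiles", "smiles", "compound", "drug"}
_SEQUENCE_COLUMNS = {"target_sequence", "sequence", "target", "protein"}
_AFFINITY_COLUMNS = {"affinity", "label", "kd", "y"}


def _pick_column(frame: pd.DataFrame, names: set[str], default: int) -> str:
    for column in frame.columns:
        if str(column).strip().lower() in names:
            return column
    return frame.columns[default]


def load_dataset(path, fmt: str = "generic") -> AffinityDataset:
    """Read a flat table of (compound SMILES, target sequence, affinity).

    Columns are matched by name when recognizable, else by position.
    Davis-style files carry raw Kd in nM and are transformed to pKd on
    load; kiba-style and generic affinities pass through unchanged.
    Malformed rows abort the load with their 1-based row numbers.
    """
    if fmt not in ("generic", "davis-style", "kiba-style"):
        raise ValueError(f"unknown dataset format: {fmt!r}")
    frame = pd.read_csv(path, sep=None, engine="python")
    if frame.shape[1] < 3:
        raise ValueError("dataset table needs at least three columns")
    smiles_col = _pick_column(frame, _SMILES_COLUMNS, 0)
    seq_col = _pick_column(frame, _SEQUENCE_COLUMNS, 1)
    aff_col = _pick_column(frame, _AFFINITY_COLUMNS, 2)

    records: list[AffinityRecord] = []
    bad_rows: list[int] = []
    for row_number in range(1, len(frame) + 1):
        frame_row = frame.iloc[row_number - 1]
        smiles = frame_row[smiles_col]
        sequence = frame_row[seq_col]
        affinity = frame_row[aff_col]
        ok = (isinstance(smiles, str) and smiles.strip()
              and isinstance(sequence, str) and sequence.strip()
              and np.isfinite(pd.to_numeric(affinity, errors="coerce")))
        if ok:
            value = float(affinity)
            if fmt == "davis-style":
                if value <= 0:
                    ok = False
                else:
                    value = pkd_transform(value)
        if not ok:
            bad_rows.append(row_number)
            continue
        records.append(AffinityRecord(smiles.strip(), sequence.strip(), value))
    if bad_rows:
        raise ValueError(f"malformed dataset rows: {bad_rows}")
    scale = "KIBA score" if fmt == "kiba-style" else "pKd"
    return AffinityDataset(records=records, provenance=fmt,
                           affinity_scale=scale)


@dataclass
class CVSplit:
    """Fold assignment of record indices: shuffled once, dealt round-robin,
    so fold sizes differ by at most one."""

    assignments: np.ndarray
    k: int
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        val = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, val


def make_cv_splits(dataset: AffinityDataset, k: int = 5,
                   seed: int = 0) -> CVSplit:
    if k < 2:
        raise ValueError("need at least two folds")
    n = len(dataset)
    if n < k:
        raise ValueError(f"dataset of {n} records cannot fill {k} folds")
    order = np.random.default_rng(seed).permutation(n)
    assignments = np.empty(n, dtype=int)
    assignments[order] = np.arange(n) % k
    return CVSplit(assignments=assignments, k=k, seed=seed)


@dataclass
class TrainingConfig:
    """Optimization and architecture-size knobs.

    Defaults are the published operating point (500 epochs, protein
    length 1000, batch 512, learning rate 5e-4, dropout 0.2, full power
    set); tests and desk runs shrink epochs/widths via the same fields.
    """

    epochs: int = 500
    protein_max_len: int = 1000
    batch_size: int = 512
    learning_rate: float = 5e-4
    dropout_rate: float = 0.2
    powers: tuple[int, ...] = (1, 2, 3)
    protein_encoder: str = "word2vec"    # word2vec | one-hot
    seed: int = 0
    embedding_dim: int = 100
    block_dims: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: {1: (78, 156, 312), 2: (156, 312), 3: (312,)})
    protein_conv_filters: tuple[int, ...] = (32, 32, 32)
    protein_kernel_sizes: tuple[int, ...] = (8, 8, 8)
    fusion_dims: tuple[int, ...] = (1024, 512)
    folds_to_run: tuple[int, ...] | None = None   # None = every fold

    def __post_init__(self):
        if self.protein_encoder not in ("word2vec", "one-hot"):
            raise ValueError("protein_encoder must be word2vec or one-hot")
        if not self.powers:
            raise ValueError("power-graph exponent set must be non-empty")

    def model_config(self, drug_feature_dim: int) -> ModelConfig:
        if self.protein_encoder == "word2vec":
            channels, rows = self.embedding_dim, self.protein_max_len - 2
        else:
            channels, rows = len(AMINO_ACIDS), self.protein_max_len
        return ModelConfig(
            drug_feature_dim=drug_feature_dim,
            powers=tuple(sorted(self.powers)),
            gcn_block_dims={k: tuple(self.block_dims[k]) for k in self.powers},
            protein_channels=channels,
            protein_rows=rows,
            protein_conv_filters=self.protein_conv_filters,
            protein_kernel_sizes=self.protein_kernel_sizes,
            fusion_dims=self.fusion_dims,
            dropout_rate=self.dropout_rate,
        )


class _FeaturizedSample(NamedTuple):
    node_features: np.ndarray
    power_norms: dict[int, np.ndarray]
    protein_matrix: np.ndarray
    affinity: float


def featurize_dataset(dataset: AffinityDataset, config: TrainingConfig,
                      dictionary: EmbeddingDictionary | None,
                      ) -> list[_FeaturizedSample]:
    """Graph tensors and protein matrices for every record, with caching
    over repeated drugs and targets."""
    drug_cache: dict[str, tuple[np.ndarray, dict[int, np.ndarray]]] = {}
    protein_cache: dict[str, np.ndarray] = {}
    samples = []
    for record in dataset.records:
        if record.smiles not in drug_cache:
            graph = smiles_to_graph(record.smiles)
            drug_cache[record.smiles] = (
                graph.node_features, build_power_graph_set(graph).as_dict())
        if record.sequence not in protein_cache:
            if config.protein_encoder == "word2vec":
                protein_cache[record.sequence] = embed_sequence(
                    record.sequence, dictionary, config.protein_max_len).matrix
            else:
                protein_cache[record.sequence] = one_hot_protein(
                    record.sequence, config.protein_max_len)
        x, powers = drug_cache[record.smiles]
        samples.append(_FeaturizedSample(x, powers,
                                         protein_cache[record.sequence],
                                         record.affinity))
    return samples


@dataclass
class FoldResult:
    fold: int
    report: EvaluationReport
    epoch_losses: list[float]


@dataclass
class TrainingResult:
    fold_results: list[FoldResult]
    models: list[DTANetwork]

    @property
    def final_model(self) -> DTANetwork:
        return self.models[-1]

    @property
    def mean_mse(self) -> float:
        return float(np.mean([f.report.mse for f in self.fold_results]))

    @property
    def mean_ci(self) -> float:
        return float(np.mean([f.report.ci for f in self.fold_results]))


def _batch_loss(model: DTANetwork, samples: list[_FeaturizedSample],
                rng: np.random.Generator, training: bool = True) -> ad.Tensor:
    predictions = [model.forward(s.node_features, s.power_norms,
                                 s.protein_matrix, training=training,
                                 rng=rng if training else None)
                   for s in samples]
    stacked = ad.hstack(predictions)
    targets = np.array([[s.affinity for s in samples]])
    return ad.mean(ad.square(ad.sub(stacked, ad.Tensor(targets))))


def _predict_many(model: DTANetwork,
                  samples: list[_FeaturizedSample]) -> np.ndarray:
    return np.array([model.predict(s.node_features, s.power_norms,
                                   s.protein_matrix) for s in samples])


def train_model(dataset: AffinityDataset, config: TrainingConfig,
                split: CVSplit,
                dictionary: EmbeddingDictionary | None = None,
                ) -> tuple[DTANetwork, TrainingResult]:
    """Cross-validated MSE training; returns the last fold's model and
    per-fold validation reports.

    When no embedding dictionary is supplied in word2vec mode, one is
    trained on the dataset's own sequences (skip-gram, seeded).
    """
    if config.protein_encoder == "word2vec" and dictionary is None:
        corpus = sorted({r.sequence for r in dataset.records})
        dictionary = train_embedding_dictionary(
            corpus, d=config.embedding_dim, seed=config.seed)
    samples = featurize_dataset(dataset, config, dictionary)
    drug_feature_dim = samples[0].node_features.shape[1]
    model_config = config.model_config(drug_feature_dim)

    folds = (range(split.k) if config.folds_to_run is None
             else config.folds_to_run)
    fold_results: list[FoldResult] = []
    models: list[DTANetwork] = []
    for fold in folds:
        train_idx, val_idx = split.fold_indices(fold)
        model = DTANetwork(model_config, seed=config.seed + fold)
        model.metadata["fold_id"] = int(fold)
        optimizer = ad.Adam(model.params, lr=config.learning_rate)
        rng = np.random.default_rng((config.seed + 7919 * (fold + 1))
                                    % 2**31)
        epoch_losses: list[float] = []
        for epoch in range(config.epochs):
            order = rng.permutation(train_idx)
            batch_losses = []
            for start in range(0, len(order), config.batch_size):
                batch = [samples[i] for i in order[start:start
                                                   + config.batch_size]]
                optimizer.zero_grad()
                loss = _batch_loss(model, batch, rng)
                value = loss.item()
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"training diverged: non-finite loss {value} at "
                        f"fold {fold}, epoch {epoch}")
                ad.backward(loss)
                optimizer.step()
                batch_losses.append(value)
            epoch_losses.append(float(np.mean(batch_losses)))
            logger.debug("fold %d epoch %d loss %.5f", fold, epoch,
                         epoch_losses[-1])
        model.metadata["epochs_completed"] = config.epochs
        y_val = np.array([samples[i].affinity for i in val_idx])
        predictions = _predict_many(model, [samples[i] for i in val_idx])
        report = evaluate_predictions(y_val, predictions)
        fold_results.append(FoldResult(int(fold), report, epoch_losses))
        models.append(model)
        logger.info("fold %d: mse %.4f ci %.4f", fold, report.mse, report.ci)
    result = TrainingResult(fold_results, models)
    return result.final_model, result


#: The five ablation configurations: protein encoder swap, then each
#: single graph power, then the full model.
ABLATION_GRID: tuple[tuple[str, str, tuple[int, ...]], ...] = (
    ("one-hot + A,A2,A3", "one-hot", (1, 2, 3)),
    ("word2vec + A3", "word2vec", (3,)),
    ("word2vec + A2", "word2vec", (2,)),
    ("word2vec + A", "word2vec", (1,)),
    ("word2vec + A,A2,A3 (full)", "word2vec", (1, 2, 3)),
)


def run_ablation(dataset: AffinityDataset, base_config: TrainingConfig,
                 split: CVSplit | None = None,
                 dictionary: EmbeddingDictionary | None = None,
                 ) -> pd.DataFrame:
    """Train every ablation configuration and tabulate CI / MSE.

    The touched_powers column records, per configuration, which
    normalized adjacency exponents the drug encoder actually consumed —
    single-power runs must touch exactly their own.
    """
    if split is None:
        split = make_cv_splits(dataset, k=5, seed=base_config.seed)
    if dictionary is None:
        corpus = sorted({r.sequence for r in dataset.records})
        dictionary = train_embedding_dictionary(
            corpus, d=base_config.embedding_dim, seed=base_config.seed)
    rows = []
    for name, encoder, powers in ABLATION_GRID:
        config = replace(base_config, protein_encoder=encoder, powers=powers)
        model, result = train_model(
            dataset, config, split,
            dictionary=dictionary if encoder == "word2vec" else None)
        touched = frozenset().union(*(m.touched_powers for m in result.models))
        rows.append({"name": name, "protein_encoder": encoder,
                     "powers": powers, "mse": result.mean_mse,
                     "ci": result.mean_ci, "touched_powers": touched})
        logger.info("ablation %-28s mse %.4f ci %.4f", name,
                    result.mean_mse, result.mean_ci)
    return pd.DataFrame(rows)
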