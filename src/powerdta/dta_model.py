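"""The affinity network: power-graph drug encoder, protein CNN and fusion head.

The drug encoder runs three graph-convolution blocks in parallel on the
same raw node features, one block per graph power: three stacked layers
on the normalized A, two on A^2, one on A^3.  Each layer applies the
propagation rule H' = sigma(A_norm H W + b); each block's node
representations are reduced by global max pooling and the three pooled
vectors are concatenated.  Deeper stacks on higher powers are
unnecessary because a single layer on A^3 already mixes 3-hop
neighborhoods.

The protein encoder is a 3-layer 1-D CNN over the word-embedding matrix
(channels = embedding dimension) followed by global max pooling.  The
fusion head concatenates both vectors and applies three fully connected
layers — dropout after the first two, linear scalar output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

#: GCN stack depth per graph-power exponent (deeper on lower powers).
BLOCK_DEPTHS = {1: 3, 2: 2, 3: 1}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    gcn_block_dims maps each enabled power exponent to its per-layer
    output widths; lengths must match BLOCK_DEPTHS.  protein_channels is
    the input channel count (embedding dimension d, or 20 in one-hot
    mode); protein_rows the input row count (max_len - 2 for word
    embeddings, max_len for one-hot).
    """

    drug_feature_dim: int = 78
    powers: tuple[int, ...] = (1, 2, 3)
    gcn_block_dims: dict[int, tuple[int, ...]] = field(
        default_factory=lambda: {1: (78, 156, 312), 2: (156, 312), 3: (312,)})
    chained_blocks: bool = False
    protein_channels: int = 100
    protein_rows: int = 998
    protein_conv_filters: tuple[int, ...] = (32, 32, 32)
    protein_kernel_sizes: tuple[int, ...] = (8, 8, 8)
    fusion_dims: tuple[int, ...] = (1024, 512)
    dropout_rate: float = 0.2
    activation: str = "relu"

    def __post_init__(self):
        if not self.powers or any(k not in (1, 2, 3) for k in self.powers):
            raise ValueError("powers must be a non-empty subset of {1, 2, 3}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        for k in self.powers:
            if len(self.gcn_block_dims[k]) != BLOCK_DEPTHS[k]:
                raise ValueError(
                    f"block for power {k} needs {BLOCK_DEPTHS[k]} layer widths")
        if len(self.protein_conv_filters) != len(self.protein_kernel_sizes):
            raise ValueError("one kernel size per protein conv layer")
        if self.activation != "relu":
            raise ValueError("only the rectifier nonlinearity is supported")

    @property
    def drug_vector_dim(self) -> int:
        return sum(self.gcn_block_dims[k][-1] for k in self.powers)

    @property
    def protein_vector_dim(self) -> int:
        return self.protein_conv_filters[-1]

    def to_json(self) -> str:
        cfg = asdict(self)
        cfg["gcn_block_dims"] = {str(k): list(v)
                                 for k, v in cfg["gcn_block_dims"].items()}
        return json.dumps(cfg)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        cfg = json.loads(text)
        cfg["powers"] = tuple(cfg["powers"])
        cfg["gcn_block_dims"] = {int(k): tuple(v)
                                 for k, v in cfg["gcn_block_dims"].items()}
        cfg["protein_conv_filters"] = tuple(cfg["protein_conv_filters"])
        cfg["protein_kernel_sizes"] = tuple(cfg["protein_kernel_sizes"])
        cfg["fusion_dims"] = tuple(cfg["fusion_dims"])
        return cls(**cfg)


def gcn_layer(h: np.ndarray, a_norm: np.ndarray, weights: np.ndarray,
              bias: np.ndarray | None = None,
              activation: bool = True) -> np.ndarray:
    """One propagation step sigma(A_norm H W + b) on plain arrays."""
    h = np.asarray(h, dtype=float)
    a_norm = np.asarray(a_norm, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if a_norm.shape[0] != a_norm.shape[1] or a_norm.shape[1] != h.shape[0]:
        raise ValueError("a_norm and h are not conformable")
    if h.shape[1] != weights.shape[0]:
        raise ValueError("h and weights are not conformable")
    out = a_norm @ h @ weights
    if bias is not None:
        out = out + np.asarray(bias, dtype=float)
    return np.maximum(out, 0.0) if activation else out


class DTANetwork:
    """The full encoder-fusion network with its trainable parameter state.

    Forward evaluation with training=False is a deterministic function
    of (inputs, weights); training=True additionally needs a random
    generator for the fusion-head dropout masks.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.metadata: dict = {"seed": seed, "epochs_completed": 0,
                               "fold_id": None}
        self.touched_powers: set[int] = set()
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)

        def init(name: str, fan_in: int, shape: tuple[int, ...]) -> None:
            bound = 1.0 / np.sqrt(fan_in)
            self.params[name] = Tensor(
                rng.uniform(-bound, bound, size=shape), requires_grad=True)

        for k in config.powers:
            dim_in = config.drug_feature_dim
            for layer, dim_out in enumerate(config.gcn_block_dims[k]):
                init(f"gcn{k}_w{layer}", dim_in, (dim_in, dim_out))
                init(f"gcn{k}_b{layer}", dim_in, (dim_out,))
                dim_in = dim_out

        ch = config.protein_channels
        for layer, (filters, kernel) in enumerate(
                zip(config.protein_conv_filters, config.protein_kernel_sizes)):
            init(f"conv_w{layer}", kernel * ch, (kernel * ch, filters))
            init(f"conv_b{layer}", kernel * ch, (filters,))
            ch = filters

        dim_in = config.drug_vector_dim + config.protein_vector_dim
        for layer, dim_out in enumerate(config.fusion_dims):
            init(f"fc_w{layer}", dim_in, (dim_in, dim_out))
            init(f"fc_b{layer}", dim_in, (dim_out,))
            dim_in = dim_out
        init("fc_w_out", dim_in, (dim_in, 1))
        init("fc_b_out", dim_in, (1,))

    # -- encoders ----------------------------------------------------------

    def _gcn_block(self, k: int, h: Tensor, a_norm: Tensor) -> Tensor:
        for layer in range(BLOCK_DEPTHS[k]):
            pre = ad.add(
                ad.matmul(ad.matmul(a_norm, h), self.params[f"gcn{k}_w{layer}"]),
                self.params[f"gcn{k}_b{layer}"])
            h = ad.relu(pre)
        return h

    def encode_drug(self, node_features: np.ndarray,
                    power_norms: dict[int, np.ndarray]) -> Tensor:
        """Concatenated max-pooled block outputs, one block per enabled
        power.  Blocks read the raw node features in parallel unless
        chained_blocks is set (then each consumes its predecessor)."""
        x = Tensor(np.asarray(node_features, dtype=float))
        pooled = []
        h = x
        for k in sorted(self.config.powers):
            self.touched_powers.add(k)
            a_norm = Tensor(np.asarray(power_norms[k], dtype=float))
            out = self._gcn_block(k, h if self.config.chained_blocks else x,
                                  a_norm)
            if self.config.chained_blocks:
                h = out
            pooled.append(ad.amax_rows(out))
        return pooled[0] if len(pooled) == 1 else ad.hstack(pooled)

    def encode_protein(self, embedding_matrix: np.ndarray) -> Tensor:
        matrix = np.asarray(embedding_matrix, dtype=float)
        if matrix.shape != (self.config.protein_rows,
                            self.config.protein_channels):
            raise ValueError(
                f"protein input shape {matrix.shape} does not match config "
                f"({self.config.protein_rows}, {self.config.protein_channels})")
        h = Tensor(matrix)
        for layer, kernel in enumerate(self.config.protein_kernel_sizes):
            length = h.data.shape[0]
            if length < kernel:
                raise ValueError("protein input shorter than kernel")
            index = (np.arange(length - kernel + 1)[:, None]
                     + np.arange(kernel)[None, :])
            patches = ad.gather_rows(h, index)
            h = ad.relu(ad.add(ad.matmul(patches, self.params[f"conv_w{layer}"]),
                               self.params[f"conv_b{layer}"]))
        return ad.amax_rows(h)

    # -- fusion head -------------------------------------------------------

    def predict_affinity(self, drug_vec: Tensor, protein_vec: Tensor, *,
                         training: bool,
                         rng: np.random.Generator | None = None) -> Tensor:
        """Concatenate, apply three fully connected layers (dropout after
        the first two in training mode), return the scalar prediction."""
        if training and rng is None:
            raise ValueError("training mode requires a random generator "
                             "for the dropout masks")
        if not training and rng is not None:
            raise ValueError("dropout is disabled in evaluation mode; "
                             "do not pass a generator")
        h = ad.hstack([drug_vec, protein_vec])
        p = self.config.dropout_rate
        for layer in range(len(self.config.fusion_dims)):
            h = ad.relu(ad.add(ad.matmul(h, self.params[f"fc_w{layer}"]),
                               self.params[f"fc_b{layer}"]))
            if training and p > 0:
                mask = (rng.random(h.data.shape) >= p) / (1.0 - p)
                h = ad.mul(h, Tensor(mask))
        return ad.add(ad.matmul(h, self.params["fc_w_out"]),
                      self.params["fc_b_out"])

    def forward(self, node_features: np.ndarray,
                power_norms: dict[int, np.ndarray],
                protein_matrix: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        drug_vec = self.encode_drug(node_features, power_norms)
        protein_vec = self.encode_protein(protein_matrix)
        return self.predict_affinity(drug_vec, protein_vec,
                                     training=training, rng=rng)

    def predict(self, node_features: np.ndarray,
                power_norms: dict[int, np.ndarray],
                protein_matrix: np.ndarray) -> float:
        """Deterministic evaluation-mode prediction."""
        return self.forward(node_features, power_norms, protein_matrix,
                            training=False).item()

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {name: p.data for name, p in self.params.items()}
        np.savez(path, __config__=np.array(self.config.to_json()),
                 __metadata__=np.array(json.dumps(self.metadata)), **arrays)

    @classmethod
    def load(cls, path) -> "DTANetwork":
        archive = np.load(path, allow_pickle=False)
        config = ModelConfig.from_json(str(archive["__config__"]))
        model = cls(config, seed=0)
        model.metadata = json.loads(str(archive["__metadata__"]))
        for name in model.params:
            model.params[name].data = archive[name]
        return model


#: Alias: a fitted network is its config plus parameter state plus metadata.
TrainedModel = DTANetwork
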