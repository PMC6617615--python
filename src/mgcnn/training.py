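"""Training the MGCNN: Adam optimization under the two-site dropout scheme.

Dropout is applied at drop probability 0.8 on the one-hot input layer and
0.2 after each pooling layer; training runs a fixed number of epochs
(default 300) with the Adam optimizer. Both rates, the epoch count and the
optimizer constants are configurable. Every source of randomness (weight
init, dropout masks, batch shuffling) derives from one integer seed, so a
run is exactly reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from ._batch import PackedGraphs, batch_forward, batch_loss, batch_loss_and_gradients
from .gcnn_core import (
    DEFAULT_LOSS_EPSILON,
    ClassifierHead,
    ConvStageWeights,
    MGCNNModel,
    ModelArchitecture,
    init_model,
)
from .molgraph import (
    AtomAlphabet,
    AtomFeatureMatrix,
    LabelMatrix,
    MolecularGraph,
    UnknownAtomError,
    infer_alphabet,
)

__all__ = [
    "TrainingConfig",
    "ModelCheckpoint",
    "train",
    "apply_dropout",
    "predict",
    "loss_and_gradients",
]

CHECKPOINT_FORMAT_VERSION = 1
DEFAULT_BATCH_SIZE = 32


@dataclass
class TrainingConfig:
    """Hyperparameters of one training run.

    Defaults: three 128-wide stages, 300 epochs of Adam (1e-3, β1=0.9,
    β2=0.999, ε=1e-8) on minibatches of 32, dropout 0.2 after each pooling
    layer and none on the input one-hots. Input dropout (``dropout_input``)
    deletes the identity of individual atoms, which for sparse signals such
    as the presence of a single heteroatom acts as label noise and can
    collapse training to the majority class; it is off by default but kept
    configurable for sensitivity studies.
    """

    n_stages: int = 3
    stage_dims: list[int] = field(default_factory=lambda: [128, 128, 128])
    epochs: int = 300
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    batch_size: int | None = None
    dropout_input: float = 0.0
    dropout_after_pool: float = 0.2
    use_bias: bool = True
    seed: int = 0
    loss_epsilon: float = DEFAULT_LOSS_EPSILON
    threshold: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.dropout_input < 1.0 and 0.0 <= self.dropout_after_pool < 1.0):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if len(self.stage_dims) != self.n_stages:
            raise ValueError("stage_dims length must equal n_stages")


@dataclass
class ModelCheckpoint:
    """Serializable bundle of a trained model and the config that produced it."""

    model: MGCNNModel
    config: TrainingConfig

    def save(self, path) -> None:
        arch = self.model.architecture
        payload = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "alphabet": list(arch.alphabet.symbols),
            "categories": list(arch.categories),
            "n_stages": arch.n_stages,
            "stage_dims": list(arch.stage_dims),
            "use_bias": arch.use_bias,
            "stages": [
                {
                    "w_self": st.w_self.tolist(),
                    "w_neighbor": st.w_neighbor.tolist(),
                    "bias": None if st.bias is None else st.bias.tolist(),
                }
                for st in self.model.stages
            ],
            "head": {
                "weight": self.model.head.weight.tolist(),
                "bias": None if self.model.head.bias is None else self.model.head.bias.tolist(),
            },
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModelCheckpoint":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {payload.get('format_version')!r}")
        arch = ModelArchitecture(
            alphabet=AtomAlphabet(tuple(payload["alphabet"])),
            categories=list(payload["categories"]),
            n_stages=payload["n_stages"],
            stage_dims=list(payload["stage_dims"]),
            use_bias=payload["use_bias"],
        )
        stages = [
            ConvStageWeights(
                w_self=np.array(st["w_self"]),
                w_neighbor=np.array(st["w_neighbor"]),
                bias=None if st["bias"] is None else np.array(st["bias"]),
            )
            for st in payload["stages"]
        ]
        head = ClassifierHead(
            weight=np.array(payload["head"]["weight"]),
            bias=None if payload["head"]["bias"] is None else np.array(payload["head"]["bias"]),
        )
        return cls(MGCNNModel(arch, stages, head), TrainingConfig(**payload["config"]))


def apply_dropout(
    f: AtomFeatureMatrix,
    rate: float,
    rng: np.random.Generator | None = None,
    training: bool = True,
) -> AtomFeatureMatrix:
    """Inverted dropout on a feature matrix.

    In training mode each entry is zeroed independently with probability
    ``rate`` and survivors are scaled by 1/(1−rate), so the expectation is
    preserved and inference needs no rescaling. In inference mode (or at
    rate 0) the input is returned unchanged.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
    if not training or rate == 0.0:
        return f
    if rng is None:
        raise ValueError("training-mode dropout requires an rng")
    mask = (rng.random(f.values.shape) >= rate) / (1.0 - rate)
    return AtomFeatureMatrix(f.values * mask, layer_index=f.layer_index)


class _Adam:
    """Plain Adam with bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], cfg: TrainingConfig):
        self.lr = cfg.learning_rate
        self.b1, self.b2, self.eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_epsilon
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _align_labels(
    graphs: list[MolecularGraph], labels: LabelMatrix
) -> np.ndarray:
    index = {cid: i for i, cid in enumerate(labels.compound_ids)}
    rows = []
    for g in graphs:
        if g.compound_id not in index:
            raise KeyError(f"no label row for compound {g.compound_id!r}")
        rows.append(labels.membership[index[g.compound_id]])
    return np.array(rows, dtype=np.int8)


def train(
    graphs: list[MolecularGraph],
    labels: LabelMatrix,
    cfg: TrainingConfig,
    alphabet: AtomAlphabet | None = None,
) -> tuple[ModelCheckpoint, list[float]]:
    """Fit an MGCNN on labeled molecules; returns (checkpoint, loss curve).

    The loss curve records, per epoch, the mean per-molecule summed cross
    entropy over the whole training set evaluated in inference mode (no
    dropout), so it is flat when the learning rate is zero and is exactly
    reproducible for a fixed (seed, data, config) triple.
    """
    if not graphs:
        raise ValueError("empty training set")
    y = _align_labels(graphs, labels)
    if alphabet is None:
        alphabet = infer_alphabet(graphs)
    arch = ModelArchitecture(
        alphabet=alphabet,
        categories=list(labels.categories),
        n_stages=cfg.n_stages,
        stage_dims=list(cfg.stage_dims),
        use_bias=cfg.use_bias,
    )
    rng = np.random.default_rng(cfg.seed)
    model = init_model(arch, rng)
    packed_all = PackedGraphs(graphs, alphabet)

    n = len(graphs)
    batch_size = cfg.batch_size if cfg.batch_size is not None else DEFAULT_BATCH_SIZE
    full_batch = batch_size >= n

    params = model.parameters()
    opt = _Adam(params, cfg)
    loss_curve: list[float] = []
    order = np.arange(n)
    for _ in range(cfg.epochs):
        if full_batch:
            batches = [(packed_all, y)]
        else:
            rng.shuffle(order)
            batches = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                batches.append((PackedGraphs([graphs[i] for i in idx], alphabet), y[idx]))
        for packed, yb in batches:
            if cfg.learning_rate > 0.0:
                _, grads = batch_loss_and_gradients(
                    model, packed, yb, cfg.loss_epsilon, rng,
                    cfg.dropout_input, cfg.dropout_after_pool,
                )
                opt.step(params, grads)
            else:
                # keep the rng stream aligned so lr=0 runs stay comparable
                batch_loss_and_gradients(
                    model, packed, yb, cfg.loss_epsilon, rng,
                    cfg.dropout_input, cfg.dropout_after_pool,
                )
        eval_tape = batch_forward(model, packed_all)
        loss_curve.append(float(batch_loss(eval_tape["probs"], y, cfg.loss_epsilon).mean()))
    return ModelCheckpoint(model, cfg), loss_curve


def loss_and_gradients(
    model: MGCNNModel,
    graphs: list[MolecularGraph],
    label_rows: np.ndarray,
    epsilon: float = DEFAULT_LOSS_EPSILON,
) -> tuple[float, list[np.ndarray]]:
    """Inference-mode (no dropout) mean loss and analytic parameter gradients."""
    packed = PackedGraphs(graphs, model.architecture.alphabet)
    return batch_loss_and_gradients(model, packed, np.asarray(label_rows), epsilon)


def predict(
    checkpoint: ModelCheckpoint | MGCNNModel,
    graphs: list[MolecularGraph],
    threshold: float | None = None,
) -> tuple[LabelMatrix, "pd.DataFrame"]:
    """Predict category membership for molecules.

    Returns the thresholded binary calls as a :class:`LabelMatrix` and a
    DataFrame of raw positive-class probabilities. Molecules containing an
    atom outside the model's frozen alphabet are skipped with a warning and
    omitted from both outputs.
    """
    import pandas as pd

    if isinstance(checkpoint, ModelCheckpoint):
        model = checkpoint.model
        if threshold is None:
            threshold = checkpoint.config.threshold
    else:
        model = checkpoint
        if threshold is None:
            threshold = 0.5
    arch = model.architecture
    usable: list[MolecularGraph] = []
    for g in graphs:
        missing = {s for s in g.atoms if s not in arch.alphabet}
        if missing:
            warnings.warn(
                f"skipping compound {g.compound_id!r}: atom(s) {sorted(missing)} "
                "not in the model alphabet",
                stacklevel=2,
            )
            continue
        usable.append(g)
    if not usable:
        empty = LabelMatrix([], list(arch.categories), np.zeros((0, len(arch.categories))))
        return empty, pd.DataFrame(columns=arch.categories)
    packed = PackedGraphs(usable, arch.alphabet)
    probs = batch_forward(model, packed)["probs"][:, :, 0]
    calls = (probs > threshold).astype(np.int8)
    ids = [g.compound_id for g in usable]
    return (
        LabelMatrix(ids, list(arch.categories), calls),
        pd.DataFrame(probs, index=pd.Index(ids, name="compound_id"), columns=arch.categories),
    )
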