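"""Forward computation of the molecular graph convolutional network (MGCNN).

The model stacks ``n_stages`` pairs of (graph convolution, neighborhood
max-pooling) on the atom-bond graph, sums all atom vectors into one molecule
vector (the gather readout), and classifies with K independent paired-softmax
heads — one (positive, negative) logit pair per starting-substance category,
so a compound may belong to several categories or to none.

The convolution is distance-indexed: the update of atom i is

    v_i' = ReLU( W_self v_i  +  W_neighbor * sum_{j bonded to i} v_j  [+ b] )

i.e. the weight applied to a contributing vertex depends only on its graph
distance from i inside the neighborhood Adj(i) ∪ {i}: distance 0 (the atom
itself) or distance 1 (a bonded neighbor). Max-pooling uses the same
neighborhood convention, taking the elementwise maximum over
{v_j : j in Adj(i) ∪ {i}}.

Everything here is inference-mode and deterministic; dropout lives in the
training module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molgraph import (
    AtomAlphabet,
    AtomFeatureMatrix,
    MolecularGraph,
    one_hot_encode,
)

__all__ = [
    "ConvStageWeights",
    "ClassifierHead",
    "ModelArchitecture",
    "MGCNNModel",
    "PredictionVector",
    "DimensionError",
    "convolve",
    "max_pool",
    "gather",
    "classify",
    "cross_entropy_loss",
    "forward",
    "init_model",
]

DEFAULT_LOSS_EPSILON = 1e-10


class DimensionError(ValueError):
    """Shape mismatch between features, graph, or weights."""


@dataclass
class ConvStageWeights:
    """Weights of one convolution stage, indexed by vertex distance.

    ``w_self`` acts on the vertex itself (distance 0), ``w_neighbor`` on each
    bonded vertex (distance 1); both map in_dim -> out_dim. ``bias`` is
    optional — the strict form of the update rule has none.
    """

    w_self: np.ndarray
    w_neighbor: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.w_self = np.asarray(self.w_self, dtype=np.float64)
        self.w_neighbor = np.asarray(self.w_neighbor, dtype=np.float64)
        if self.w_self.shape != self.w_neighbor.shape:
            raise DimensionError(
                f"w_self {self.w_self.shape} and w_neighbor {self.w_neighbor.shape} differ"
            )
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=np.float64)
            if self.bias.shape != (self.w_self.shape[0],):
                raise DimensionError("bias length does not match output width")
        for a in (self.w_self, self.w_neighbor):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite convolution weights")

    @property
    def in_dim(self) -> int:
        return self.w_self.shape[1]

    @property
    def out_dim(self) -> int:
        return self.w_self.shape[0]


@dataclass
class ClassifierHead:
    """K paired-softmax heads: molecule vector -> 2K logits, (P_k, N_k) per category."""

    weight: np.ndarray  # (2K, in_dim)
    bias: np.ndarray | None = None  # (2K,)

    def __post_init__(self):
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if self.weight.ndim != 2 or self.weight.shape[0] % 2 != 0:
            raise DimensionError("head weight must be (2K, in_dim)")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=np.float64)
            if self.bias.shape != (self.weight.shape[0],):
                raise DimensionError("head bias length must be 2K")

    @property
    def n_categories(self) -> int:
        return self.weight.shape[0] // 2

    @property
    def in_dim(self) -> int:
        return self.weight.shape[1]


@dataclass
class ModelArchitecture:
    """Static shape of an MGCNN: stage widths, alphabet, category names."""

    alphabet: AtomAlphabet
    categories: list[str]
    n_stages: int = 3
    stage_dims: list[int] = field(default_factory=lambda: [128, 128, 128])
    use_bias: bool = True

    def __post_init__(self):
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if len(self.stage_dims) != self.n_stages:
            raise ValueError("stage_dims length must equal n_stages")
        if len(self.categories) < 1:
            raise ValueError("at least one category required")

    @property
    def final_dim(self) -> int:
        return self.stage_dims[-1]


@dataclass
class MGCNNModel:
    """Architecture plus all learnable weights."""

    architecture: ModelArchitecture
    stages: list[ConvStageWeights]
    head: ClassifierHead

    def __post_init__(self):
        arch = self.architecture
        if len(self.stages) != arch.n_stages:
            raise DimensionError("stage count mismatch")
        in_dim = len(arch.alphabet)
        for s, (stage, out_dim) in enumerate(zip(self.stages, arch.stage_dims)):
            if stage.in_dim != in_dim or stage.out_dim != out_dim:
                raise DimensionError(
                    f"stage {s}: expected {in_dim}->{out_dim}, got {stage.in_dim}->{stage.out_dim}"
                )
            in_dim = out_dim
        if self.head.in_dim != arch.final_dim:
            raise DimensionError("head input width must equal the final stage width")
        if self.head.n_categories != len(arch.categories):
            raise DimensionError("head category count mismatch")

    def parameters(self) -> list[np.ndarray]:
        """Flat list of all weight arrays, in a fixed traversal order."""
        params: list[np.ndarray] = []
        for st in self.stages:
            params.append(st.w_self)
            params.append(st.w_neighbor)
            if st.bias is not None:
                params.append(st.bias)
        params.append(self.head.weight)
        if self.head.bias is not None:
            params.append(self.head.bias)
        return params


@dataclass
class PredictionVector:
    """Per-category probability pairs (y_kp, y_kn); each pair sums to 1."""

    categories: list[str]
    probabilities: np.ndarray  # (K, 2) columns: positive, negative

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.shape != (len(self.categories), 2):
            raise DimensionError("probabilities must be (K, 2)")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each (positive, negative) pair must sum to 1")

    @property
    def positive(self) -> np.ndarray:
        return self.probabilities[:, 0]

    def calls(self, threshold: float = 0.5) -> np.ndarray:
        """Binary category calls: positive iff y_kp strictly exceeds the threshold."""
        return (self.positive > threshold).astype(np.int8)


def convolve(
    f: AtomFeatureMatrix, g: MolecularGraph, w: ConvStageWeights
) -> AtomFeatureMatrix:
    """One distance-indexed graph convolution followed by ReLU.

    Row i of the output is ReLU(w_self·f_i + Σ_{j~i} w_neighbor·f_j + bias);
    the sum runs over atoms bonded to i. Vectorized over atoms via the
    adjacency matrix.
    """
    if f.n_atoms != g.n_atoms:
        raise DimensionError(
            f"feature rows ({f.n_atoms}) != atoms of {g.compound_id!r} ({g.n_atoms})"
        )
    if w.in_dim != f.width:
        raise DimensionError(
            f"stage expects input width {w.in_dim}, features have {f.width}"
        )
    a = g.adjacency()
    z = f.values @ w.w_self.T + (a @ f.values) @ w.w_neighbor.T
    if w.bias is not None:
        z = z + w.bias
    return AtomFeatureMatrix(np.maximum(z, 0.0), layer_index=f.layer_index + 1)


def max_pool(f: AtomFeatureMatrix, g: MolecularGraph) -> AtomFeatureMatrix:
    """Neighborhood max-pooling: out[i] = elementwise max over Adj(i) ∪ {i}."""
    if f.n_atoms != g.n_atoms:
        raise DimensionError(
            f"feature rows ({f.n_atoms}) != atoms of {g.compound_id!r} ({g.n_atoms})"
        )
    mask = g.adjacency().astype(bool)
    np.fill_diagonal(mask, True)
    expanded = np.where(mask[:, :, None], f.values[None, :, :], -np.inf)
    return AtomFeatureMatrix(expanded.max(axis=1), layer_index=f.layer_index)


def gather(f: AtomFeatureMatrix) -> np.ndarray:
    """Sum-gather readout: the molecule vector is the column sum over atoms."""
    if f.n_atoms == 0:
        raise ValueError("cannot gather a zero-atom feature matrix")
    return f.values.sum(axis=0)


def _paired_softmax(logits: np.ndarray) -> np.ndarray:
    """Softmax over the last axis of (..., K, 2) logit pairs, numerically stable."""
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def classify(mol_vec: np.ndarray, head: ClassifierHead, categories: list[str]) -> PredictionVector:
    """Apply the K independent paired-softmax heads to a molecule vector."""
    mol_vec = np.asarray(mol_vec, dtype=np.float64)
    if mol_vec.shape != (head.in_dim,):
        raise DimensionError(
            f"molecule vector width {mol_vec.shape} does not match head input {head.in_dim}"
        )
    if len(categories) != head.n_categories:
        raise DimensionError("category name count does not match head")
    logits = head.weight @ mol_vec
    if head.bias is not None:
        logits = logits + head.bias
    probs = _paired_softmax(logits.reshape(-1, 2))
    return PredictionVector(list(categories), probs)


def cross_entropy_loss(
    pred: PredictionVector,
    label_row: np.ndarray,
    epsilon: float = DEFAULT_LOSS_EPSILON,
) -> float:
    """Summed per-category cross entropy against a binary membership row.

    The membership bit for category k expands to the one-hot pair
    (ŷ_kp, ŷ_kn) = (m_k, 1 − m_k) and the loss is
    −Σ_k [ŷ_kp log y_kp + ŷ_kn log y_kn], with log arguments clamped below
    by ``epsilon`` so a saturated softmax stays finite.
    """
    label_row = np.asarray(label_row)
    if label_row.shape != (len(pred.categories),):
        raise DimensionError(
            f"label row has {label_row.shape} entries, prediction has {len(pred.categories)} categories"
        )
    y_hat = np.stack([label_row, 1 - label_row], axis=1).astype(np.float64)
    logp = np.log(np.maximum(pred.probabilities, epsilon))
    return float(-(y_hat * logp).sum())


def forward(g: MolecularGraph, model: MGCNNModel) -> PredictionVector:
    """Full deterministic inference pass on one molecule.

    one-hot encode -> [convolve -> max_pool] x n_stages -> gather -> classify.
    """
    f = one_hot_encode(g, model.architecture.alphabet)
    for stage in model.stages:
        f = max_pool(convolve(f, g, stage), g)
    return classify(gather(f), model.head, model.architecture.categories)


def init_model(arch: ModelArchitecture, seed: int | np.random.Generator = 0) -> MGCNNModel:
    """He-scaled random-normal weights (suits ReLU stages), zero biases, seeded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stages = []
    in_dim = len(arch.alphabet)
    for out_dim in arch.stage_dims:
        scale = np.sqrt(2.0 / in_dim)
        stages.append(
            ConvStageWeights(
                w_self=rng.normal(0.0, scale, size=(out_dim, in_dim)),
                w_neighbor=rng.normal(0.0, scale, size=(out_dim, in_dim)),
                bias=np.zeros(out_dim) if arch.use_bias else None,
            )
        )
        in_dim = out_dim
    k = len(arch.categories)
    head = ClassifierHead(
        weight=rng.normal(0.0, np.sqrt(1.0 / arch.final_dim), size=(2 * k, arch.final_dim)),
        bias=np.zeros(2 * k) if arch.use_bias else None,
    )
    return MGCNNModel(arch, stages, head)
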