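"""Packed mini-batch computation for training: many molecules, one set of arrays.

Molecules of different sizes are concatenated atom-wise into a single feature
matrix with a block-diagonal sparse adjacency, so one sparse matmul performs
the neighbor sum for the whole batch and one ``reduceat`` performs each
per-neighborhood max or per-molecule gather. The backward pass is derived by
hand (no autograd framework is used anywhere in the package):

* softmax + summed cross entropy: d logits = probs − one-hot targets;
* gather: the molecule-level gradient broadcasts to every atom row;
* max-pool: the gradient of each pooled entry is routed to the neighborhood
  entries attaining the maximum, split equally among exact ties (a valid,
  order-independent subgradient);
* ReLU: mask on the pre-activation sign;
* convolution: with Z = H W_s^T + (A H) W_n^T + b and symmetric A,
  dW_s = dZ^T H, dW_n = dZ^T (A H), db = Σ dZ, dH = dZ W_s + A (dZ W_n).

Dropout masks (inverted dropout, pre-scaled by 1/(1−rate)) are recorded in
the forward pass and reapplied in the backward pass.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .gcnn_core import MGCNNModel, _paired_softmax
from .molgraph import AtomAlphabet, MolecularGraph, UnknownAtomError

__all__ = ["PackedGraphs", "batch_forward", "batch_loss_and_gradients"]


class PackedGraphs:
    """A batch of molecular graphs packed into flat arrays.

    Atoms are numbered consecutively molecule by molecule. ``adjacency`` is
    the block-diagonal neighbor-only matrix; the pooling index arrays cover
    the closed neighborhood (neighbors plus a self-loop per atom) sorted once
    by source and once by destination for fast segment reductions.
    """

    def __init__(self, graphs: list[MolecularGraph], alphabet: AtomAlphabet):
        self.n_mols = len(graphs)
        if self.n_mols == 0:
            raise ValueError("cannot pack an empty list of graphs")
        counts = np.array([g.n_atoms for g in graphs], dtype=np.int64)
        self.atom_offsets = np.concatenate([[0], np.cumsum(counts)])
        n = int(self.atom_offsets[-1])
        self.n_atoms = n
        self.mol_of_atom = np.repeat(np.arange(self.n_mols), counts)

        sym_index = {s: i for i, s in enumerate(alphabet.symbols)}
        x0 = np.zeros((n, len(alphabet)), dtype=np.float64)
        src_parts, dst_parts = [], []
        for g, off in zip(graphs, self.atom_offsets[:-1]):
            for i, s in enumerate(g.atoms):
                if s not in sym_index:
                    raise UnknownAtomError(s, g.compound_id)
                x0[off + i, sym_index[s]] = 1.0
            for i, j in g.edge_list():
                src_parts.extend((off + i, off + j))
                dst_parts.extend((off + j, off + i))
        src = np.array(src_parts, dtype=np.int64)
        dst = np.array(dst_parts, dtype=np.int64)
        self.features0 = x0
        self.adjacency = sp.csr_matrix(
            (np.ones(len(src)), (src, dst)), shape=(n, n)
        )

        loops = np.arange(n, dtype=np.int64)
        pool_src = np.concatenate([src, loops])
        pool_dst = np.concatenate([dst, loops])
        by_src = np.argsort(pool_src, kind="stable")
        self.pool_dst_by_src = pool_dst[by_src]
        self.pool_src_sorted = pool_src[by_src]
        self.src_starts = np.concatenate(
            [[0], np.cumsum(np.bincount(pool_src, minlength=n))]
        )[:-1]
        # permutation regrouping the src-sorted edge arrays by destination
        self._by_dst_of_by_src: np.ndarray = np.argsort(self.pool_dst_by_src, kind="stable")
        self.dst_starts = np.concatenate(
            [[0], np.cumsum(np.bincount(pool_dst, minlength=n))]
        )[:-1]

    # -- segment primitives -------------------------------------------------

    def pool_max(self, h: np.ndarray) -> np.ndarray:
        """Per-atom closed-neighborhood elementwise maximum."""
        return np.maximum.reduceat(h[self.pool_dst_by_src], self.src_starts, axis=0)

    def pool_max_backward(
        self, h: np.ndarray, pooled: np.ndarray, grad_pooled: np.ndarray
    ) -> np.ndarray:
        """Route gradients to the argmax entries, splitting ties equally."""
        s = self.pool_src_sorted
        d = self.pool_dst_by_src
        winners = (h[d] == pooled[s]).astype(np.float64)
        tie_counts = np.add.reduceat(winners, self.src_starts, axis=0)
        contrib = winners * (grad_pooled[s] / tie_counts[s])
        return np.add.reduceat(contrib[self._by_dst_of_by_src], self.dst_starts, axis=0)

    def gather(self, h: np.ndarray) -> np.ndarray:
        """Per-molecule column sums (the readout), shape (n_mols, width)."""
        return np.add.reduceat(h, self.atom_offsets[:-1], axis=0)


def _head_logits(model: MGCNNModel, g_vecs: np.ndarray) -> np.ndarray:
    logits = g_vecs @ model.head.weight.T
    if model.head.bias is not None:
        logits = logits + model.head.bias
    return logits


def batch_forward(
    model: MGCNNModel,
    packed: PackedGraphs,
    rng: np.random.Generator | None = None,
    dropout_input: float = 0.0,
    dropout_after_pool: float = 0.0,
) -> dict:
    """Run the packed forward pass, returning probabilities and a tape.

    With ``rng`` set, inverted-dropout masks are drawn (training mode);
    without it the pass is deterministic inference. The returned dict holds
    every intermediate needed by :func:`batch_loss_and_gradients`.
    """
    train = rng is not None

    def mask_like(a: np.ndarray, rate: float) -> np.ndarray | None:
        if not train or rate <= 0.0:
            return None
        return (rng.random(a.shape) >= rate).astype(np.float64) / (1.0 - rate)

    h = packed.features0
    m0 = mask_like(h, dropout_input)
    if m0 is not None:
        h = h * m0
    tape = {"input_mask": m0, "stages": []}
    for stage in model.stages:
        h_in = h
        s_in = packed.adjacency @ h_in
        z = h_in @ stage.w_self.T + s_in @ stage.w_neighbor.T
        if stage.bias is not None:
            z = z + stage.bias
        relu = np.maximum(z, 0.0)
        pooled = packed.pool_max(relu)
        mk = mask_like(pooled, dropout_after_pool)
        h = pooled if mk is None else pooled * mk
        tape["stages"].append(
            {"h_in": h_in, "s_in": s_in, "z": z, "relu": relu, "pooled": pooled, "mask": mk}
        )
    g_vecs = packed.gather(h)
    logits = _head_logits(model, g_vecs).reshape(packed.n_mols, -1, 2)
    tape["g_vecs"] = g_vecs
    tape["probs"] = _paired_softmax(logits)
    return tape


def batch_loss(probs: np.ndarray, labels: np.ndarray, epsilon: float) -> np.ndarray:
    """Per-molecule summed cross entropy; ``labels`` is (n_mols, K) binary."""
    y_hat = np.stack([labels, 1 - labels], axis=2).astype(np.float64)
    logp = np.log(np.maximum(probs, epsilon))
    return -(y_hat * logp).sum(axis=(1, 2))


def batch_loss_and_gradients(
    model: MGCNNModel,
    packed: PackedGraphs,
    labels: np.ndarray,
    epsilon: float,
    rng: np.random.Generator | None = None,
    dropout_input: float = 0.0,
    dropout_after_pool: float = 0.0,
) -> tuple[float, list[np.ndarray]]:
    """Mean per-molecule loss and its gradient w.r.t. ``model.parameters()``.

    The loss is the mean over molecules of the per-molecule summed cross
    entropy, so the value (and gradient scale) is batching-invariant.
    """
    tape = batch_forward(model, packed, rng, dropout_input, dropout_after_pool)
    probs = tape["probs"]
    loss = float(batch_loss(probs, labels, epsilon).mean())

    n_mols = packed.n_mols
    y_hat = np.stack([labels, 1 - labels], axis=2).astype(np.float64)
    d_logits = ((probs - y_hat) / n_mols).reshape(n_mols, -1)

    grads: list[np.ndarray] = []
    g_vecs = tape["g_vecs"]
    d_head_w = d_logits.T @ g_vecs
    d_head_b = d_logits.sum(axis=0) if model.head.bias is not None else None
    d_g = d_logits @ model.head.weight
    d_h = d_g[packed.mol_of_atom]

    stage_grads: list[list[np.ndarray]] = []
    for stage, rec in zip(reversed(model.stages), reversed(tape["stages"])):
        if rec["mask"] is not None:
            d_h = d_h * rec["mask"]
        d_relu = packed.pool_max_backward(rec["relu"], rec["pooled"], d_h)
        d_z = d_relu * (rec["z"] > 0.0)
        g = [d_z.T @ rec["h_in"], d_z.T @ rec["s_in"]]
        if stage.bias is not None:
            g.append(d_z.sum(axis=0))
        stage_grads.append(g)
        d_h = d_z @ stage.w_self + packed.adjacency @ (d_z @ stage.w_neighbor)

    for g in reversed(stage_grads):
        grads.extend(g)
    grads.append(d_head_w)
    if d_head_b is not None:
        grads.append(d_head_b)
    return loss, grads
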