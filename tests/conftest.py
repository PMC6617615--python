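"""Shared fixtures: small graphs, independent oracles, heavy shared results.

The oracles here are deliberately naive re-implementations (explicit loops,
union-find) kept separate from the library's vectorized code paths so they
can serve as independent references.
"""

from __future__ import annotations

import numpy as np
import pytest

from mgcnn.evaluation import cross_validate, stage_sweep
from mgcnn.gcnn_core import ConvStageWeights, init_model, ModelArchitecture
from mgcnn.molgraph import AtomAlphabet, MolecularGraph
from mgcnn.synthetic import distance_rule_dataset, two_rule_dataset
from mgcnn.training import TrainingConfig


# ---------------------------------------------------------------- oracles


def convolve_oracle(f: np.ndarray, g: MolecularGraph, w: ConvStageWeights) -> np.ndarray:
    """Explicit per-atom double loop over (i, j in Adj(i) U {i})."""
    n, out_dim = f.shape[0], w.out_dim
    out = np.zeros((n, out_dim))
    for i in range(n):
        z = w.w_self @ f[i]
        for j in g.neighbors(i):
            z = z + w.w_neighbor @ f[j]
        if w.bias is not None:
            z = z + w.bias
        out[i] = np.maximum(z, 0.0)
    return out


def loss_oracle(probs: np.ndarray, label_row: np.ndarray, epsilon: float = 1e-10) -> float:
    """Scalar per-category accumulation of the summed cross entropy."""
    total = 0.0
    for k in range(len(label_row)):
        y_p, y_n = float(label_row[k]), 1.0 - float(label_row[k])
        total -= y_p * np.log(max(probs[k, 0], epsilon))
        total -= y_n * np.log(max(probs[k, 1], epsilon))
    return total


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def components(self) -> dict[int, list[int]]:
        comp: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            comp.setdefault(self.find(i), []).append(i)
        return comp


def random_graph(rng: np.random.Generator, n_atoms: int, symbols=("C", "H", "N", "O")) -> MolecularGraph:
    """Random connected graph: spanning tree plus a few extra edges."""
    atoms = [symbols[i] for i in rng.integers(0, len(symbols), size=n_atoms)]
    edges = {(int(rng.integers(0, i)), i) for i in range(1, n_atoms)}
    for _ in range(int(rng.integers(0, n_atoms // 2 + 1))):
        i, j = rng.integers(0, n_atoms, size=2)
        if i != j:
            edges.add((min(int(i), int(j)), max(int(i), int(j))))
    return MolecularGraph.from_edge_pairs(f"rand-{rng.integers(1e9)}", atoms, edges)


def permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Relabel atom indices by ``perm`` (new index of old atom i is perm[i])."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    atoms = [g.atoms[int(inv[k])] for k in range(g.n_atoms)]
    edges = [(int(perm[i]), int(perm[j])) for i, j in g.edge_list()]
    return MolecularGraph.from_edge_pairs(g.compound_id, atoms, edges)


@pytest.fixture
def oracles():
    return {
        "convolve": convolve_oracle,
        "loss": loss_oracle,
        "union_find": UnionFind,
        "random_graph": random_graph,
        "permute_graph": permute_graph,
    }


# ------------------------------------------------------- small structures


@pytest.fixture(scope="session")
def water():
    from mgcnn.molgraph import parse_smiles

    return parse_smiles("O water")


@pytest.fixture(scope="session")
def methane():
    from mgcnn.molgraph import parse_smiles

    return parse_smiles("C methane")


@pytest.fixture
def small_model():
    """A seeded untrained model over {C, H, N, O} with narrow stages."""
    arch = ModelArchitecture(
        alphabet=AtomAlphabet(("C", "H", "N", "O")),
        categories=["a", "b"],
        n_stages=2,
        stage_dims=[6, 6],
    )
    return init_model(arch, seed=11)


# ---------------------------------------------- shared expensive results
# Computed once per session; both the acceptance tests and consistency
# checks read them. Sizes follow the documented evaluation protocol.


@pytest.fixture(scope="session")
def two_rule_cv5_report():
    ds = two_rule_dataset(n=200, seed=42)
    cfg = TrainingConfig(seed=42)
    return cross_validate(ds.graphs, ds.labels, cfg, scheme="CV5")


@pytest.fixture(scope="session")
def distance_rule_sweep():
    ds = distance_rule_dataset(n=300, seed=42)
    cfg = TrainingConfig(seed=42)
    return stage_sweep(ds.graphs, ds.labels, cfg, [1, 3])
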