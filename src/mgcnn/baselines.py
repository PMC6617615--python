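"""Fingerprint/descriptor baselines and correlation-network feature selection.

The comparison methods treat each category as an independent binary
problem — mirroring the graph network's independent paired heads — on a
fixed feature matrix: a 1024-bit ECFP fingerprint (diameter 2) or any
externally computed descriptor table. Redundant descriptors are thinned by
the correlation-network procedure: drop zero-variance variables, connect
pairs with |r| above a threshold, and keep one randomly chosen
representative per connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .evaluation import CVReport, assign_folds
from .molgraph import LabelMatrix, MolecularGraph

__all__ = [
    "DescriptorMatrix",
    "SelectionResult",
    "ecfp",
    "read_descriptor_csv",
    "select_features",
    "run_baseline",
]

ECFP_BITS = 1024
ECFP_RADIUS = 1  # diameter 2


@dataclass
class DescriptorMatrix:
    """Numeric feature table: one row per compound, one column per variable."""

    compound_ids: list[str]
    variable_names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.compound_ids), len(self.variable_names)):
            raise ValueError("values shape does not match ids x variables")
        if len(set(self.variable_names)) != len(self.variable_names):
            raise ValueError("duplicate variable names")

    def subset(self, names: list[str]) -> "DescriptorMatrix":
        idx = [self.variable_names.index(n) for n in names]
        return DescriptorMatrix(self.compound_ids, list(names), self.values[:, idx])


@dataclass
class SelectionResult:
    """Outcome of correlation-network selection.

    One kept variable per connected component of the |r|-thresholded
    correlation graph; zero-variance variables are removed beforehand and
    never enter a component. Component ids are canonical (ordering-invariant):
    components are numbered by their lexicographically smallest member.
    """

    kept_variable_names: list[str]
    removed_noninformative: list[str]
    component_assignment: dict[str, int]
    seed: int


def _to_rdkit_mol(structure):
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    if isinstance(structure, Chem.Mol):
        return structure
    if isinstance(structure, str):
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ValueError(f"toolkit rejected structure {structure!r}")
        return mol
    if isinstance(structure, MolecularGraph):
        # rebuild with single bonds only; the graph carries no bond orders
        rw = Chem.RWMol()
        for sym in structure.atoms:
            rw.AddAtom(Chem.Atom(sym))
        for i, j in structure.edge_list():
            rw.AddBond(i, j, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - toolkit-specific failure
            raise ValueError(f"toolkit rejected graph {structure.compound_id!r}: {exc}")
        return mol
    raise TypeError(f"unsupported structure type {type(structure).__name__}")


def ecfp(structure, n_bits: int = ECFP_BITS, radius: int = ECFP_RADIUS) -> np.ndarray:
    """1024-bit extended-connectivity fingerprint of diameter 2 (radius 1)."""
    from rdkit.Chem import rdFingerprintGenerator

    mol = _to_rdkit_mol(structure)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.array(gen.GetFingerprint(mol), dtype=np.int8)


def read_descriptor_csv(path) -> DescriptorMatrix:
    """Read a descriptor table: ``compound_id`` column then numeric variables."""
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.columns[0] != "compound_id":
        raise ValueError(f"{path}: first column must be 'compound_id'")
    return DescriptorMatrix(
        df["compound_id"].astype(str).tolist(),
        list(df.columns[1:]),
        df.iloc[:, 1:].to_numpy(dtype=np.float64),
    )


def select_features(
    d: DescriptorMatrix,
    r_threshold: float = 0.6,
    seed: int = 0,
    use_absolute: bool = True,
) -> SelectionResult:
    """Thin a descriptor matrix to one variable per correlation component.

    Steps: (1) remove non-informative (zero-variance) variables; (2) Pearson
    correlation matrix of the remainder; (3) connect variable pairs with
    correlation strictly above ``r_threshold`` (|r| by default, signed r
    with ``use_absolute=False``); (4) find connected components; (5) keep
    one seeded-random representative per component.
    """
    n, p = d.values.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples to correlate, got {n}")
    if not (0.0 < r_threshold < 1.0):
        raise ValueError("r_threshold must lie in (0, 1)")
    std = d.values.std(axis=0)
    informative = std > 0.0
    removed = [v for v, keep in zip(d.variable_names, informative) if not keep]
    names = [v for v, keep in zip(d.variable_names, informative) if keep]
    if not names:
        raise ValueError("all variables are non-informative")
    x = d.values[:, informative]
    corr = np.corrcoef(x, rowvar=False)
    if corr.ndim == 0:  # single variable
        corr = corr.reshape(1, 1)
    strength = np.abs(corr) if use_absolute else corr
    adj = strength > r_threshold
    np.fill_diagonal(adj, False)
    n_comp, raw_labels = connected_components(sp.csr_matrix(adj), directed=False)

    # canonical component numbering: sort components by their smallest member name
    members: dict[int, list[str]] = {}
    for name, lab in zip(names, raw_labels):
        members.setdefault(int(lab), []).append(name)
    ordered = sorted(members.values(), key=lambda ms: min(ms))
    assignment = {name: cid for cid, ms in enumerate(ordered) for name in ms}
    rng = np.random.default_rng(seed)
    kept = [sorted(ms)[int(rng.integers(0, len(ms)))] for ms in ordered]
    return SelectionResult(kept, removed, assignment, seed)


_GRIDS = {
    "rf": {"n_estimators": [100], "max_features": ["sqrt", 0.5]},
    "nn": {"hidden_layer_sizes": [(64,), (128,)], "alpha": [1e-4, 1e-2]},
    "svm": {"C": [1.0, 10.0], "gamma": ["scale"]},
}


def _make_learner(learner: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if learner == "rf":
        return RandomForestClassifier(random_state=seed), _GRIDS["rf"]
    if learner == "nn":
        est = Pipeline(
            [("scale", StandardScaler()), ("clf", MLPClassifier(max_iter=500, random_state=seed))]
        )
        return est, {f"clf__{k}": v for k, v in _GRIDS["nn"].items()}
    if learner == "svm":
        est = Pipeline([("scale", StandardScaler()), ("clf", SVC(random_state=seed))])
        return est, {f"clf__{k}": v for k, v in _GRIDS["svm"].items()}
    raise ValueError(f"unknown learner {learner!r}; choose rf, nn or svm")


def run_baseline(
    features: DescriptorMatrix,
    labels: LabelMatrix,
    learner: str = "rf",
    scheme: str = "CV5",
    seed: int = 0,
    grid_search: bool = True,
) -> CVReport:
    """Cross-validate per-category binary learners on a fixed feature matrix.

    Each category gets its own classifier (grid-searched over a small
    documented grid inside each training fold); the report has the same
    shape as the graph network's, so the two are directly comparable. A
    category whose training fold holds a single class is skipped for that
    fold with a warning.
    """
    from sklearn.model_selection import GridSearchCV

    id_index = {cid: i for i, cid in enumerate(labels.compound_ids)}
    missing = [cid for cid in features.compound_ids if cid not in id_index]
    if missing:
        raise ValueError(f"no label row for compound(s) {missing[:3]}")
    y_all = np.array([labels.membership[id_index[cid]] for cid in features.compound_ids])
    x_all = features.values
    n = len(features.compound_ids)

    scheme = scheme.upper()
    if scheme == "CV5":
        k_folds = 5
    elif scheme == "LOOCV":
        k_folds = n
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    folds = assign_folds(n, k_folds, rng)

    categories = list(labels.categories)
    confusion = {c: {"tp": 0, "fp": 0, "fn": 0, "tn": 0} for c in categories}
    for fold in range(k_folds):
        tr, te = folds != fold, folds == fold
        for k, cat in enumerate(categories):
            y_tr = y_all[tr, k]
            if len(np.unique(y_tr)) < 2:
                warnings.warn(
                    f"fold {fold}: category {cat!r} has a single class in training; skipped",
                    stacklevel=2,
                )
                continue
            est, grid = _make_learner(learner, seed)
            if grid_search:
                est = GridSearchCV(est, grid, cv=3, n_jobs=1)
            est.fit(x_all[tr], y_tr)
            pred = est.predict(x_all[te])
            for t, p in zip(y_all[te, k], pred):
                key = {(1, 1): "tp", (0, 1): "fp", (1, 0): "fn", (0, 0): "tn"}[(int(t), int(p))]
                confusion[cat][key] += 1

    report = CVReport(
        scheme=scheme,
        per_category_accuracy={},
        global_average=float("nan"),
        per_fold_seeds=[seed],
        confusion=confusion,
        n_samples=n,
        seed=seed,
        n_folds=k_folds,
    )
    report.per_category_accuracy = {
        c: report.accuracy_from_confusion(c) for c in categories
    }
    vals = [v for v in report.per_category_accuracy.values() if not np.isnan(v)]
    report.global_average = float(np.mean(vals)) if vals else float("nan")
    return report
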