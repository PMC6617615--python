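"""Cross-validation harnesses and multilabel summary statistics.

Per-category "accuracy" is binary accuracy over held-out samples: the
fraction whose thresholded positive call for that category matches the
label bit. The global average is the unweighted mean of the K per-category
accuracies. Fold assignment is random (seeded), unstratified, and by
compound, so a compound never appears in both the training and test side
of one fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .molgraph import LabelMatrix, MolecularGraph
from .training import ModelCheckpoint, TrainingConfig, predict, train

__all__ = [
    "CVReport",
    "CountStats",
    "assign_folds",
    "cross_validate",
    "count_statistics",
    "stage_sweep",
]


@dataclass
class CVReport:
    """Outcome of one cross-validation run.

    ``confusion`` maps each category to {tp, fp, fn, tn} counts accumulated
    over all test folds; accuracies are derived from these counts, so the
    report is internally consistent by construction.
    """

    scheme: str
    per_category_accuracy: dict[str, float]
    global_average: float
    per_fold_seeds: list[int]
    confusion: dict[str, dict[str, int]]
    n_samples: int
    seed: int
    n_folds: int

    def accuracy_from_confusion(self, category: str) -> float:
        c = self.confusion[category]
        total = c["tp"] + c["fp"] + c["fn"] + c["tn"]
        return (c["tp"] + c["tn"]) / total if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": k, "accuracy": v, **self.confusion[k]}
            for k, v in self.per_category_accuracy.items()
        ]
        rows.append({"category": "Av", "accuracy": self.global_average})
        return pd.DataFrame(rows)


@dataclass
class CountStats:
    """Predicted-vs-original starting-substance count statistics.

    Means are per-compound positive-label counts. The correlation and the
    ordinary-least-squares line (with 95% confidence intervals) relate the
    per-category totals of predicted to original positives, one point per
    category. ``degenerate`` flags zero variance, where r is undefined.
    """

    mean_original: float
    mean_predicted: float
    correlation_r: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    degenerate: bool = False


def assign_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random unstratified fold labels 0..n_folds-1, balanced to within one."""
    if n < n_folds:
        raise ValueError(f"dataset of {n} samples cannot fill {n_folds} folds")
    folds = np.arange(n) % n_folds
    rng.shuffle(folds)
    return folds


def _dedup_by_compound(
    graphs: list[MolecularGraph], labels: LabelMatrix
) -> list[MolecularGraph]:
    seen: set[str] = set()
    out = []
    for g in graphs:
        if g.compound_id in seen:
            continue
        seen.add(g.compound_id)
        out.append(g)
    return out


def cross_validate(
    graphs: list[MolecularGraph],
    labels: LabelMatrix,
    cfg: TrainingConfig,
    scheme: str = "CV5",
    n_folds: int | None = None,
    keep_duplicates: bool = False,
    trainer=None,
) -> CVReport:
    """Cross-validate an MGCNN (or a drop-in trainer) over a labeled dataset.

    ``scheme`` is "CV5", "LOOCV" or "holdout" (holdout = one 80/20 split).
    One model is trained per fold with ``cfg``; per-category confusion
    counts accumulate over the held-out predictions of every fold.
    ``trainer(graphs, labels, cfg) -> checkpoint`` may replace MGCNN
    training, e.g. for baseline learners that emit the same report shape.
    """
    scheme = scheme.upper() if scheme.lower() != "holdout" else "holdout"
    if not keep_duplicates:
        graphs = _dedup_by_compound(graphs, labels)
    n = len(graphs)
    if scheme == "CV5":
        k_folds = n_folds or 5
    elif scheme == "LOOCV":
        k_folds = n
    elif scheme == "holdout":
        k_folds = 5  # a single 1-in-5 test split
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(cfg.seed)
    folds = assign_folds(n, k_folds, rng)
    fold_ids = range(1) if scheme == "holdout" else range(k_folds)

    categories = list(labels.categories)
    confusion = {c: {"tp": 0, "fp": 0, "fn": 0, "tn": 0} for c in categories}
    label_index = {cid: i for i, cid in enumerate(labels.compound_ids)}
    per_fold_seeds = []

    for fold in fold_ids:
        train_graphs = [g for g, f in zip(graphs, folds) if f != fold]
        test_graphs = [g for g, f in zip(graphs, folds) if f == fold]
        fold_seed = int(np.random.default_rng([cfg.seed, fold]).integers(2**31))
        per_fold_seeds.append(fold_seed)
        fold_cfg = replace(cfg, seed=fold_seed)
        if trainer is None:
            checkpoint, _ = train(train_graphs, labels, fold_cfg)
        else:
            checkpoint = trainer(train_graphs, labels, fold_cfg)
        calls, _ = predict(checkpoint, test_graphs)
        call_index = {cid: i for i, cid in enumerate(calls.compound_ids)}
        for g in test_graphs:
            if g.compound_id not in call_index:
                continue  # skipped (e.g. unknown atom); excluded from counts
            truth = labels.membership[label_index[g.compound_id]]
            pred = calls.membership[call_index[g.compound_id]]
            for c, t, p in zip(categories, truth, pred):
                key = {(1, 1): "tp", (0, 1): "fp", (1, 0): "fn", (0, 0): "tn"}[(int(t), int(p))]
                confusion[c][key] += 1

    report = CVReport(
        scheme=scheme,
        per_category_accuracy={},
        global_average=float("nan"),
        per_fold_seeds=per_fold_seeds,
        confusion=confusion,
        n_samples=n,
        seed=cfg.seed,
        n_folds=k_folds,
    )
    report.per_category_accuracy = {
        c: report.accuracy_from_confusion(c) for c in categories
    }
    report.global_average = float(np.mean(list(report.per_category_accuracy.values())))
    return report


def count_statistics(predicted: LabelMatrix, original: LabelMatrix) -> CountStats:
    """Compare predicted and original positive-label counts.

    Requires identical compound and category sets (order-insensitive for
    compounds). With zero variance in either per-category count vector the
    correlation is undefined: reported as NaN with ``degenerate=True``.
    """
    if set(predicted.compound_ids) != set(original.compound_ids):
        raise ValueError("predicted and original label matrices cover different compounds")
    if list(predicted.categories) != list(original.categories):
        raise ValueError("category lists differ")
    order = [predicted.compound_ids.index(cid) for cid in original.compound_ids]
    pred = predicted.membership[order]
    orig = original.membership

    mean_original = float(orig.sum(axis=1).mean())
    mean_predicted = float(pred.sum(axis=1).mean())
    x = orig.sum(axis=0).astype(float)  # per-category totals
    y = pred.sum(axis=0).astype(float)

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        nan = float("nan")
        return CountStats(
            mean_original, mean_predicted, nan, nan, nan, (nan, nan), (nan, nan),
            degenerate=True,
        )
    fit = scipy.stats.linregress(x, y)
    dof = len(x) - 2
    t_crit = scipy.stats.t.ppf(0.975, dof) if dof > 0 else float("nan")
    return CountStats(
        mean_original=mean_original,
        mean_predicted=mean_predicted,
        correlation_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci=(
            float(fit.slope - t_crit * fit.stderr),
            float(fit.slope + t_crit * fit.stderr),
        ),
        intercept_ci=(
            float(fit.intercept - t_crit * fit.intercept_stderr),
            float(fit.intercept + t_crit * fit.intercept_stderr),
        ),
    )


def stage_sweep(
    graphs: list[MolecularGraph],
    labels: LabelMatrix,
    cfg: TrainingConfig,
    stage_range: list[int],
    scheme: str = "CV5",
) -> pd.DataFrame:
    """Cross-validate once per convolution-stage count, all else fixed.

    Every swept network uses the final stage width of ``cfg`` for all its
    stages. Returns a table with one row per entry of ``stage_range``.
    """
    if not stage_range:
        raise ValueError("stage_range must be non-empty")
    width = cfg.stage_dims[-1]
    rows = []
    for s in stage_range:
        swept = replace(cfg, n_stages=s, stage_dims=[width] * s)
        report = cross_validate(graphs, labels, swept, scheme=scheme)
        rows.append({"n_stages": s, "global_average": report.global_average})
    return pd.DataFrame(rows)
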