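"""Fingerprints, correlation-network feature selection, baseline learners."""

import numpy as np
import pytest

from mgcnn.baselines import (
    DescriptorMatrix,
    ecfp,
    read_descriptor_csv,
    run_baseline,
    select_features,
)
from mgcnn.molgraph import LabelMatrix, parse_smiles


class TestEcfp:
    def test_contract_1024_binary(self):
        fp = ecfp("CCO")
        assert fp.shape == (1024,)
        assert set(np.unique(fp)) <= {0, 1}
        assert fp.sum() > 0

    def test_identical_molecules_identical_fingerprints(self):
        np.testing.assert_array_equal(ecfp("c1ccccc1O"), ecfp("Oc1ccccc1"))

    def test_tanimoto_self_similarity_is_one(self):
        fp = ecfp("CC(=O)Nc1ccc(O)cc1")
        inter = np.logical_and(fp, fp).sum()
        union = np.logical_or(fp, fp).sum()
        assert inter / union == 1.0

    def test_accepts_molecular_graph(self):
        g = parse_smiles("CCO ethanol", explicit_h=False)
        fp = ecfp(g)
        assert fp.shape == (1024,)

    def test_rejected_structure_raises(self):
        with pytest.raises(ValueError):
            ecfp("not-a-smiles")


def _block_matrix(rng, n=100, n_blocks=4, block_size=5, n_singletons=3):
    """Known correlation structure: clones within blocks, independent singletons."""
    cols, names, block_of = [], [], {}
    for b in range(n_blocks):
        base = rng.normal(size=n)
        for j in range(block_size):
            name = f"b{b}_v{j}"
            cols.append(base + rng.normal(scale=1e-6, size=n))
            names.append(name)
            block_of[name] = b
    for s in range(n_singletons):
        name = f"s{s}"
        cols.append(rng.normal(size=n))
        names.append(name)
        block_of[name] = n_blocks + s
    values = np.column_stack(cols)
    ids = [f"c{i}" for i in range(n)]
    return DescriptorMatrix(ids, names, values), block_of


class TestSelectFeatures:
    def test_blocks_reduce_to_one_representative_each(self, oracles):
        rng = np.random.default_rng(1)
        d, block_of = _block_matrix(rng)
        result = select_features(d, r_threshold=0.6, seed=0)
        assert len(result.kept_variable_names) == 7
        kept_blocks = sorted(block_of[v] for v in result.kept_variable_names)
        assert kept_blocks == list(range(7))  # exactly one per block/singleton

        # independent union-find over the same |r| > 0.6 graph
        corr = np.corrcoef(d.values, rowvar=False)
        uf = oracles["union_find"](len(d.variable_names))
        for i in range(len(d.variable_names)):
            for j in range(i + 1, len(d.variable_names)):
                if abs(corr[i, j]) > 0.6:
                    uf.union(i, j)
        assert len(uf.components()) == 7
        by_name = {n: i for i, n in enumerate(d.variable_names)}
        for comp in uf.components().values():
            roots = {uf.find(by_name[v]) for v in result.kept_variable_names if by_name[v] in comp}
            assert len(roots) <= 1

    def test_constant_variable_goes_to_noninformative(self):
        rng = np.random.default_rng(2)
        d = DescriptorMatrix(
            [f"c{i}" for i in range(20)],
            ["flat", "ok"],
            np.column_stack([np.full(20, 3.0), rng.normal(size=20)]),
        )
        result = select_features(d, seed=0)
        assert result.removed_noninformative == ["flat"]
        assert "flat" not in result.component_assignment
        assert result.kept_variable_names == ["ok"]

    def test_independent_variables_all_kept_at_high_threshold(self):
        rng = np.random.default_rng(3)
        n, p = 200, 30
        d = DescriptorMatrix(
            [f"c{i}" for i in range(n)],
            [f"v{j}" for j in range(p)],
            rng.standard_normal((n, p)),
        )
        corr = np.corrcoef(d.values, rowvar=False)
        off = corr[~np.eye(p, dtype=bool)]
        assert np.abs(off).max() < 0.999  # premise of the check
        result = select_features(d, r_threshold=0.999, seed=0)
        assert sorted(result.kept_variable_names) == sorted(d.variable_names)

    def test_component_assignment_invariant_to_column_order(self):
        rng = np.random.default_rng(4)
        d, _ = _block_matrix(rng, n=50, n_blocks=2, block_size=3, n_singletons=2)
        shuffled_idx = list(range(len(d.variable_names)))[::-1]
        d2 = DescriptorMatrix(
            d.compound_ids,
            [d.variable_names[i] for i in shuffled_idx],
            d.values[:, shuffled_idx],
        )
        r1 = select_features(d, seed=9)
        r2 = select_features(d2, seed=9)
        assert r1.component_assignment == r2.component_assignment
        assert r1.kept_variable_names == r2.kept_variable_names

    def test_too_few_samples_rejected(self):
        d = DescriptorMatrix(["a", "b"], ["v"], np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError):
            select_features(d)


class TestRunBaseline:
    def _labels(self, rng, n, k=2):
        return LabelMatrix(
            [f"c{i}" for i in range(n)],
            [f"cat{j}" for j in range(k)],
            rng.integers(0, 2, size=(n, k)),
        )

    @pytest.mark.parametrize("learner", ["rf", "nn", "svm"])
    def test_leaked_label_column_scores_perfectly(self, learner):
        rng = np.random.default_rng(6)
        n = 60
        labels = self._labels(rng, n, k=1)
        values = np.column_stack(
            [labels.membership[:, 0].astype(float), rng.normal(size=n)]
        )
        feats = DescriptorMatrix(list(labels.compound_ids), ["leak", "noise"], values)
        report = run_baseline(feats, labels, learner=learner, seed=0, grid_search=False)
        assert report.per_category_accuracy["cat0"] == 1.0

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(7)
        n = 200
        labels = self._labels(rng, n, k=1)  # labels independent of features
        feats = DescriptorMatrix(
            list(labels.compound_ids),
            [f"v{j}" for j in range(10)],
            rng.standard_normal((n, 10)),
        )
        report = run_baseline(feats, labels, learner="rf", seed=1, grid_search=False)
        acc = report.per_category_accuracy["cat0"]
        se = np.sqrt(0.25 / n)
        assert abs(acc - 0.5) < 3 * se + abs(labels.membership.mean() - 0.5)

    def test_report_shape_matches_network_cv_report(self):
        rng = np.random.default_rng(8)
        labels = self._labels(rng, 30)
        feats = DescriptorMatrix(
            list(labels.compound_ids), ["v0", "v1"], rng.standard_normal((30, 2))
        )
        report = run_baseline(feats, labels, learner="rf", seed=0, grid_search=False)
        assert set(report.per_category_accuracy) == {"cat0", "cat1"}
        assert set(report.confusion["cat0"]) == {"tp", "fp", "fn", "tn"}
        assert report.scheme == "CV5"
        assert 0.0 <= report.global_average <= 1.0

    def test_single_class_category_skipped_with_warning(self):
        rng = np.random.default_rng(9)
        n = 25
        labels = LabelMatrix(
            [f"c{i}" for i in range(n)], ["never"], np.zeros((n, 1), dtype=int)
        )
        feats = DescriptorMatrix(
            list(labels.compound_ids), ["v"], rng.standard_normal((n, 1))
        )
        with pytest.warns(UserWarning, match="single class"):
            report = run_baseline(feats, labels, learner="rf", seed=0, grid_search=False)
        assert np.isnan(report.global_average)


def test_descriptor_csv_round_trip(tmp_path):
    p = tmp_path / "desc.csv"
    p.write_text("compound_id,v1,v2\nc1,0.5,1\nc2,-1.5,0\n")
    d = read_descriptor_csv(p)
    assert d.variable_names == ["v1", "v2"]
    assert d.values.shape == (2, 2)
    assert d.values[1, 0] == -1.5
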