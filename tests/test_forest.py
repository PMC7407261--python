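import json

import numpy as np
import pytest

from epiforest import (
    ForestParams,
    GenotypeMatrix,
    PhenotypeVector,
    RandomForestGwas,
    SplitCandidate,
    aggregate_local_bests,
    best_split,
    expected_runtime,
    gen_features,
    gini_impurity,
    grow_tree,
    op_count,
    partition,
    train,
)


def _pheno(labels):
    labels = np.asarray(labels)
    k = int(labels.max()) + 1
    return PhenotypeVector(labels, tuple(str(i) for i in range(k)))


def brute_force_best_split(values, rows, y, candidates, n_levels=3):
    """Independent oracle: enumerate every (candidate, threshold) pair."""
    y_node = y[rows]
    classes = np.unique(y)
    parent = np.array([(y_node == c).sum() for c in classes], dtype=float)
    n = len(rows)
    imp_parent = 1 - ((parent / n) ** 2).sum()
    best = None
    for v in sorted(candidates):
        g = values[rows, v]
        for t in range(n_levels - 1):
            left = g <= t
            n_l, n_r = left.sum(), n - left.sum()
            if n_l == 0 or n_r == 0:
                continue

            def imp(mask):
                cnt = np.array([(y_node[mask] == c).sum() for c in classes], float)
                p = cnt / cnt.sum()
                return 1 - (p**2).sum()

            gain = imp_parent - (n_l * imp(left) + n_r * imp(~left)) / n
            key = (-gain, v, t)
            if gain > 0 and (best is None or key < best[0]):
                best = (key, v, t, gain, n_l, n_r)
    return best


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 0), 0.0), ((5, 5), 0.5), ((1, 1, 1, 1), 0.75)],
    )
    def test_closed_forms(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))
        with pytest.raises(ValueError):
            gini_impurity((1, -1))


class TestBestSplit:
    def test_perfect_split_gains_parent_impurity(self):
        values = np.array([[0], [0], [1], [2]])
        m = GenotypeMatrix(values, ("v0",), ("a", "b", "c", "d"))
        ph = _pheno([0, 0, 1, 1])
        (block,) = partition(m, 1)
        cand = best_split(block, np.arange(4), ph, np.array([0]))
        assert cand.variant_index == 0 and cand.threshold == 0
        assert cand.gain == pytest.approx(0.5)  # parent impurity, pure children

    def test_constant_candidate_gives_none(self):
        m = GenotypeMatrix(np.ones((6, 1), dtype=int), ("v0",), tuple("abcdef"))
        ph = _pheno([0, 1, 0, 1, 0, 1])
        (block,) = partition(m, 1)
        assert best_split(block, np.arange(6), ph, np.array([0])) is None

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            values = rng.integers(0, 3, size=(8, 3))
            y = rng.integers(0, 2, size=8)
            if len(np.unique(y)) < 2:
                continue
            m = GenotypeMatrix(
                values, tuple(f"v{j}" for j in range(3)), tuple(f"s{i}" for i in range(8))
            )
            ph = _pheno(y)
            (block,) = partition(m, 1)
            got = best_split(block, np.arange(8), ph, np.arange(3))
            want = brute_force_best_split(values, np.arange(8), y, range(3))
            if want is None:
                assert got is None
            else:
                assert (got.variant_index, got.threshold) == (want[1], want[2])
                assert got.gain == pytest.approx(want[3])


class TestAggregate:
    def c(self, gain, v=0, t=0):
        return SplitCandidate(v, t, gain, 1, 1)

    def test_argmax(self):
        best = aggregate_local_bests([self.c(0.3, 1), self.c(0.5, 2), None])
        assert best.gain == 0.5 and best.variant_index == 2

    def test_tie_breaks_to_lower_variant_then_threshold(self):
        best = aggregate_local_bests([self.c(0.4, 7, 1), self.c(0.4, 3, 1), self.c(0.4, 3, 0)])
        assert (best.variant_index, best.threshold) == (3, 0)

    def test_all_none(self):
        assert aggregate_local_bests([None, None]) is None


class TestGrowTree:
    def test_forced_single_variant_split(self):
        values = np.zeros((20, 3), dtype=int)
        values[10:, 1] = 2
        m = GenotypeMatrix(values, ("a", "b", "c"), tuple(f"s{i}" for i in range(20)))
        ph = _pheno([0] * 10 + [1] * 10)
        blocks = partition(m, 1)
        params = ForestParams(n_tree=1, m_try=3, seed=0)
        root = grow_tree(blocks, ph, params, 0, bootstrap=False)
        assert root.split.variant_index == 1
        assert root.left.is_leaf and root.right.is_leaf

    @staticmethod
    def _walk(root):
        stack, nodes = [root], []
        while stack:
            n = stack.pop()
            nodes.append(n)
            if not n.is_leaf:
                stack += [n.left, n.right]
        return nodes

    def test_depth_and_node_size_limits(self, planted_dataset):
        matrix, phenotype, _ = planted_dataset
        blocks = partition(matrix, 4)
        root = grow_tree(
            blocks, phenotype, ForestParams(n_tree=1, max_depth=3, seed=1), 0
        )
        assert all(n.depth <= 3 for n in self._walk(root))
        root = grow_tree(
            blocks, phenotype, ForestParams(n_tree=1, min_node_size=50, seed=1), 0
        )
        assert all(n.n_samples >= 50 for n in self._walk(root) if not n.is_leaf)

    def test_gain_conservation(self, planted_dataset):
        matrix, phenotype, _ = planted_dataset
        y = phenotype.labels
        blocks = partition(matrix, 2)
        root = grow_tree(blocks, phenotype, ForestParams(n_tree=1, seed=2), 0, bootstrap=False)
        for n in self._walk(root):
            if n.is_leaf:
                continue
            assert n.split.gain > 0
            assert n.left.n_samples + n.right.n_samples == n.n_samples

    def test_single_class_rejected(self, tiny_matrix):
        ph = PhenotypeVector(np.zeros(8, dtype=int), ("only",))
        with pytest.raises(Exception, match="class"):
            grow_tree(partition(tiny_matrix, 1), ph, ForestParams(n_tree=1), 0)


class TestTrain:
    def test_partition_and_batch_invariance(self, planted_dataset):
        matrix, phenotype, _ = planted_dataset
        params = ForestParams(n_tree=12, seed=5, batch_size=4)
        ref = train(matrix, phenotype, params, n_blocks=1)
        ref_json = ref.to_json()
        for n_blocks in (3, 7):
            alt = train(matrix, phenotype, params, n_blocks=n_blocks)
            assert alt.to_json() == ref_json
            np.testing.assert_array_equal(alt.importance_, ref.importance_)
        for rbs in (1, 12):
            alt = train(
                matrix,
                phenotype,
                ForestParams(n_tree=12, seed=5, batch_size=rbs),
                n_blocks=3,
            )
            assert alt.to_json() == ref_json

    def test_single_tree_without_bootstrap_is_deterministic_dt(self, planted_dataset):
        matrix, phenotype, _ = planted_dataset
        params = ForestParams(n_tree=1, m_try=matrix.n_variants, seed=0)
        res = train(matrix, phenotype, params, bootstrap=False)
        res2 = train(matrix, phenotype, params, bootstrap=False)
        assert res.to_json() == res2.to_json()
        # a fully grown tree with all variants available fits training data
        assert np.mean(res.predict() == phenotype.labels) == 1.0

    def test_importance_zero_for_unselected_variants(self, planted_dataset):
        matrix, phenotype, _ = planted_dataset
        res = train(matrix, phenotype, ForestParams(n_tree=10, seed=3))
        selected = set()
        for tree in res.trees:
            stack = [tree]
            while stack:
                n = stack.pop()
                if not n.is_leaf:
                    selected.add(n.split.variant_index)
                    stack += [n.left, n.right]
        unselected = set(range(matrix.n_variants)) - selected
        assert np.all(res.importance_[list(unselected)] == 0)
        assert np.all(res.importance_ >= 0)

    def test_importance_formula_single_stump(self):
        # one tree, root split on full (bootstrap-free) sample with gain g:
        # weighted importance = (n/n) * g / n_tree = g
        values = np.zeros((10, 2), dtype=int)
        values[5:, 0] = 2
        m = GenotypeMatrix(values, ("a", "b"), tuple(f"s{i}" for i in range(10)))
        ph = _pheno([0] * 5 + [1] * 5)
        res = train(m, ph, ForestParams(n_tree=1, m_try=2, seed=0), bootstrap=False)
        assert res.importance_[0] == pytest.approx(res.trees[0].split.gain)
        assert res.model_stats() == (1.0, 1.0)

    def test_causal_variants_match_sklearn_ranking(self, planted_dataset):
        matrix, phenotype, truth = planted_dataset
        res = train(matrix, phenotype, ForestParams(n_tree=150, seed=1))
        ours = set(np.argsort(-res.importance_)[:3])

        from sklearn.ensemble import RandomForestClassifier

        rf = RandomForestClassifier(n_estimators=150, random_state=0)
        rf.fit(np.asarray(matrix.values), phenotype.labels)
        theirs = set(np.argsort(-rf.feature_importances_)[:3])
        assert ours == set(truth.truth_variants) == theirs

    def test_oob_undefined_without_bootstrap(self, planted_dataset):
        matrix, phenotype, _ = planted_dataset
        res = train(matrix, phenotype, ForestParams(n_tree=2, seed=0), bootstrap=False)
        with pytest.raises(ValueError, match="out-of-bag"):
            _ = res.oob_error_

    def test_mtry_resolution(self):
        assert ForestParams(m_try=None).resolve_m_try(400) == 20
        assert ForestParams(m_try=0.1).resolve_m_try(400) == 40
        assert ForestParams(m_try=7).resolve_m_try(400) == 7
        with pytest.raises(ValueError):
            ForestParams(m_try=500).resolve_m_try(400)


class TestComplexityModels:
    def test_op_count_is_product(self):
        assert op_count(10, 100, 7, 3) == 10 * 100 * 7 * 3
        assert op_count(1, 1, 1, 1) == 1
        with pytest.raises(ValueError):
            op_count(0, 1, 1, 1)

    def test_expected_runtime_affine(self):
        assert expected_runtime(100, 2, 1000) == 2100
        assert expected_runtime(5, 0, 123) == 5
        assert expected_runtime(5, 2, 0) == 5


def test_model_json_export_fields(planted_dataset, tmp_path):
    matrix, phenotype, _ = planted_dataset
    res = train(matrix, phenotype, ForestParams(n_tree=4, seed=0))
    path = tmp_path / "model.json"
    res.to_json(path)
    doc = json.loads(path.read_text())
    assert doc["params"]["n_tree"] == 4
    assert len(doc["trees"]) == 4
    assert len(doc["tree_depths"]) == 4
    assert 0 <= doc["oob_error"] <= 1
    root = doc["trees"][0]
    assert "leaf_class" in root or ("variant" in root and "gain" in root)
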