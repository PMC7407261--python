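"""Random-forest association engine over column-partitioned genotype matrices.

The model follows the classic random-forest classifier specialised to ordinal
genotype features: binary trees, Gini-impurity splits with thresholds over the
ordinal domain, bootstrap resampling, out-of-bag (OOB) error, and a
per-variant importance score defined as the node-size-weighted Gini gain a
variant earns wherever it is the best split, averaged over trees.  Because a
variant's gain at a node is conditional on every split above it, the
importance score absorbs interaction signal that single-variant tests cannot
see — this is what makes the forest an association engine for epistatic
phenotypes, not just a classifier.

Training honours a vertical-partitioning contract: the variant axis is tiled
into column blocks, each block evaluates only its own share of a node's
candidate variants and surfaces a single local best split, and the global
split is the argmax over local bests with a total-order tie-break.  Together
with a counter-based RNG discipline (per-tree streams keyed by
``(seed, tree_index)``, per-node streams by ``(seed, tree_index, node_id)``)
this makes the fitted model bit-identical for any number of column blocks,
any tree-batch size, and any worker count.

The statsmodels-style surface is :class:`RandomForestGwas` (build from data,
call :meth:`~RandomForestGwas.fit`) returning :class:`ForestResults`.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .genodata import (
    ColumnBlock,
    GenotypeMatrix,
    PhenotypeVector,
    partition,
)

__all__ = [
    "ForestParams",
    "SplitCandidate",
    "TreeNode",
    "RandomForestGwas",
    "ForestResults",
    "gini_impurity",
    "best_split",
    "aggregate_local_bests",
    "grow_tree",
    "train",
    "oob_error",
    "importance_scores",
    "model_stats",
    "op_count",
    "expected_runtime",
]

# spawn-key namespaces for the two RNG stream families
_BOOTSTRAP_STREAM = 0
_NODE_STREAM = 1


@dataclass(frozen=True)
class ForestParams:
    """Forest hyper-parameters.

    n_tree
        Trees in the forest.
    m_try
        Candidate variants evaluated at each node.  ``None`` resolves to
        ``round(sqrt(n_variants))`` (the classic rule of thumb); a float in
        (0, 1) resolves to that fraction of the variant count; an integer is
        used as-is.
    max_depth
        Maximum tree depth, root at depth 0; ``None`` means unlimited.
    min_node_size
        Minimum samples a node must hold to be processed (split); a smaller
        node becomes a leaf without evaluation.  ``None`` means no limit.
    batch_size
        Trees grown per parallel batch ("rbs").  A throughput knob only:
        the fitted model is identical for every value.
    seed
        Master seed from which every tree- and node-level stream derives.
    """

    n_tree: int = 1000
    m_try: int | float | None = None
    max_depth: int | None = None
    min_node_size: int | None = None
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tree < 1:
            raise ValueError("n_tree must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")
        if self.min_node_size is not None and self.min_node_size < 2:
            raise ValueError("min_node_size must be >= 2 or None")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def resolve_m_try(self, n_variants: int) -> int:
        if self.m_try is None:
            m = round(math.sqrt(n_variants))
        elif isinstance(self.m_try, float) and 0 < self.m_try < 1:
            m = round(self.m_try * n_variants)
        else:
            m = int(self.m_try)
        m = max(1, m)
        if m > n_variants:
            raise ValueError(f"m_try={m} exceeds n_variants={n_variants}")
        return m


@dataclass(frozen=True)
class SplitCandidate:
    """A proposed binary split: samples with ``g <= threshold`` go left."""

    variant_index: int
    threshold: int
    gain: float
    left_size: int
    right_size: int

    def sort_key(self):
        # total order: higher gain first, then lower variant, lower threshold
        return (-self.gain, self.variant_index, self.threshold)


@dataclass
class TreeNode:
    """A node of a fitted tree; a leaf iff ``split`` is None."""

    node_id: int
    depth: int
    n_samples: int
    split: SplitCandidate | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    leaf_class: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


# ---------------------------------------------------------------------------
# impurity and split search


def gini_impurity(class_counts: Sequence[int]) -> float:
    """Gini impurity ``1 - sum_c p_c^2`` of a node's class counts."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("class_counts must be a non-empty 1-D sequence")
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty node has no impurity")
    p = counts / total
    return float(1.0 - (p * p).sum())


@njit(cache=True)
def _count_genotype_classes(values, rows, cand, y, n_levels, n_classes):
    """Per-candidate contingency counts over a node's sample multiset.

    values : (nS, nV) int8, Fortran order; rows : node sample indices with
    bootstrap multiplicity; cand : global candidate variant indices.
    Returns counts of shape (len(cand), n_levels, n_classes).
    """
    m = cand.shape[0]
    counts = np.zeros((m, n_levels, n_classes), dtype=np.int64)
    for j in range(m):
        col = values[:, cand[j]]
        for i in range(rows.shape[0]):
            r = rows[i]
            counts[j, col[r], y[r]] += 1
    return counts


def _best_from_counts(
    counts: np.ndarray,
    cand: np.ndarray,
    parent_counts: np.ndarray,
    parent_impurity: float,
) -> SplitCandidate | None:
    """Pick the best (candidate, threshold) pair from contingency counts.

    gain = imp(parent) - (nL/n) imp(L) - (nR/n) imp(R); splits leaving a
    child empty are invalid; non-positive gains are discarded.  The gain of a
    candidate depends only on its own column and the node labels, so the
    value is bit-identical no matter which block computed it.
    """
    n = int(parent_counts.sum())
    cum = counts.cumsum(axis=1)[:, :-1, :]  # (m, n_levels-1, K) left counts
    n_left = cum.sum(axis=2).astype(np.float64)  # (m, T)
    n_right = n - n_left
    with np.errstate(divide="ignore", invalid="ignore"):
        p_left = cum / n_left[:, :, None]
        p_right = (parent_counts[None, None, :] - cum) / n_right[:, :, None]
        imp_left = 1.0 - np.nansum(p_left * p_left, axis=2)
        imp_right = 1.0 - np.nansum(p_right * p_right, axis=2)
    gain = parent_impurity - (n_left * imp_left + n_right * imp_right) / n
    valid = (n_left > 0) & (n_right > 0)
    gain = np.where(valid, gain, -np.inf)
    best_gain = gain.max()
    if not (best_gain > 0.0):
        return None
    # tie-break among exact-equal gains: lowest variant index, lowest threshold
    js, ts = np.nonzero(gain == best_gain)
    order = np.lexsort((ts, cand[js]))
    j, t = int(js[order[0]]), int(ts[order[0]])
    return SplitCandidate(
        variant_index=int(cand[j]),
        threshold=t,
        gain=float(best_gain),
        left_size=int(n_left[j, t]),
        right_size=int(n_right[j, t]),
    )


def best_split(
    block: ColumnBlock,
    node_sample_index: np.ndarray,
    labels: PhenotypeVector,
    candidates_in_block: np.ndarray,
) -> SplitCandidate | None:
    """Local best split among a block's share of a node's candidate variants.

    This is the per-worker half of the communication contract: a block
    evaluates only candidates it owns and surfaces one local best (or none).
    """
    cand = np.asarray(candidates_in_block, dtype=np.int64)
    if cand.size == 0:
        return None
    if not all(block.owns(int(v)) for v in cand):
        raise ValueError("candidate outside this block's span")
    rows = np.asarray(node_sample_index, dtype=np.int64)
    y = labels.labels
    n_classes = labels.n_classes
    if rows.size < 2 or np.unique(y[rows]).size < 2:
        return None
    parent_counts = np.bincount(y[rows], minlength=n_classes)
    counts = _count_genotype_classes(
        block.matrix.values, rows, cand, y, block.matrix.n_levels, n_classes
    )
    return _best_from_counts(
        counts, cand, parent_counts, gini_impurity(parent_counts)
    )


def aggregate_local_bests(
    local_bests: Sequence[SplitCandidate | None],
) -> SplitCandidate | None:
    """Master-side aggregation: global argmax over per-block local bests.

    Ordering is (gain descending, variant index ascending, threshold
    ascending); all-None means the node cannot be split.
    """
    present = [c for c in local_bests if c is not None]
    if not present:
        return None
    return min(present, key=SplitCandidate.sort_key)


# ---------------------------------------------------------------------------
# tree growth


def _node_rng(seed: int, tree_index: int, node_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_NODE_STREAM, tree_index, node_id))
    )


def _bootstrap_rng(seed: int, tree_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_BOOTSTRAP_STREAM, tree_index))
    )


def _route_candidates(cand_sorted: np.ndarray, blocks: Sequence[ColumnBlock]):
    """Split a sorted candidate array into per-block sub-arrays."""
    bounds = [b.lo for b in blocks] + [blocks[-1].hi]
    edges = np.searchsorted(cand_sorted, bounds)
    return [cand_sorted[edges[i] : edges[i + 1]] for i in range(len(blocks))]


@dataclass
class _GrownTree:
    root: TreeNode
    in_bag_counts: np.ndarray  # per-sample bootstrap multiplicity
    importance_weighted: np.ndarray
    importance_unweighted: np.ndarray
    max_leaf_depth: int
    n_split_nodes: int


def _grow_tree_impl(
    blocks: Sequence[ColumnBlock],
    labels: PhenotypeVector,
    params: ForestParams,
    tree_index: int,
    bootstrap: bool = True,
) -> _GrownTree:
    matrix = blocks[0].matrix
    n_s, n_v = matrix.n_samples, matrix.n_variants
    y = labels.labels
    n_classes = labels.n_classes
    m_try = params.resolve_m_try(n_v)
    n_levels = matrix.n_levels

    if bootstrap:
        rows0 = _bootstrap_rng(params.seed, tree_index).integers(0, n_s, size=n_s)
        in_bag = np.bincount(rows0, minlength=n_s)
    else:
        rows0 = np.arange(n_s)
        in_bag = np.ones(n_s, dtype=np.int64)

    imp_w = np.zeros(n_v)
    imp_u = np.zeros(n_v)
    max_leaf_depth = 0
    n_split_nodes = 0
    node_counter = 0

    root = TreeNode(node_id=-1, depth=0, n_samples=rows0.size)
    # stack of (node, rows); children pushed right-first so the left child is
    # processed next and node ids follow a pre-order traversal — deterministic
    # for any blocking or batching.
    stack: list[tuple[TreeNode, np.ndarray]] = [(root, rows0)]
    while stack:
        node, rows = stack.pop()
        node.node_id = node_counter
        node_counter += 1
        class_counts = np.bincount(y[rows], minlength=n_classes)
        majority = int(np.argmax(class_counts))  # ties -> lowest class index

        stop = (
            (class_counts > 0).sum() < 2
            or (params.min_node_size is not None and rows.size < params.min_node_size)
            or (params.max_depth is not None and node.depth >= params.max_depth)
        )
        chosen: SplitCandidate | None = None
        if not stop:
            rng = _node_rng(params.seed, tree_index, node.node_id)
            cand = np.sort(rng.choice(n_v, size=m_try, replace=False))
            parent_counts = class_counts
            parent_imp = gini_impurity(parent_counts)
            locals_ = []
            for block, block_cand in zip(blocks, _route_candidates(cand, blocks)):
                if block_cand.size == 0:
                    locals_.append(None)
                    continue
                counts = _count_genotype_classes(
                    matrix.values,
                    rows,
                    block_cand,
                    y,
                    n_levels,
                    n_classes,
                )
                locals_.append(
                    _best_from_counts(counts, block_cand, parent_counts, parent_imp)
                )
            chosen = aggregate_local_bests(locals_)

        if chosen is None:
            node.leaf_class = majority
            max_leaf_depth = max(max_leaf_depth, node.depth)
            continue

        n_split_nodes += 1
        imp_w[chosen.variant_index] += (rows.size / n_s) * chosen.gain
        imp_u[chosen.variant_index] += chosen.gain
        node.split = chosen
        col = matrix.column(chosen.variant_index)
        mask = col[rows] <= chosen.threshold
        left_rows, right_rows = rows[mask], rows[~mask]
        node.left = TreeNode(node_id=-1, depth=node.depth + 1, n_samples=left_rows.size)
        node.right = TreeNode(node_id=-1, depth=node.depth + 1, n_samples=right_rows.size)
        stack.append((node.right, right_rows))
        stack.append((node.left, left_rows))

    return _GrownTree(root, in_bag, imp_w, imp_u, max_leaf_depth, n_split_nodes)


def grow_tree(
    blocks: Sequence[ColumnBlock],
    labels: PhenotypeVector,
    params: ForestParams,
    tree_index: int,
    bootstrap: bool = True,
) -> TreeNode:
    """Grow a single tree; see :class:`RandomForestGwas` for the full fit."""
    labels.require_trainable()
    return _grow_tree_impl(blocks, labels, params, tree_index, bootstrap).root


def _predict_tree(root: TreeNode, values: np.ndarray, rows: np.ndarray) -> np.ndarray:
    out = np.empty(rows.size, dtype=np.int64)
    stack = [(root, np.arange(rows.size))]
    while stack:
        node, pos = stack.pop()
        if node.is_leaf:
            out[pos] = node.leaf_class
            continue
        g = values[rows[pos], node.split.variant_index]
        mask = g <= node.split.threshold
        stack.append((node.left, pos[mask]))
        stack.append((node.right, pos[~mask]))
    return out


# ---------------------------------------------------------------------------
# model / results


class RandomForestGwas:
    """Random-forest association model for a genotype matrix and labels.

    Parameters
    ----------
    genotypes
        The ordinal genotype matrix.
    phenotype
        Aligned class labels (binary in the default case/control design;
        multi-class is supported).
    n_blocks
        Number of contiguous column blocks the variant axis is tiled into.
        Affects data layout and the communication pattern only — the fitted
        model is identical for every value.

    Examples
    --------
    >>> model = RandomForestGwas(matrix, phenotype, n_blocks=4)
    >>> result = model.fit(ForestParams(n_tree=200, seed=7))
    >>> result.importance_frame().head()
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        phenotype: PhenotypeVector,
        n_blocks: int = 1,
    ) -> None:
        if genotypes.n_samples != phenotype.n_samples:
            raise ValueError(
                f"{genotypes.n_samples} samples in genotypes vs "
                f"{phenotype.n_samples} labels"
            )
        self.genotypes = genotypes
        self.phenotype = phenotype
        self.blocks = partition(genotypes, n_blocks)

    @classmethod
    def from_dataframe(
        cls,
        genotypes,
        labels: Sequence[str],
        n_blocks: int = 1,
    ) -> "RandomForestGwas":
        """Build from a pandas DataFrame (samples x variants) and raw labels."""
        matrix = GenotypeMatrix.from_dataframe(genotypes)
        class_names = tuple(sorted(set(str(l) for l in labels)))
        index = {c: i for i, c in enumerate(class_names)}
        pheno = PhenotypeVector(
            np.array([index[str(l)] for l in labels]),
            class_names,
            sample_ids=matrix.sample_ids,
        )
        return cls(matrix, pheno, n_blocks=n_blocks)

    def fit(
        self,
        params: ForestParams | None = None,
        n_jobs: int = 1,
        bootstrap: bool = True,
        **param_overrides,
    ) -> "ForestResults":
        """Train the forest in batches of ``params.batch_size`` trees.

        Keyword overrides (e.g. ``n_tree=500, seed=3``) are applied on top of
        ``params``.  ``bootstrap=False`` is a testing hook that trains every
        tree on the full sample (a 1-tree, ``m_try=n_variants`` fit then
        equals a deterministic decision tree).
        """
        params = params or ForestParams()
        if param_overrides:
            params = replace(params, **param_overrides)
        self.phenotype.require_trainable()
        params.resolve_m_try(self.genotypes.n_variants)  # validate early

        t0 = time.perf_counter()
        grown: list[_GrownTree] = []
        rbs = min(params.batch_size, params.n_tree)
        for start in range(0, params.n_tree, rbs):
            batch = range(start, min(start + rbs, params.n_tree))
            if n_jobs == 1:
                grown.extend(
                    _grow_tree_impl(self.blocks, self.phenotype, params, t, bootstrap)
                    for t in batch
                )
            else:
                from joblib import Parallel, delayed

                grown.extend(
                    Parallel(n_jobs=n_jobs)(
                        delayed(_grow_tree_impl)(
                            self.blocks, self.phenotype, params, t, bootstrap
                        )
                        for t in batch
                    )
                )
        train_time = time.perf_counter() - t0
        return ForestResults(self, params, grown, bootstrap, train_time)


class ForestResults:
    """A fitted forest: trees, importance, OOB error, and shape statistics."""

    def __init__(
        self,
        model: RandomForestGwas,
        params: ForestParams,
        grown: list[_GrownTree],
        bootstrap: bool,
        train_time: float,
    ) -> None:
        self.model = model
        self.params = params
        self.bootstrap = bootstrap
        self.train_time = train_time
        self.trees: list[TreeNode] = [g.root for g in grown]
        self.in_bag_counts = np.stack([g.in_bag_counts for g in grown])
        self.tree_depths = np.array([g.max_leaf_depth for g in grown])
        self.tree_node_counts = np.array([g.n_split_nodes for g in grown])
        n_tree = params.n_tree
        self.importance_ = sum(g.importance_weighted for g in grown) / n_tree
        self.importance_unweighted_ = (
            sum(g.importance_unweighted for g in grown) / n_tree
        )
        self._oob_error: float | None = None

    # -- importance ---------------------------------------------------------

    def importance(self, mode: str = "weighted") -> np.ndarray:
        """Per-variant importance score.

        ``weighted`` (default) weights each selection's gain by the fraction
        of the bootstrap sample reaching the node; ``unweighted`` averages
        raw gains.  Both divide by the number of trees; variants never chosen
        as a best split score exactly 0.
        """
        if mode == "weighted":
            return self.importance_
        if mode == "unweighted":
            return self.importance_unweighted_
        raise ValueError(f"unknown importance mode {mode!r}")

    def importance_frame(self, mode: str = "weighted"):
        """Importance table sorted by rank: variant_id, importance, rank."""
        import pandas as pd

        scores = self.importance(mode)
        order = np.lexsort((np.arange(scores.size), -scores))
        frame = pd.DataFrame(
            {
                "variant_id": [self.model.genotypes.variant_ids[i] for i in order],
                "importance": scores[order],
            }
        )
        frame["rank"] = np.arange(1, scores.size + 1)
        return frame

    # -- prediction / OOB ---------------------------------------------------

    def predict(self, matrix: GenotypeMatrix | None = None) -> np.ndarray:
        """Majority-vote class prediction (ties to the lowest class index)."""
        values = (matrix or self.model.genotypes).values
        n = values.shape[0]
        votes = np.zeros((n, self.model.phenotype.n_classes), dtype=np.int64)
        rows = np.arange(n)
        for tree in self.trees:
            pred = _predict_tree(tree, values, rows)
            votes[rows, pred] += 1
        return np.argmax(votes, axis=1)

    @property
    def oob_error_(self) -> float:
        if self._oob_error is None:
            self._oob_error = self._compute_oob()
        return self._oob_error

    def _compute_oob(self) -> float:
        y = self.model.phenotype.labels
        values = self.model.genotypes.values
        n_s = y.size
        votes = np.zeros((n_s, self.model.phenotype.n_classes), dtype=np.int64)
        for tree, in_bag in zip(self.trees, self.in_bag_counts):
            oob_rows = np.nonzero(in_bag == 0)[0]
            if oob_rows.size == 0:
                continue
            pred = _predict_tree(tree, values, oob_rows)
            votes[oob_rows, pred] += 1
        covered = votes.sum(axis=1) > 0
        if not covered.any():
            raise ValueError(
                "no sample is out-of-bag for any tree; OOB error undefined"
            )
        pred = np.argmax(votes[covered], axis=1)  # ties -> lowest class index
        return float(np.mean(pred != y[covered]))

    # -- shape statistics ---------------------------------------------------

    def model_stats(self) -> tuple[float, float]:
        """(average max leaf depth, average non-leaf node count) over trees."""
        return float(self.tree_depths.mean()), float(self.tree_node_counts.mean())

    @property
    def theta(self) -> float:
        """Average train time per tree, in seconds."""
        return self.train_time / self.params.n_tree

    # -- export -------------------------------------------------------------

    def _tree_to_dict(self, root: TreeNode) -> dict:
        # iterative encoding so unlimited-depth trees cannot hit the
        # interpreter recursion limit
        out: dict = {}
        stack = [(root, out)]
        while stack:
            node, slot = stack.pop()
            slot["node_id"] = node.node_id
            slot["size"] = node.n_samples
            slot["depth"] = node.depth
            if node.is_leaf:
                slot["leaf_class"] = node.leaf_class
            else:
                slot.update(
                    variant=node.split.variant_index,
                    variant_id=self.model.genotypes.variant_ids[
                        node.split.variant_index
                    ],
                    threshold=node.split.threshold,
                    gain=node.split.gain,
                )
                slot["left"], slot["right"] = {}, {}
                stack.append((node.right, slot["right"]))
                stack.append((node.left, slot["left"]))
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        """Model export: params, per-tree shape stats, nested nodes, importance."""
        avg_depth, avg_nodes = self.model_stats()
        # batch size and blocking are execution provenance, not part of the
        # model: exports from any run configuration compare equal.
        try:
            oob = self.oob_error_
        except ValueError:
            oob = None
        doc = {
            "params": {
                "n_tree": self.params.n_tree,
                "m_try": self.params.resolve_m_try(self.model.genotypes.n_variants),
                "max_depth": self.params.max_depth,
                "min_node_size": self.params.min_node_size,
                "seed": self.params.seed,
            },
            "oob_error": oob,
            "avg_depth": avg_depth,
            "avg_nodes_per_tree": avg_nodes,
            "tree_depths": self.tree_depths.tolist(),
            "tree_node_counts": self.tree_node_counts.tolist(),
            "importance": {
                vid: float(s)
                for vid, s in zip(self.model.genotypes.variant_ids, self.importance_)
                if s > 0
            },
            "trees": [self._tree_to_dict(t) for t in self.trees],
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        """Plain-text fit summary."""
        avg_depth, avg_nodes = self.model_stats()
        m = self.model
        lines = [
            "Random-forest association results",
            "=" * 41,
            f"samples:            {m.genotypes.n_samples}",
            f"variants:           {m.genotypes.n_variants}",
            f"classes:            {', '.join(m.phenotype.class_names)}",
            f"trees:              {self.params.n_tree}",
            f"m_try:              {self.params.resolve_m_try(m.genotypes.n_variants)}",
            f"max depth:          {self.params.max_depth or 'unlimited'}",
            f"min node size:      {self.params.min_node_size or 'unlimited'}",
            f"column blocks:      {len(m.blocks)}",
            f"OOB error:          {self.oob_error_:.4f}",
            f"avg tree depth:     {avg_depth:.2f}",
            f"avg split nodes:    {avg_nodes:.2f}",
            "-" * 41,
            "top variants by importance:",
        ]
        frame = self.importance_frame().head(10)
        for _, row in frame.iterrows():
            lines.append(
                f"  {row['rank']:>4d}  {row['variant_id']:<24s} {row['importance']:.6f}"
            )
        return "\n".join(lines)

    def plot_importance(self, top: int = 20, ax=None):
        """Bar plot of the top-ranked variants (requires matplotlib)."""
        import matplotlib.pyplot as plt

        frame = self.importance_frame().head(top)[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * top + 1))
        ax.barh(frame["variant_id"], frame["importance"])
        ax.set_xlabel("Gini importance")
        ax.set_ylabel("variant")
        return ax


# ---------------------------------------------------------------------------
# functional surface


def train(
    matrix: GenotypeMatrix,
    labels: PhenotypeVector,
    params: ForestParams,
    n_blocks: int = 1,
    n_jobs: int = 1,
    bootstrap: bool = True,
) -> ForestResults:
    """Functional wrapper over :class:`RandomForestGwas` + :meth:`fit`."""
    return RandomForestGwas(matrix, labels, n_blocks=n_blocks).fit(
        params, n_jobs=n_jobs, bootstrap=bootstrap
    )


def oob_error(results: ForestResults) -> float:
    """Out-of-bag misclassification rate of a fitted forest."""
    return results.oob_error_


def importance_scores(results: ForestResults, mode: str = "weighted") -> np.ndarray:
    return results.importance(mode)


def model_stats(results: ForestResults) -> tuple[float, float]:
    return results.model_stats()


def op_count(n_tree: int, n_node: int, m_try: int, n_samples: int) -> int:
    """Operation-count model of the core training loop.

    Training cost is linear in trees x average split nodes per tree x
    candidates per node x samples, since evaluating one candidate at one
    node is a single pass over the node's samples.
    """
    for name, v in [("n_tree", n_tree), ("n_node", n_node), ("m_try", m_try), ("n_samples", n_samples)]:
        if v < 1:
            raise ValueError(f"{name} must be a positive integer")
    return int(n_tree) * int(n_node) * int(m_try) * int(n_samples)


def expected_runtime(beta: float, theta: float, n_tree: int) -> float:
    """Projected wall time: data-load time beta plus n_tree x per-tree time theta."""
    if beta < 0 or theta < 0:
        raise ValueError("beta and theta must be non-negative")
    return beta + n_tree * theta
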