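"""Enrichment-criterion decision-tree induction.

Instead of entropy or Gini, splits are scored by the enrichment factor of
the ≥-side treated as a selected subset: EF = precision / prevalence on
the data reaching the node.  This directly optimises the quantity a
screening-library designer cares about.  Construction stops when a split
would leave a child with fewer than ``min_leaf`` observations (default 5).

A consensus procedure re-fits the tree on k cross-validation training
folds (default 20) and keeps, position by position, the descriptor chosen
by most folds with the modal threshold, exposing minority alternatives in
a per-fold report.

Descriptor preprocessing (zero-variance drop, |r| > 0.9 correlation
grouping keeping the most class-separating member, Welch t-test screen at
p > 0.2) mirrors the usual workflow for culling a large redundant
descriptor block before induction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.model_selection import StratifiedKFold

from .errors import DataError
from .profiler import RuleNode

# ---------------------------------------------------------------------------
# data container


@dataclass
class LabeledTable:
    """Descriptor matrix + binary labels (1 = active)."""

    X: pd.DataFrame
    y: np.ndarray
    ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise DataError("X and y must have equal length")
        if self.X.isna().any().any():
            raise DataError("descriptor table contains missing values")
        if len(np.unique(self.y)) < 2:
            raise DataError("labels must contain both classes")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str, id_col: str | None = None):
        if label_col not in df.columns:
            raise DataError(f"label column {label_col!r} not in table")
        ids = df[id_col].tolist() if id_col else None
        drop = [label_col] + ([id_col] if id_col else [])
        return cls(X=df.drop(columns=drop), y=df[label_col].to_numpy(), ids=ids)

    def subset(self, idx: np.ndarray) -> "LabeledTable":
        ids = [self.ids[i] for i in idx] if self.ids is not None else None
        return LabeledTable(self.X.iloc[idx].reset_index(drop=True), self.y[idx], ids)

    def __len__(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class PreprocessReport:
    dropped_zero_variance: list[str] = field(default_factory=list)
    dropped_correlated: dict[str, str] = field(default_factory=dict)  # dropped -> kept
    dropped_ttest: dict[str, float] = field(default_factory=dict)     # dropped -> p
    kept: list[str] = field(default_factory=list)


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    """Welch two-sample t-test p-value between classes; NaN-safe (→ 1.0)."""
    p = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def preprocess(
    table: LabeledTable, corr_cut: float = 0.9, p_cut: float = 0.2
) -> tuple[LabeledTable, PreprocessReport]:
    """Three-stage descriptor culling.

    1. drop zero-variance columns;
    2. group columns with |Pearson r| > ``corr_cut`` (connected components
       of the correlation graph) and keep the member with the smallest
       Welch t-test p-value between classes;
    3. drop remaining columns whose t-test p-value exceeds ``p_cut``.
    """
    report = PreprocessReport()
    X, y = table.X, table.y
    for col in X.columns:
        if not np.issubdtype(X[col].dtype, np.number):
            raise DataError(f"non-numeric descriptor column {col!r}")

    var = X.var(ddof=0)
    report.dropped_zero_variance = [c for c in X.columns if var[c] == 0]
    X = X.drop(columns=report.dropped_zero_variance)

    cols = list(X.columns)
    if cols:
        corr = np.abs(np.corrcoef(X.to_numpy(), rowvar=False))
        corr = np.atleast_2d(corr)
        adj = csr_matrix((corr > corr_cut).astype(int))
        _, comp = connected_components(adj, directed=False)
        pvals = {c: _welch_p(X[c].to_numpy(dtype=float), y) for c in cols}
        keep = []
        for label in np.unique(comp):
            members = [cols[i] for i in np.flatnonzero(comp == label)]
            rep = min(members, key=lambda c: (pvals[c], members.index(c)))
            keep.append(rep)
            for m in members:
                if m != rep:
                    report.dropped_correlated[m] = rep
        X = X[[c for c in cols if c in set(keep)]]
        for c in list(X.columns):
            if pvals[c] > p_cut:
                report.dropped_ttest[c] = pvals[c]
        X = X.drop(columns=list(report.dropped_ttest))

    report.kept = list(X.columns)
    if not report.kept:
        raise DataError("preprocessing dropped every descriptor")
    return LabeledTable(X.reset_index(drop=True), y, table.ids), report


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitResult:
    threshold: float
    ef: float
    n_selected: int


def best_split(
    values: np.ndarray, labels: np.ndarray, min_count: int = 1
) -> Optional[SplitResult]:
    """Best enrichment-factor threshold for one descriptor.

    Candidate thresholds are midpoints between consecutive sorted distinct
    values; the ≥-side is the selected subset.  Equal EF means equal
    precision, so ties are broken toward the split selecting more
    observations (equal purity, higher recall), hence toward the smaller
    threshold.  Returns None when no candidate enriches (EF ≤ 1),
    when fewer than two distinct values exist, or when no candidate
    respects ``min_count`` on both sides.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(values)
    n_pos = int(labels.sum())
    if n_pos == 0:
        return None
    order = np.argsort(values, kind="mergesort")
    v, yl = values[order], labels[order]
    # suffix positives: tp for a cut at index k is positives in v[k:]
    suffix_pos = np.concatenate([np.cumsum(yl[::-1])[::-1], [0]])
    change = np.flatnonzero(np.diff(v) > 0) + 1  # cut indices k where v[k-1] < v[k]
    if change.size == 0:
        return None
    n_sel = n - change
    ok = (n_sel >= min_count) & (change >= min_count)
    change = change[ok]
    if change.size == 0:
        return None
    n_sel = n - change
    tp = suffix_pos[change]
    prevalence = n_pos / n
    ef = np.where(n_sel > 0, (tp / n_sel) / prevalence, 0.0)
    thresholds = (v[change - 1] + v[change]) / 2.0
    # lexicographic: max ef, then max n_sel (ties go to the wider selection)
    best_idx = max(
        range(len(change)), key=lambda i: (ef[i], n_sel[i], -thresholds[i])
    )
    if ef[best_idx] <= 1.0:
        return None
    return SplitResult(
        threshold=float(thresholds[best_idx]),
        ef=float(ef[best_idx]),
        n_selected=int(n_sel[best_idx]),
    )


# ---------------------------------------------------------------------------
# tree growth


@dataclass
class TreeNode:
    """Internal node (descriptor/threshold) or leaf (label)."""

    n_obs: int
    descriptor: Optional[str] = None
    threshold: Optional[float] = None
    pass_child: Optional["TreeNode"] = None
    fail_child: Optional["TreeNode"] = None
    label: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def to_rule_node(self) -> RuleNode:
        if self.is_leaf:
            return RuleNode(accept=bool(self.label))
        return RuleNode(
            descriptor=self.descriptor,
            threshold=self.threshold,
            pass_child=self.pass_child.to_rule_node(),
            fail_child=self.fail_child.to_rule_node(),
        )


@dataclass
class TrainedTree:
    root: TreeNode
    prevalence: float
    min_leaf: int
    max_depth: int
    seed: Optional[int] = None
    folds: Optional[int] = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(X), dtype=int)
        for i, (_, row) in enumerate(X.iterrows()):
            node = self.root
            while not node.is_leaf:
                node = node.pass_child if row[node.descriptor] >= node.threshold else node.fail_child
            out[i] = node.label
        return out

    def depth(self) -> int:
        def _d(node):
            return 0 if node.is_leaf else 1 + max(_d(node.pass_child), _d(node.fail_child))
        return _d(self.root)

    def internal_nodes(self) -> list[tuple[str, str, float]]:
        """(position path, descriptor, threshold) triples, root path = ''."""
        out = []
        def _walk(node, path):
            if node.is_leaf:
                return
            out.append((path, node.descriptor, node.threshold))
            _walk(node.pass_child, path + "P")
            _walk(node.fail_child, path + "F")
        _walk(self.root, "")
        return out


def grow_tree(table: LabeledTable, min_leaf: int = 5, max_depth: int = 3) -> TrainedTree:
    """Greedy recursive induction with the enrichment criterion.

    At each node the descriptor whose best threshold yields the highest EF
    (on the data reaching the node) is chosen; a split is rejected when
    either child would hold fewer than ``min_leaf`` observations.  Leaves
    are labelled positive when their contained actives are enriched beyond
    the full training table's prevalence (leaf EF > 1).
    """
    prevalence = table.y.mean()

    def leaf(idx: np.ndarray) -> TreeNode:
        frac = table.y[idx].mean() if len(idx) else 0.0
        return TreeNode(n_obs=len(idx), label=int(frac > prevalence))

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        y_here = table.y[idx]
        if depth >= max_depth or len(idx) < 2 * min_leaf or len(np.unique(y_here)) < 2:
            return leaf(idx)
        best: tuple[str, SplitResult] | None = None
        for col in table.X.columns:
            s = best_split(table.X[col].to_numpy(dtype=float)[idx], y_here, min_count=min_leaf)
            if s is None:
                continue
            if best is None or (s.ef, s.n_selected) > (best[1].ef, best[1].n_selected):
                best = (col, s)
        if best is None:
            return leaf(idx)
        col, s = best
        mask = table.X[col].to_numpy(dtype=float)[idx] >= s.threshold
        return TreeNode(
            n_obs=len(idx),
            descriptor=col,
            threshold=s.threshold,
            pass_child=build(idx[mask], depth + 1),
            fail_child=build(idx[~mask], depth + 1),
        )

    root = build(np.arange(len(table)), 0)
    return TrainedTree(root=root, prevalence=float(prevalence),
                       min_leaf=min_leaf, max_depth=max_depth)


# ---------------------------------------------------------------------------
# k-fold consensus


def _modal_value(vals: Sequence[float]) -> float:
    """Mode; ties (including all-distinct) resolve to the median of tied modes."""
    counts = Counter(vals)
    top = max(counts.values())
    tied = sorted(v for v, c in counts.items() if c == top)
    if len(tied) == 1:
        return float(tied[0])
    return float(np.median(tied))


@dataclass
class ConsensusResult:
    tree: TrainedTree
    per_fold: pd.DataFrame          # fold, path, descriptor, threshold
    fold_trees: list[TrainedTree]


def kfold_consensus(
    table: LabeledTable,
    k: int = 20,
    seed: int = 0,
    min_leaf: int = 5,
    max_depth: int = 3,
) -> ConsensusResult:
    """Consensus tree over k stratified cross-validation training folds.

    One tree is grown on each of the k training portions.  Position by
    position (root, then pass/fail children), the descriptor used by the
    majority of contributing folds is kept and its threshold set to the
    modal value across those folds; positions without a majority become
    leaves.  Leaf labels are then assigned by pushing the full table
    through the consensus structure (leaf EF > 1 rule).  The per-fold
    report records every fold's internal nodes so minority descriptor
    choices remain visible.
    """
    n = len(table)
    if k > n:
        raise DataError(f"k={k} exceeds the number of observations ({n})")
    class_min = min(np.bincount(table.y))
    if k > class_min:
        raise DataError(
            f"k={k} exceeds the minority class count ({class_min}); "
            "stratified folds would be empty"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_trees = []
    rows = []
    for fold, (train_idx, _) in enumerate(skf.split(table.X, table.y)):
        t = grow_tree(table.subset(train_idx), min_leaf=min_leaf, max_depth=max_depth)
        fold_trees.append(t)
        for path, desc, thr in t.internal_nodes():
            rows.append({"fold": fold, "path": path, "descriptor": desc, "threshold": thr})
    per_fold = pd.DataFrame(rows, columns=["fold", "path", "descriptor", "threshold"])

    prevalence = table.y.mean()

    def consensus(nodes: list[TreeNode], idx: np.ndarray) -> TreeNode:
        internal = [nd for nd in nodes if not nd.is_leaf]
        def leaf() -> TreeNode:
            frac = table.y[idx].mean() if len(idx) else prevalence
            return TreeNode(n_obs=len(idx), label=int(frac > prevalence))
        if not internal or len(internal) * 2 <= len(nodes):
            return leaf()
        desc_counts = Counter(nd.descriptor for nd in internal)
        top = max(desc_counts.values())
        descriptor = sorted(d for d, c in desc_counts.items() if c == top)[0]
        if top * 2 <= len(nodes):
            return leaf()
        chosen = [nd for nd in internal if nd.descriptor == descriptor]
        threshold = _modal_value([nd.threshold for nd in chosen])
        mask = table.X[descriptor].to_numpy(dtype=float)[idx] >= threshold
        if mask.all() or not mask.any():
            return leaf()
        return TreeNode(
            n_obs=len(idx),
            descriptor=descriptor,
            threshold=threshold,
            pass_child=consensus([nd.pass_child for nd in chosen], idx[mask]),
            fail_child=consensus([nd.fail_child for nd in chosen], idx[~mask]),
        )

    root = consensus([t.root for t in fold_trees], np.arange(n))
    tree = TrainedTree(root=root, prevalence=float(prevalence), min_leaf=min_leaf,
                       max_depth=max_depth, seed=seed, folds=k)
    return ConsensusResult(tree=tree, per_fold=per_fold, fold_trees=fold_trees)


class EnrichmentTree:
    """Thin scikit-learn-flavoured wrapper: fit(X, y) / predict(X).

    ``consensus_folds`` > 0 fits via :func:`kfold_consensus`, otherwise a
    single tree is grown on the full table.
    """

    def __init__(self, min_leaf: int = 5, max_depth: int = 3,
                 consensus_folds: int = 0, seed: int = 0):
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.consensus_folds = consensus_folds
        self.seed = seed
        self.tree_: TrainedTree | None = None
        self.per_fold_: pd.DataFrame | None = None

    def fit(self, X: pd.DataFrame, y) -> "EnrichmentTree":
        table = LabeledTable(X.reset_index(drop=True), np.asarray(y))
        if self.consensus_folds:
            res = kfold_consensus(table, k=self.consensus_folds, seed=self.seed,
                                  min_leaf=self.min_leaf, max_depth=self.max_depth)
            self.tree_, self.per_fold_ = res.tree, res.per_fold
        else:
            self.tree_ = grow_tree(table, min_leaf=self.min_leaf, max_depth=self.max_depth)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.tree_ is None:
            raise DataError("EnrichmentTree is not fitted")
        return self.tree_.predict(X)
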