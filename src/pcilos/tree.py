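"""Tree-structured prognostic classification (TSPC).

Two layers:

* :func:`tspc_classify` — the *published* four-variable rule as a fixed
  total partition: heart failure present -> very high; otherwise age >= 70
  splits by sex (male -> low, female -> moderate); otherwise renal failure
  -> high, else very low.
* a generic binary recursive-partitioning grower for binary endpoints
  (:func:`grow_tree`, Gini splits on midpoint thresholds), weakest-link
  cost-complexity pruning (:func:`prune_ccp`) and V-fold cross-validated
  subtree selection (:func:`cv_select`), with which the published partition
  can be rediscovered from data carrying tree-structured complication risk.

Because the complication endpoint is rare (sub-percent leaf rates), every
subtree predicts the majority class everywhere and 0/1 misclassification
cannot rank subtrees.  Pruning and cross-validation therefore score the
trees as class-probability models, by default with the binomial deviance
(whose per-split statistic is scale-free in the leaf event rate, so weak
true splits in low-rate branches are not outranked by noise splits in
high-rate branches); Gini/Brier and misclassification risk remain
available, the latter for hand-checked textbook examples.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pcilos.schema import RISK_CLASSES, risk_categorical

__all__ = [
    "TreeNode",
    "PrognosticTree",
    "PruneSequence",
    "tspc_classify",
    "tspc_design_matrix",
    "grow_tree",
    "prune_ccp",
    "cv_select",
    "tree_report",
    "leaf_partition",
    "same_partition",
]


# ---------------------------------------------------------------------------
# Published fixed rule
# ---------------------------------------------------------------------------


def tspc_classify(cohort: pd.DataFrame, hf_mode: str = "any") -> pd.Categorical:
    """Route records through the published TSPC rule.

    ``hf_mode`` controls what counts as "heart failure present": ``"any"``
    (default; past or current) or ``"current"``.  Renal failure means
    creatinine >2.5 mg/dL or dialysis.  Ages tie-break to the older branch
    (the question is ``age >= 70``).
    """
    if hf_mode not in ("any", "current"):
        raise ValueError(f"hf_mode must be 'any' or 'current', got {hf_mode!r}")
    hf_levels = ("past", "current") if hf_mode == "any" else ("current",)
    hf = cohort["heart_failure"].isin(hf_levels).to_numpy()
    old = (cohort["age"].to_numpy(float) >= 70.0)
    female = (cohort["sex"] == "female").to_numpy()
    renal = (
        cohort["creatinine_gt_2_5"].astype(bool) | cohort["dialysis"].astype(bool)
    ).to_numpy()
    out = np.select(
        [hf, old & female, old & ~female, renal],
        ["very_high", "moderate", "low", "high"],
        default="very_low",
    )
    return risk_categorical(out)


def tspc_design_matrix(cohort: pd.DataFrame, hf_mode: str = "any") -> pd.DataFrame:
    """The four TSPC questions as a numeric covariate matrix for the grower."""
    hf_levels = ("past", "current") if hf_mode == "any" else ("current",)
    return pd.DataFrame(
        {
            "hf_present": cohort["heart_failure"].isin(hf_levels).astype(float),
            "age": cohort["age"].astype(float),
            "female": (cohort["sex"] == "female").astype(float),
            "renal_failure": (
                cohort["creatinine_gt_2_5"].astype(bool) | cohort["dialysis"].astype(bool)
            ).astype(float),
        },
        index=cohort.index,
    )


# ---------------------------------------------------------------------------
# Generic grower
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """One node: either a binary question (``feature >= threshold`` goes
    right) or a leaf carrying the training event rate."""

    n: int
    n_events: int
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def rate(self) -> float:
        return self.n_events / self.n if self.n else 0.0


@dataclass
class PrognosticTree:
    """A grown or fixed binary prognostic tree over named covariates."""

    root: TreeNode
    feature_names: tuple[str, ...]

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)]
        return np.asarray(X, dtype=float)

    def leaf_index(self, X) -> np.ndarray:
        """Index (in :meth:`leaves` order) of the leaf each record reaches."""
        M = self._matrix(X)
        col = {f: i for i, f in enumerate(self.feature_names)}
        out = np.empty(len(M), dtype=np.int64)
        counter = [0]

        def rec(node: TreeNode, mask: np.ndarray) -> None:
            if node.is_leaf:
                out[mask] = counter[0]
                counter[0] += 1
                return
            go_right = M[mask, col[node.feature]] >= node.threshold
            idx = np.flatnonzero(mask)
            left_mask = np.zeros(len(M), dtype=bool)
            right_mask = np.zeros(len(M), dtype=bool)
            left_mask[idx[~go_right]] = True
            right_mask[idx[go_right]] = True
            rec(node.left, left_mask)
            rec(node.right, right_mask)

        rec(self.root, np.ones(len(M), dtype=bool))
        return out

    def predict_rate(self, X) -> np.ndarray:
        """Training event rate of the leaf each record reaches."""
        rates = np.array([lf.rate for lf in self.leaves()])
        return rates[self.leaf_index(X)]

    def classify(self, X) -> np.ndarray:
        """Leaf labels (risk classes, once assigned) per record."""
        labels = np.array([lf.label or "" for lf in self.leaves()], dtype=object)
        return labels[self.leaf_index(X)]

    def assign_risk_labels(self) -> None:
        """Label leaves by training event rate: highest rate -> highest risk.

        With at most five leaves the shared ordered category names are used
        (lowest rate -> very_low); larger trees get ``class_01`` (highest
        risk) downward.
        """
        leaves = self.leaves()
        order = np.argsort([-lf.rate for lf in leaves], kind="stable")
        if len(leaves) <= len(RISK_CLASSES):
            names = list(RISK_CLASSES)[: len(leaves)][::-1]  # highest risk first
        else:
            names = [f"class_{i + 1:02d}" for i in range(len(leaves))]
        for rank, pos in enumerate(order):
            leaves[pos].label = names[rank]

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        nodes: list[dict] = []

        def rec(node: TreeNode) -> int:
            me = len(nodes)
            nodes.append({})
            if node.is_leaf:
                nodes[me] = {
                    "n": node.n,
                    "n_events": node.n_events,
                    "label": node.label,
                }
            else:
                left = rec(node.left)
                right = rec(node.right)
                nodes[me] = {
                    "n": node.n,
                    "n_events": node.n_events,
                    "feature": node.feature,
                    "threshold": node.threshold,
                    "left": left,
                    "right": right,
                }
            return me

        rec(self.root)
        text = json.dumps({"feature_names": list(self.feature_names), "nodes": nodes}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "PrognosticTree":
        data = json.loads(text)
        nodes = data["nodes"]

        def build(i: int) -> TreeNode:
            d = nodes[i]
            if "feature" in d:
                return TreeNode(
                    n=d["n"],
                    n_events=d["n_events"],
                    feature=d["feature"],
                    threshold=d["threshold"],
                    left=build(d["left"]),
                    right=build(d["right"]),
                )
            return TreeNode(n=d["n"], n_events=d["n_events"], label=d.get("label"))

        return cls(root=build(0), feature_names=tuple(data["feature_names"]))

    def render(self) -> str:
        """Plain-text rendering: questions, node sizes and event rates."""
        lines: list[str] = []

        def rec(node: TreeNode, prefix: str, answer: str) -> None:
            if node.is_leaf:
                lab = f" [{node.label}]" if node.label else ""
                lines.append(
                    f"{prefix}{answer}leaf n={node.n} rate={node.rate:.4f}{lab}"
                )
                return
            lines.append(
                f"{prefix}{answer}{node.feature} >= {node.threshold:g}?"
                f" (n={node.n}, rate={node.rate:.4f})"
            )
            rec(node.left, prefix + "  ", "no:  ")
            rec(node.right, prefix + "  ", "yes: ")

        rec(self.root, "", "")
        return "\n".join(lines)


def _best_split(
    x: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[float, float] | None:
    """Best Gini split of one feature: (impurity decrease, threshold).

    Thresholds are midpoints between consecutive distinct values; the
    lowest threshold wins ties exactly.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    n = len(xs)
    boundaries = np.flatnonzero(xs[:-1] != xs[1:])  # split after position b
    if len(boundaries) == 0:
        return None
    n_left = boundaries + 1
    n_right = n - n_left
    ok = (n_left >= min_leaf) & (n_right >= min_leaf)
    if not ok.any():
        return None
    boundaries = boundaries[ok]
    n_left = n_left[ok]
    n_right = n_right[ok]
    e = np.cumsum(ys)
    e_left = e[boundaries]
    e_tot = e[-1]
    e_right = e_tot - e_left
    # Gini cost of a group with n records, e events: 2 e (n - e) / n
    cost_parent = 2.0 * e_tot * (n - e_tot) / n
    cost = 2.0 * e_left * (n_left - e_left) / n_left + 2.0 * e_right * (
        n_right - e_right
    ) / n_right
    delta = cost_parent - cost
    k = int(np.argmax(delta))  # first occurrence -> lowest threshold on ties
    if delta[k] <= 1e-12:
        return None
    b = boundaries[k]
    thr = (xs[b] + xs[b + 1]) / 2.0
    return float(delta[k]), thr


def grow_tree(
    X,
    y,
    min_leaf: int = 50,
    max_depth: int | None = None,
    feature_names: tuple[str, ...] | None = None,
) -> PrognosticTree:
    """Grow a binary classification tree by greedy Gini splitting.

    Continuous covariates are searched over midpoints between sorted
    distinct values; growth stops at node homogeneity, ``min_leaf`` or
    ``max_depth``.  Ties in impurity decrease break to the lower covariate
    index, then the lower threshold, so growth is deterministic.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if feature_names is None:
            feature_names = tuple(f"x{i}" for i in range(M.shape[1]))
    y = np.asarray(y).astype(np.int64).ravel()
    if len(M) == 0:
        raise ValueError("cannot grow a tree on empty data")
    if len(y) != len(M):
        raise ValueError("X and y must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        n = len(idx)
        e = int(y[idx].sum())
        node = TreeNode(n=n, n_events=e)
        if e in (0, n) or n < 2 * min_leaf or (max_depth is not None and depth >= max_depth):
            return node
        best: tuple[float, int, float] | None = None
        for j in range(M.shape[1]):
            res = _best_split(M[idx, j], y[idx], min_leaf)
            if res is None:
                continue
            delta, thr = res
            if best is None or delta > best[0] + 1e-12:
                best = (delta, j, thr)
        if best is None:
            return node
        _, j, thr = best
        go_right = M[idx, j] >= thr
        node.feature = feature_names[j]
        node.threshold = thr
        node.left = build(idx[~go_right], depth + 1)
        node.right = build(idx[go_right], depth + 1)
        return node

    return PrognosticTree(root=build(np.arange(len(M)), 0), feature_names=feature_names)


# ---------------------------------------------------------------------------
# Cost-complexity pruning
# ---------------------------------------------------------------------------


@dataclass
class PruneSequence:
    """Nested subtree sequence from weakest-link pruning.

    ``alphas`` are the complexity parameters at which each subtree becomes
    optimal (ascending; first is 0 for the full tree, last corresponds to
    the root-only tree).  ``cv_risk``/``cv_se`` are filled by
    :func:`cv_select`.
    """

    alphas: list[float]
    trees: list[PrognosticTree]
    risk_measure: str = "gini"
    cv_risk: list[float] | None = None
    cv_se: list[float] | None = None

    def subtree_for(self, alpha: float) -> PrognosticTree:
        """Subtree optimal at complexity ``alpha`` (largest alphas[k] <= alpha)."""
        k = int(np.searchsorted(np.asarray(self.alphas), alpha, side="right")) - 1
        return self.trees[max(k, 0)]


def _node_risk(node: TreeNode, n_total: int, measure: str) -> float:
    if measure == "deviance":
        e, n = node.n_events, node.n
        out = 0.0
        if 0 < e:
            out -= e * np.log(e / n)
        if e < n:
            out -= (n - e) * np.log(1.0 - e / n)
        return out / n_total
    if measure == "gini":
        return 2.0 * node.n_events * (node.n - node.n_events) / node.n / n_total
    if measure == "misclassification":
        return min(node.n_events, node.n - node.n_events) / n_total
    raise ValueError(f"unknown risk measure {measure!r}")


def _cv_loss(p: np.ndarray, y: np.ndarray, measure: str) -> np.ndarray:
    """Held-out per-record loss matching a node risk measure."""
    if measure == "deviance":
        p = np.clip(p, 1e-6, 1.0 - 1e-6)
        return -(y * np.log(p) + (1 - y) * np.log1p(-p))
    if measure == "gini":
        return (p - y) ** 2
    if measure == "misclassification":
        return ((p >= 0.5).astype(float) != y).astype(float)
    raise ValueError(f"unknown risk measure {measure!r}")


def prune_ccp(tree: PrognosticTree, risk_measure: str = "deviance") -> PruneSequence:
    """Weakest-link cost-complexity pruning.

    Repeatedly collapses the internal node(s) with the smallest
    ``g(t) = (R(t) - R(T_t)) / (|leaves(T_t)| - 1)`` until only the root
    remains, recording the full nested sequence with its alpha values.
    ``risk_measure`` is the resubstitution risk R: ``"deviance"`` (default;
    the binomial log-likelihood, whose split statistic is scale-free in the
    leaf rate and therefore ranks weak true splits above noise splits in
    high-rate branches), ``"gini"``, or ``"misclassification"`` (the
    classic textbook choice, hand-checkable).
    """
    current = copy.deepcopy(tree)
    n_total = current.root.n
    alphas = [0.0]
    trees = [copy.deepcopy(current)]

    def subtree_stats(node: TreeNode) -> tuple[float, int]:
        if node.is_leaf:
            return _node_risk(node, n_total, risk_measure), 1
        rl, ll = subtree_stats(node.left)
        rr, lr = subtree_stats(node.right)
        return rl + rr, ll + lr

    while not current.root.is_leaf:
        links: list[tuple[float, TreeNode]] = []

        def collect(node: TreeNode) -> None:
            if node.is_leaf:
                return
            r_sub, n_leaves = subtree_stats(node)
            g = (_node_risk(node, n_total, risk_measure) - r_sub) / (n_leaves - 1)
            links.append((g, node))
            collect(node.left)
            collect(node.right)

        collect(current.root)
        g_min = min(g for g, _ in links)
        # collapse every weakest link still present (ancestors first: a
        # collapsed ancestor removes its descendants from the tree)
        for g, node in links:
            if g <= g_min + 1e-12 and not node.is_leaf:
                node.feature = None
                node.threshold = None
                node.left = None
                node.right = None
        alpha = max(g_min, 0.0)
        if alpha <= alphas[-1] + 1e-15:
            # zero-gain (or tied) links belong to the previous level: keep
            # the alpha sequence strictly increasing
            trees[-1] = copy.deepcopy(current)
        else:
            alphas.append(alpha)
            trees.append(copy.deepcopy(current))
    return PruneSequence(alphas=alphas, trees=trees, risk_measure=risk_measure)


# ---------------------------------------------------------------------------
# Cross-validated selection
# ---------------------------------------------------------------------------


def _stratified_folds(y: np.ndarray, X: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Outcome-stratified fold assignment, invariant to record order.

    Records are ranked by their full (covariates, outcome) tuple before the
    seeded shuffle, so permuting the input rows permutes the assignment
    identically; identical records are interchangeable.
    """
    if folds >= len(y):  # leave-one-out: stratification is vacuous
        return np.arange(len(y), dtype=np.int64)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=np.int64)
    order = np.lexsort(tuple(X.T) + (y,))
    for cls in (0, 1):
        idx = order[y[order] == cls]
        perm = rng.permutation(len(idx))
        fold[idx] = perm % folds
    return fold


def cv_select(
    X,
    y,
    folds: int = 10,
    rule: str = "one_se",
    seed: int = 0,
    min_leaf: int = 50,
    max_depth: int | None = None,
    risk_measure: str = "deviance",
) -> tuple[PrognosticTree, PruneSequence]:
    """Grow, prune and select a subtree by V-fold cross-validation.

    The full-data prune sequence is evaluated at the geometric-midpoint
    alphas; each fold grows and prunes its own tree and contributes a
    held-out per-record loss matched to ``risk_measure`` (log loss for
    deviance, Brier for gini, error rate for misclassification) on its
    leaf event rates.  ``rule="min_risk"`` picks the risk-minimising
    subtree; ``rule="one_se"`` (default) the smallest subtree within one
    standard error of the minimum.  Fold assignment is stratified by
    outcome and deterministic under ``seed``.

    Returns the selected subtree (risk labels assigned) and the full-data
    :class:`PruneSequence` with CV risks attached.
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = tuple(f"x{i}" for i in range(M.shape[1]))
    y = np.asarray(y).astype(np.int64).ravel()
    if len(y) < folds:
        raise ValueError(f"need n >= folds, got n={len(y)}, folds={folds}")
    if rule not in ("min_risk", "one_se"):
        raise ValueError(f"rule must be 'min_risk' or 'one_se', got {rule!r}")

    Xf = pd.DataFrame(M, columns=names)
    full = grow_tree(Xf, y, min_leaf=min_leaf, max_depth=max_depth)
    seq = prune_ccp(full, risk_measure=risk_measure)
    K = len(seq.alphas)
    if K == 1:
        tree = seq.trees[0]
        tree.assign_risk_labels()
        seq.cv_risk = [float(_cv_loss(tree.predict_rate(Xf), y, risk_measure).mean())]
        seq.cv_se = [0.0]
        return tree, seq

    rep = np.empty(K)
    for k in range(K - 1):
        a, b = seq.alphas[k], seq.alphas[k + 1]
        rep[k] = np.sqrt(a * b) if a > 0 else b / 2.0
    rep[K - 1] = seq.alphas[-1]

    fold_of = _stratified_folds(y, M, folds, seed)
    sq_err = np.zeros((K, len(y)))
    for f in range(folds):
        test = fold_of == f
        train = ~test
        t_full = grow_tree(Xf.loc[train], y[train], min_leaf=min_leaf, max_depth=max_depth)
        t_seq = prune_ccp(t_full, risk_measure=risk_measure)
        Xt = Xf.loc[test]
        for k in range(K):
            sub = t_seq.subtree_for(rep[k])
            sq_err[k, test] = _cv_loss(sub.predict_rate(Xt), y[test], risk_measure)

    risks = sq_err.mean(axis=1)
    k_min = int(np.argmin(risks))
    # the one-SE band uses the SE of the *paired* risk difference against
    # the minimiser: subtrees share most of their predictions, so the
    # unpaired SE of the risk itself would swallow real but small splits
    # (rare events make Brier improvements tiny relative to Brier noise)
    diffs = sq_err - sq_err[k_min]
    ses = diffs.std(axis=1, ddof=1) / np.sqrt(len(y))
    seq.cv_risk = [float(r) for r in risks]
    seq.cv_se = [float(s) for s in ses]
    if rule == "min_risk":
        k_sel = k_min
    else:
        ok = [k for k in range(K) if risks[k] <= risks[k_min] + ses[k]]
        k_sel = max(ok)
    selected = copy.deepcopy(seq.trees[k_sel])
    selected.assign_risk_labels()
    return selected, seq


# ---------------------------------------------------------------------------
# Reporting and partition comparison
# ---------------------------------------------------------------------------


def tree_report(labels, los) -> pd.DataFrame:
    """Per-leaf/class counts and mean LOS (the tree-annotation summary)."""
    df = pd.DataFrame({"class": np.asarray(labels, dtype=object), "los": np.asarray(los)})
    out = (
        df.groupby("class", observed=True)["los"]
        .agg(n="count", mean_los="mean", sd_los="std")
        .reset_index()
    )
    order = {c: i for i, c in enumerate(RISK_CLASSES)}
    out["__o"] = out["class"].map(lambda c: order.get(c, len(order)))
    out = out.sort_values(["__o", "class"]).drop(columns="__o").reset_index(drop=True)
    return out


def leaf_partition(labels) -> dict:
    """Canonical form of a record partition: frozenset of record-index blocks."""
    labels = np.asarray(labels, dtype=object)
    return frozenset(
        frozenset(np.flatnonzero(labels == v).tolist()) for v in pd.unique(labels)
    )


def same_partition(labels_a, labels_b) -> bool:
    """Whether two labelings induce the same partition of the records."""
    return leaf_partition(labels_a) == leaf_partition(labels_b)
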