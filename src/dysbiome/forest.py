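"""Class-weighted random-forest classification with OOB evaluation,
Gini importance, ROC/PR curves, and label-permutation significance.

The forest follows cost-sensitive CART semantics: per-class weights
enter both the Gini split criterion and leaf voting, trees are grown
to purity or exhaustion, and candidate features are a uniform sample
of ``mtry`` columns per node.  Evaluation is out-of-bag: each sample
is scored by the fraction of trees in which it was out-of-bag that
vote for the positive ("responder") class.  Two sampling modes are
supported: a plain bootstrap of all samples (with inverse-class-size
weights doing the balancing) and a balanced subsample drawing a fixed
number of samples per class per tree with replacement.

The tree grower is compiled with numba because permutation calibration
refits the entire forest for every label shuffle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .containers import ValidationError

log = logging.getLogger("dysbiome")

__all__ = [
    "ForestConfig",
    "ForestModel",
    "ClassifierReport",
    "grow_forest",
    "oob_report",
    "roc_auc",
    "precision_recall",
    "gini_importance",
    "permutation_significance",
]

WEIGHTED_BOOTSTRAP = 0
BALANCED_SUBSAMPLE = 1


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    ``mtry=None`` means floor(sqrt(p)).  ``sampling`` is
    ``weighted_full_bootstrap`` (bootstrap of all n samples, class
    imbalance handled by inverse-class-size weights) or
    ``balanced_subsample`` (``n_per_class`` draws per class per tree,
    with replacement; ``None`` means the minority class size).
    """

    n_trees: int = 25001
    mtry: int | None = None
    sampling: str = "weighted_full_bootstrap"
    n_per_class: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.sampling not in ("weighted_full_bootstrap",
                                 "balanced_subsample"):
            raise ValidationError(f"unknown sampling {self.sampling!r}")


@njit(cache=False)
def _grow_forest_kernel(X, y, n_trees, mtry, w0, w1, mode, n_per_class, seed):
    """Grow a class-weighted forest; return OOB vote tallies, OOB
    counts, summed Gini importance, and per-tree split counts."""
    np.random.seed(seed)
    n, p = X.shape
    oob_pos = np.zeros(n, dtype=np.float64)   # trees voting class 1
    oob_cnt = np.zeros(n, dtype=np.int64)     # trees where sample is OOB
    importance = np.zeros(p, dtype=np.float64)

    idx0 = np.empty(n, dtype=np.int64)
    idx1 = np.empty(n, dtype=np.int64)
    n0 = 0
    n1 = 0
    for i in range(n):
        if y[i] == 0:
            idx0[n0] = i
            n0 += 1
        else:
            idx1[n1] = i
            n1 += 1

    bag_size = n if mode == 0 else 2 * n_per_class
    max_nodes = 2 * bag_size + 3
    feat = np.empty(max_nodes, dtype=np.int64)
    thr = np.empty(max_nodes, dtype=np.float64)
    left = np.empty(max_nodes, dtype=np.int64)
    right = np.empty(max_nodes, dtype=np.int64)
    leafc = np.empty(max_nodes, dtype=np.int8)

    bag = np.empty(bag_size, dtype=np.int64)
    inbag = np.zeros(n, dtype=np.bool_)
    samples = np.empty(bag_size, dtype=np.int64)
    node_start = np.empty(max_nodes, dtype=np.int64)
    node_end = np.empty(max_nodes, dtype=np.int64)
    stack = np.empty(max_nodes, dtype=np.int64)
    cand = np.empty(p, dtype=np.int64)
    vals = np.empty(bag_size, dtype=np.float64)
    order = np.empty(bag_size, dtype=np.int64)

    for _tree in range(n_trees):
        # ---- draw the bag -------------------------------------------------
        if mode == 0:
            for k in range(n):
                bag[k] = np.random.randint(0, n)
        else:
            for k in range(n_per_class):
                bag[k] = idx0[np.random.randint(0, n0)]
            for k in range(n_per_class):
                bag[n_per_class + k] = idx1[np.random.randint(0, n1)]
        for i in range(n):
            inbag[i] = False
        for k in range(bag_size):
            inbag[bag[k]] = True
            samples[k] = bag[k]

        # ---- grow the tree (stack of nodes over a partitioned index array)
        n_nodes = 1
        node_start[0] = 0
        node_end[0] = bag_size
        stack[0] = 0
        top = 1
        while top > 0:
            top -= 1
            node = stack[top]
            s = node_start[node]
            e = node_end[node]
            c0 = 0
            c1 = 0
            for k in range(s, e):
                if y[samples[k]] == 0:
                    c0 += 1
                else:
                    c1 += 1
            nw0 = w0 * c0
            nw1 = w1 * c1
            nw = nw0 + nw1
            if c0 == 0 or c1 == 0 or e - s < 2:
                feat[node] = -1
                leafc[node] = 1 if nw1 >= nw0 else 0
                continue
            gini_parent = 1.0 - (nw0 * nw0 + nw1 * nw1) / (nw * nw)

            # sample mtry distinct candidate features (partial Fisher-Yates)
            for j in range(p):
                cand[j] = j
            m = mtry if mtry < p else p
            for j in range(m):
                r = j + np.random.randint(0, p - j)
                tmp = cand[j]
                cand[j] = cand[r]
                cand[r] = tmp
            # sort candidates ascending so ties break to lowest feature index
            for a in range(1, m):
                key = cand[a]
                b = a - 1
                while b >= 0 and cand[b] > key:
                    cand[b + 1] = cand[b]
                    b -= 1
                cand[b + 1] = key

            best_gain = 0.0
            best_f = -1
            best_thr = 0.0
            for ci in range(m):
                f = cand[ci]
                msz = e - s
                for k in range(msz):
                    vals[k] = X[samples[s + k], f]
                    order[k] = s + k
                # insertion sort of (vals, order) on vals
                for a in range(1, msz):
                    kv = vals[a]
                    ko = order[a]
                    b = a - 1
                    while b >= 0 and vals[b] > kv:
                        vals[b + 1] = vals[b]
                        order[b + 1] = order[b]
                        b -= 1
                    vals[b + 1] = kv
                    order[b + 1] = ko
                l0 = 0.0
                l1 = 0.0
                for k in range(msz - 1):
                    if y[samples[order[k]]] == 0:
                        l0 += w0
                    else:
                        l1 += w1
                    if vals[k + 1] > vals[k]:
                        lw = l0 + l1
                        r0 = nw0 - l0
                        r1 = nw1 - l1
                        rw = r0 + r1
                        gini_l = 1.0 - (l0 * l0 + l1 * l1) / (lw * lw)
                        gini_r = 1.0 - (r0 * r0 + r1 * r1) / (rw * rw)
                        gain = nw * gini_parent - lw * gini_l - rw * gini_r
                        if gain > best_gain + 1e-12:
                            best_gain = gain
                            best_f = f
                            best_thr = 0.5 * (vals[k] + vals[k + 1])
            if best_f < 0:
                feat[node] = -1
                leafc[node] = 1 if nw1 >= nw0 else 0
                continue

            # partition samples[s:e] around the split
            i_lo = s
            i_hi = e - 1
            while i_lo <= i_hi:
                if X[samples[i_lo], best_f] <= best_thr:
                    i_lo += 1
                else:
                    tmp = samples[i_lo]
                    samples[i_lo] = samples[i_hi]
                    samples[i_hi] = tmp
                    i_hi -= 1
            split_at = i_lo
            feat[node] = best_f
            thr[node] = best_thr
            importance[best_f] += best_gain
            lnode = n_nodes
            rnode = n_nodes + 1
            n_nodes += 2
            left[node] = lnode
            right[node] = rnode
            node_start[lnode] = s
            node_end[lnode] = split_at
            node_start[rnode] = split_at
            node_end[rnode] = e
            stack[top] = lnode
            top += 1
            stack[top] = rnode
            top += 1

        # ---- OOB votes ----------------------------------------------------
        for i in range(n):
            if not inbag[i]:
                node = 0
                while feat[node] >= 0:
                    if X[i, feat[node]] <= thr[node]:
                        node = left[node]
                    else:
                        node = right[node]
                oob_cnt[i] += 1
                if leafc[node] == 1:
                    oob_pos[i] += 1.0

    return oob_pos, oob_cnt, importance


@dataclass
class ForestModel:
    """A fitted forest: OOB responder-vote fractions per sample, mean
    Gini importance per feature, and the configuration used."""

    oob_votes: np.ndarray          # fraction of OOB trees voting responder
    oob_counts: np.ndarray         # number of trees where sample was OOB
    importance: np.ndarray         # mean decrease in class-weighted Gini
    feature_names: list[str]
    class_weights: tuple[float, float]
    config: ForestConfig
    n_samples: int
    mtry_used: int = 0


def default_mtry(p: int) -> int:
    return max(1, int(math.floor(math.sqrt(p))))


def grow_forest(
    X: np.ndarray,
    y: np.ndarray,
    config: ForestConfig = ForestConfig(),
    feature_names: list[str] | None = None,
) -> ForestModel:
    """Fit a class-weighted forest on features ``X`` and binary labels
    ``y`` (1 = responder, the positive class).

    Class weights are the inverse class sizes, normalized so they sum
    to 2; with equal classes both weights are 1 and the criterion
    reduces to plain Gini.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    y = np.asarray(y).astype(np.int8)
    n, p = X.shape
    if n < 4:
        raise ValidationError("need at least 4 samples")
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValidationError("both classes must be present")
    mtry = config.mtry if config.mtry is not None else default_mtry(p)
    if mtry > p:
        log.warning("mtry=%d exceeds p=%d; clamped", mtry, p)
        mtry = p
    w0 = (1.0 / n0)
    w1 = (1.0 / n1)
    scale = 2.0 / (w0 + w1)
    w0 *= scale
    w1 *= scale
    mode = (WEIGHTED_BOOTSTRAP if config.sampling == "weighted_full_bootstrap"
            else BALANCED_SUBSAMPLE)
    npc = config.n_per_class if config.n_per_class is not None else min(n0, n1)
    if mode == BALANCED_SUBSAMPLE and npc < 1:
        raise ValidationError("n_per_class must be >= 1")
    oob_pos, oob_cnt, imp = _grow_forest_kernel(
        X, y, config.n_trees, mtry, w0, w1, mode, npc,
        config.seed & 0x7FFFFFFF)
    never_oob = int((oob_cnt == 0).sum())
    if never_oob:
        log.warning("%d samples were never out-of-bag; increase n_trees",
                    never_oob)
    with np.errstate(invalid="ignore", divide="ignore"):
        votes = np.where(oob_cnt > 0, oob_pos / np.maximum(oob_cnt, 1), np.nan)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    return ForestModel(
        oob_votes=votes, oob_counts=oob_cnt,
        importance=imp / config.n_trees,
        feature_names=list(feature_names),
        class_weights=(w0, w1), config=config, n_samples=n,
        mtry_used=mtry,
    )


@dataclass
class ClassifierReport:
    confusion: np.ndarray          # rows = true class (0,1), cols = predicted
    accuracy: float
    per_class_error: np.ndarray
    n_evaluated: int


def oob_report(model: ForestModel, y: np.ndarray) -> ClassifierReport:
    """OOB confusion matrix and accuracy.

    Predicted class is responder iff the OOB vote fraction is >= 0.5
    (a tie votes for the rarer responder class).  Samples never OOB
    are excluded with a warning.
    """
    y = np.asarray(y).astype(int)
    votes = model.oob_votes
    usable = np.isfinite(votes)
    if not usable.all():
        log.warning("excluding %d never-OOB samples from the report",
                    int((~usable).sum()))
    y_u = y[usable]
    pred = (votes[usable] >= 0.5).astype(int)
    confusion = np.zeros((2, 2), dtype=int)
    for t, q in zip(y_u, pred):
        confusion[t, q] += 1
    n_eval = int(usable.sum())
    accuracy = float(np.trace(confusion)) / n_eval if n_eval else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        row_sums = confusion.sum(axis=1)
        per_class_error = np.where(
            row_sums > 0,
            1.0 - np.diag(confusion) / np.maximum(row_sums, 1),
            np.nan,
        )
    return ClassifierReport(confusion=confusion, accuracy=accuracy,
                            per_class_error=per_class_error,
                            n_evaluated=n_eval)


def roc_auc(scores: np.ndarray, y: np.ndarray
            ) -> tuple[np.ndarray, float]:
    """ROC points over all score thresholds and the AUC by the
    rank (Mann-Whitney) formula with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValidationError("both classes needed for a ROC curve")
    from scipy.stats import rankdata
    ranks = rankdata(scores)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)

    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    # collapse threshold ties: keep last point of each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    points = np.column_stack([
        np.r_[0.0, fps[distinct] / n0],
        np.r_[0.0, tps[distinct] / n1],
    ])
    return points, float(auc)


def precision_recall(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Precision-recall points over all score thresholds (positive
    class = responder)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n1 = int(y.sum())
    if n1 == 0:
        raise ValidationError("no positive samples")
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    preds = np.arange(1, len(ys) + 1)
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    recall = tps[distinct] / n1
    precision = tps[distinct] / preds[distinct]
    return np.column_stack([recall, precision])


def gini_importance(model: ForestModel, top_k: int | None = None
                    ) -> list[tuple[str, float]]:
    """Features ranked by mean decrease in class-weighted Gini."""
    order = np.argsort(-model.importance, kind="stable")
    ranked = [(model.feature_names[j], float(model.importance[j]))
              for j in order]
    return ranked if top_k is None else ranked[:top_k]


def permutation_significance(
    X: np.ndarray,
    y: np.ndarray,
    statistic: str,
    observed: float,
    n_permutations: int,
    config: ForestConfig,
    rng: np.random.Generator,
) -> float:
    """Label-permutation p-value of an OOB statistic.

    For each permutation the labels are shuffled, the entire forest is
    refit under the same configuration, and the statistic (``accuracy``
    or ``auc``) recomputed; ``p = (1 + #{perm >= observed}) /
    (1 + n_permutations)`` (add-one convention, never exactly 0).
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if statistic not in ("accuracy", "auc"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    y = np.asarray(y).astype(int)
    exceed = 0
    for _ in range(n_permutations):
        y_perm = rng.permutation(y)
        seed = int(rng.integers(0, 2 ** 31 - 1))
        model = grow_forest(X, y_perm, ForestConfig(
            n_trees=config.n_trees, mtry=config.mtry,
            sampling=config.sampling, n_per_class=config.n_per_class,
            seed=seed))
        if statistic == "accuracy":
            stat = oob_report(model, y_perm).accuracy
        else:
            usable = np.isfinite(model.oob_votes)
            _, stat = roc_auc(model.oob_votes[usable], y_perm[usable])
        if stat >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)
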