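"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive pair counting, O(n^2)
scans) and shares no code with the package.
"""

import numpy as np


def oracle_metrics(y_true, y_pred, y_prob, classes, averaging, positive=None):
    """Metric definitions computed from first principles."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = list(classes)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)

    def class_recall(c):
        idx = [i for i, t in enumerate(y_true) if t == c]
        return sum(y_pred[i] == c for i in idx) / len(idx)

    def class_precision(c):
        idx = [i for i, p in enumerate(y_pred) if p == c]
        if not idx:
            return 0.0
        return sum(y_true[i] == c for i in idx) / len(idx)

    def pair_auc(labels01, scores):
        """Exhaustive concordant/discordant pair count (ties worth 1/2)."""
        pos = [s for l, s in zip(labels01, scores) if l == 1]
        neg = [s for l, s in zip(labels01, scores) if l == 0]
        total = 0.0
        for sp in pos:
            for sn in neg:
                if sp > sn:
                    total += 1.0
                elif sp == sn:
                    total += 0.5
        return total / (len(pos) * len(neg))

    if averaging == "binary":
        pos = positive if positive is not None else classes[-1]
        recall = class_recall(pos) if any(y_true == pos) else 0.0
        precision = class_precision(pos)
        col = classes.index(pos)
        labels01 = (y_true == pos).astype(int)
        if 0 < labels01.sum() < len(labels01):
            auc = pair_auc(labels01, y_prob[:, col])
        else:
            auc = np.nan
        return acc, auc, recall, precision

    recalls, precisions, supports = [], [], []
    aucs, auc_w = [], []
    for j, c in enumerate(classes):
        support = int(np.sum(y_true == c))
        if support == 0:
            continue
        recalls.append(class_recall(c))
        precisions.append(class_precision(c))
        supports.append(support)
        labels01 = (y_true == c).astype(int)
        if 0 < labels01.sum() < len(labels01):
            aucs.append(pair_auc(labels01, y_prob[:, j]))
            auc_w.append(support)
    recall = float(np.average(recalls, weights=supports))
    precision = float(np.average(precisions, weights=supports))
    auc = float(np.average(aucs, weights=auc_w)) if aucs else np.nan
    return acc, auc, recall, precision


def oracle_greedy_selection(X, names, corr_cut):
    """Simulate the keep-first greedy scan with all-pairs correlations."""
    X = np.asarray(X, dtype=float)
    kept = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.std(col) == 0:
            continue
        ok = True
        for i in kept:
            r = np.corrcoef(X[:, i], col)[0, 1]
            if abs(r) > corr_cut:
                ok = False
                break
        if ok:
            kept.append(j)
    return [names[j] for j in kept]


def oracle_knn(Xmin, i, k):
    """Indices of the k nearest minority neighbours of row i (self excluded),
    ties broken by row index."""
    d = np.sqrt(((Xmin - Xmin[i]) ** 2).sum(axis=1))
    order = [j for j in np.argsort(d, kind="stable") if j != i]
    return order[:k]


def on_segment(point, a, b, tol=1e-9):
    """True if `point` lies on the segment [a, b] within residual `tol`."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.linalg.norm(point - a)) < tol
    t = float((point - a) @ ab) / denom
    residual = float(np.linalg.norm(point - (a + t * ab)))
    return residual < tol and -tol <= t <= 1 + tol


def oracle_stump_shap(X, feature, threshold, left_value, right_value):
    """Closed-form SHAP values for a single-split stump.

    With a single binary split, the only non-zero attribution is on the
    split feature and equals leaf_value - expected_value.
    """
    X = np.asarray(X, dtype=float)
    go_left = X[:, feature] <= threshold
    p_left = go_left.mean()
    base = p_left * left_value + (1 - p_left) * right_value
    phi = np.zeros_like(X)
    phi[go_left, feature] = left_value - base
    phi[~go_left, feature] = right_value - base
    return phi, base
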