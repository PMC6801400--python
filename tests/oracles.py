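"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in plain Python (lists, ``math``) on purpose:
no code is shared with the package paths under test.
"""

import math


def zscore_knn_predict(train_rows, train_labels, query_row, k):
    """Plain k-NN with train-fitted z-scoring; ties by training order.

    ``train_rows`` is a list of feature lists; labels are arbitrary
    hashables; returns the majority label among the k nearest.
    """
    n = len(train_rows)
    p = len(train_rows[0])
    means, sds = [], []
    for f in range(p):
        col = [row[f] for row in train_rows]
        mu = sum(col) / n
        var = sum((v - mu) ** 2 for v in col) / (n - 1)
        means.append(mu)
        sds.append(math.sqrt(var) if var > 1e-30 else 1.0)
    dists = []
    for j, row in enumerate(train_rows):
        d = sum(((row[f] - query_row[f]) / sds[f]) ** 2 for f in range(p))
        dists.append((d, j))
    dists.sort()  # ties resolve to lower training index
    votes = {}
    for d, j in dists[:k]:
        votes[train_labels[j]] = votes.get(train_labels[j], 0) + 1
    return max(votes.items(), key=lambda kv: kv[1])[0]


def loocv_accuracy_bruteforce(rows, labels, k):
    """LOOCV accuracy (percent) by explicit per-fold refitting."""
    n = len(rows)
    correct = 0
    for i in range(n):
        train_rows = rows[:i] + rows[i + 1:]
        train_labels = labels[:i] + labels[i + 1:]
        pred = zscore_knn_predict(train_rows, train_labels, rows[i], k)
        if pred == labels[i]:
            correct += 1
    return 100.0 * correct / n


def holdout_accuracy_bruteforce(train_rows, train_labels, val_rows, val_labels, k):
    correct = 0
    for row, lab in zip(val_rows, val_labels):
        if zscore_knn_predict(train_rows, train_labels, row, k) == lab:
            correct += 1
    return 100.0 * correct / len(val_rows)


def posterior_tally(accepted_sets):
    """Frequency of each element over a list of sets, by direct counting."""
    n = len(accepted_sets)
    counts = {}
    for s in accepted_sets:
        for item in set(s):
            counts[item] = counts.get(item, 0) + 1
    return {item: c / n for item, c in counts.items()}


def hypergeom_upper_tail(k, universe, set_size, query_size):
    """P(X >= k) by exact enumeration with integer combinatorics."""
    total = math.comb(universe, query_size)
    acc = 0
    for j in range(k, min(set_size, query_size) + 1):
        if query_size - j > universe - set_size:
            continue
        acc += math.comb(set_size, j) * math.comb(universe - set_size, query_size - j)
    return acc / total


def bh_stepup(p_values):
    """Benjamini-Hochberg q-values from the direct step-up formula."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = p_values[i] * m / rank_from_end
        running_min = min(running_min, val)
        q[i] = min(running_min, 1.0)
    return q
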