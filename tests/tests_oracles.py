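"""Brute-force clustering-metric oracles shared by the test modules.

These are deliberately independent of the package implementation: ARI from
literal pair counting, NMI from contingency counts, and IoU by exhaustive
enumeration of assignments.
"""

import itertools
import math

import numpy as np


def ari_oracle(truth, pred):
    """Pair-counting ARI from the definition."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    n = len(truth)
    a = c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        st = truth[i] == truth[j]
        sp = pred[i] == pred[j]
        if st and sp:
            a += 1
        elif st:
            c += 1
        elif sp:
            d += 1
    n_pairs = math.comb(n, 2)
    sum_t = a + c
    sum_p = a + d
    expected = sum_t * sum_p / n_pairs if n_pairs else 0.0
    max_index = (sum_t + sum_p) / 2
    if max_index == expected:
        return 0.0 if a != max_index else 1.0
    return (a - expected) / (max_index - expected)


def nmi_oracle(truth, pred):
    """MI / arithmetic-mean entropy, from contingency counts."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    n = len(truth)
    mi = 0.0
    for t in np.unique(truth):
        for p in np.unique(pred):
            nij = np.sum((truth == t) & (pred == p))
            if nij == 0:
                continue
            pij = nij / n
            mi += pij * math.log(pij / ((np.sum(truth == t) / n)
                                        * (np.sum(pred == p) / n)))
    def ent(lab):
        return -sum((np.sum(lab == v) / n) * math.log(np.sum(lab == v) / n)
                    for v in np.unique(lab))
    h = (ent(truth) + ent(pred)) / 2
    if h == 0:
        return 1.0 if mi == 0 else mi / h
    return mi / h


def iou_oracle_values(truth, pred):
    """Mean IoUs of every assignment maximising total intersection.

    The Hungarian step optimises total overlap; ties on that objective may
    differ in matched-pair IoU, so the oracle returns the full optimal set.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    t_vals = list(np.unique(truth))
    p_vals = list(np.unique(pred))
    k = len(t_vals)
    padded = p_vals + [None] * k  # dummies: truth classes may stay unmatched
    best_inter = -1
    values = []
    for perm in itertools.permutations(padded, k):
        total = 0.0
        inter_sum = 0
        for t, p in zip(t_vals, perm):
            if p is None:
                continue
            inter = int(np.sum((truth == t) & (pred == p)))
            union = int(np.sum((truth == t) | (pred == p)))
            total += inter / union if union else 0.0
            inter_sum += inter
        if inter_sum > best_inter:
            best_inter = inter_sum
            values = [total / k]
        elif inter_sum == best_inter:
            values.append(total / k)
    return values
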