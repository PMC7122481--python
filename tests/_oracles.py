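"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible — double loops over
pairs, samples and candidate features, direct summation over empirical
joint tables — and deliberately shares no code with the package paths it
verifies.
"""

from __future__ import annotations

import math
from collections import Counter


def order_counts_brute(a, b):
    """(n_gt, n_lt, n_tie, n_missing) of gene vectors a, b across samples."""
    n_gt = n_lt = n_tie = n_miss = 0
    for x, y in zip(a, b):
        if _is_missing(x) or _is_missing(y):
            n_miss += 1
        elif x > y:
            n_gt += 1
        elif x < y:
            n_lt += 1
        else:
            n_tie += 1
    return n_gt, n_lt, n_tie, n_miss


def stable_pairs_brute(gene_ids, values, threshold):
    """{(gene_a, gene_b): direction} over all pairs, gene_a < gene_b.

    A pair is stable-GT iff Ea > Eb in at least threshold of ALL samples
    (inclusive), with a the lexicographically smaller gene.
    """
    n_samples = len(values[0])
    out = {}
    order = sorted(range(len(gene_ids)), key=lambda i: gene_ids[i])
    for ii in range(len(order)):
        for jj in range(ii + 1, len(order)):
            i, j = order[ii], order[jj]
            n_gt, n_lt, _, _ = order_counts_brute(values[i], values[j])
            # integer comparison avoids threshold*n representation error
            if n_gt * 10**9 >= round(threshold * 10**9) * n_samples:
                out[(gene_ids[i], gene_ids[j])] = "GT"
            elif n_lt * 10**9 >= round(threshold * 10**9) * n_samples:
                out[(gene_ids[i], gene_ids[j])] = "LT"
    return out


def encode_brute(matrix_by_gene, sample_count, oriented_pairs):
    """Per-cell ternary encoding: 1 if Ea>Eb, 0 if Ea<Eb or tie, -1 missing."""
    rows = []
    for a, b in oriented_pairs:
        row = []
        for s in range(sample_count):
            ea = matrix_by_gene.get(a, [None] * sample_count)[s]
            eb = matrix_by_gene.get(b, [None] * sample_count)[s]
            if _is_missing(ea) or _is_missing(eb):
                row.append(-1)
            elif ea > eb:
                row.append(1)
            else:
                row.append(0)
        rows.append(row)
    return rows


def mi_brute(x, y):
    """Plug-in discrete mutual information in nats by direct summation."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (xv, yv), c in joint.items():
        p = c / n
        total += p * math.log(p / ((px[xv] / n) * (py[yv] / n)))
    return total


def mrmr_brute(feature_rows, ids, labels):
    """Greedy mRMR (difference form), recomputing every MI term naively.

    First pick maximises I(g, T); each later pick maximises
    I(g, T) - mean over selected s of I(g, s). Ties break on the
    lexicographically smaller id.
    """
    remaining = list(range(len(ids)))
    selected = []
    while remaining:
        best, best_key = None, None
        for i in remaining:
            rel = mi_brute(feature_rows[i], labels)
            if selected:
                red = sum(mi_brute(feature_rows[i], feature_rows[s]) for s in selected)
                obj = rel - red / len(selected)
            else:
                obj = rel
            key = (-obj, ids[i])
            if best_key is None or key < best_key:
                best, best_key = i, key
        selected.append(best)
        remaining.remove(best)
    return [ids[i] for i in selected]


def auc_brute(scores, truth):
    """Mann-Whitney AUC by O(n^2) pairwise comparison, ties at 0.5."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def confusion_brute(pred, truth):
    """(tp, fn, tn, fp) by direct tally over aligned boolean labels."""
    tp = fn = tn = fp = 0
    for p, t in zip(pred, truth):
        if t and p:
            tp += 1
        elif t and not p:
            fn += 1
        elif not t and not p:
            tn += 1
        else:
            fp += 1
    return tp, fn, tn, fp


def _is_missing(v) -> bool:
    return v is None or v != v  # NaN
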