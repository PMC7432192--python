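"""Independent brute-force oracles for the ranking metrics."""

import numpy as np


def pairwise_concordance_auc(scores, labels):
    """O(n^2) Mann-Whitney concordance: ties between a positive and a
    negative score count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def threshold_enumeration_aupr(scores, labels):
    """Step precision-recall area by enumerating every distinct threshold in
    descending order (ties grouped), no interpolation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        kept = scores >= t
        tp = int(labels[kept].sum())
        precision = tp / int(kept.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
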