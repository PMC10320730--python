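"""Shared test utilities (imported by test modules via pytest's rootdir path)."""

import numpy as np

from saelgmda.io_formats import GeneNetwork


def make_network(edges):
    net = GeneNetwork()
    for g1, g2, s in edges:
        net.set_score(g1, g2, s)
    return net


def brute_force_auc(scores, labels):
    """Concordant-pair count with half credit for ties (O(n^2) oracle)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
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
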