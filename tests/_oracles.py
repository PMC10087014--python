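"""Independent brute-force oracles used by the test suite.

Everything here is written with plain loops, straight from the written
rules, and never calls into the package's own implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

NORMAL = "normal"


def naive_children(labels, parents):
    return {
        lab: [l for l, p in zip(labels, parents) if p == lab]
        for lab in list(labels) + [NORMAL]
    }


def naive_is_forest(labels, parents):
    parent_of = dict(zip(labels, parents))
    for start in labels:
        seen = set()
        node = start
        while node != NORMAL:
            if node in seen:
                return False
            seen.add(node)
            node = parent_of[node]
    return True


def naive_unique_ccf(ccf, labels, parents):
    idx = {lab: i for i, lab in enumerate(labels)}
    children = naive_children(labels, parents)
    uccf = np.array(ccf, dtype=float).copy()
    for lab in labels:
        for child in children[lab]:
            uccf[idx[lab]] = uccf[idx[lab]] - np.asarray(ccf)[idx[child]]
    return uccf


def _no_reappearance(row, tol):
    """Once positive and then zero, a trajectory must stay zero."""
    was_positive = False
    gap = False
    for v in row:
        if v > tol:
            if gap:
                return False
            was_positive = True
        elif was_positive:
            gap = True
    return True


def naive_valid(ccf, labels, parents, tol=1e-9):
    """Direct evaluation of the four written validity rules."""
    ccf = np.asarray(ccf, dtype=float)
    idx = {lab: i for i, lab in enumerate(labels)}
    children = naive_children(labels, parents)
    n, m = ccf.shape
    # (i) children cannot exceed their parent
    for lab in labels:
        for t in range(m):
            child_sum = sum(ccf[idx[c], t] for c in children[lab])
            if ccf[idx[lab], t] + tol < child_sum:
                return False
    # (ii) founders cannot add up to more than 100%
    for t in range(m):
        if sum(ccf[idx[c], t] for c in children[NORMAL]) > 100 + tol:
            return False
    # (iii) a clone cannot reappear
    for lab in labels:
        if not _no_reappearance(ccf[idx[lab]], tol):
            return False
    # (iv) a thoroughly replaced parent cannot reappear
    uccf = naive_unique_ccf(ccf, labels, parents)
    for lab in labels:
        if not _no_reappearance(uccf[idx[lab]], tol):
            return False
    return True


def exhaustive_trees(ccf, labels, tol=1e-9):
    """All of the n^n parent vectors that are forests and pass the rules.

    Enumerated lexicographically with NORMAL sorting before the (sorted)
    clone labels, matching the explorer's documented output order.
    """
    options = [
        [NORMAL] + sorted(l for l in labels if l != lab) for lab in labels
    ]
    out = []
    for vector in itertools.product(*options):
        if not naive_is_forest(labels, vector):
            continue
        if naive_valid(ccf, labels, vector, tol):
            out.append(tuple(vector))
    return out
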