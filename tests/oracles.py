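"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths they check: reachability by
per-node depth-first search instead of the package's closure, confusion
counts by a plain python tally, Holm-Bonferroni by literal step-down
enumeration.
"""

from collections import defaultdict

import numpy as np


def dfs_closure(node_ids, edges):
    """Brute-force reachability: per-node DFS over inverted is_a edges.

    ``edges`` are child->parent pairs; returns R aligned to sorted node
    order with R[i, j] = 1 iff j == i or j is a descendant of i.
    """
    order = sorted(node_ids)
    idx = {n: i for i, n in enumerate(order)}
    children = defaultdict(list)
    for child, parent in edges:
        children[parent].append(child)
    r = np.eye(len(order), dtype=np.uint8)
    for node in order:
        stack, seen = [node], set()
        while stack:
            for ch in children[stack.pop()]:
                if ch not in seen:
                    seen.add(ch)
                    stack.append(ch)
        for desc in seen:
            r[idx[node], idx[desc]] = 1
    return r


def random_dag(rng, n_nodes, edge_prob=0.15):
    """A random multi-parent DAG: edges only from later to earlier nodes."""
    nodes = [f"n{i:03d}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(1, n_nodes)
        for j in range(i)
        if rng.random() < edge_prob
    ]
    return nodes, edges


def tally_confusion(preds, truths, reachability, n_classes):
    """Hand tally of the descendant-correct confusion counts."""
    tp = [0] * n_classes
    fp = [0] * n_classes
    fn = [0] * n_classes
    for p, t in zip(preds, truths):
        correct = p == t or reachability[t][p] == 1
        if correct:
            tp[t] += 1
        else:
            fp[p] += 1
            fn[t] += 1
    return tp, fp, fn


def tally_macro_f1(tp, fp, fn, include):
    scores = []
    for i in include:
        prec = tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] else 0.0
        rec = tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] else 0.0
        scores.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return sum(scores) / len(scores)


def holm_stepdown(pvals):
    """Literal Holm-Bonferroni step-down with monotonicity enforcement."""
    pvals = list(pvals)
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_max = 0.0
    for rank, i in enumerate(order):
        candidate = min(1.0, (m - rank) * pvals[i])
        running_max = max(running_max, candidate)
        adjusted[i] = running_max
    return adjusted
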