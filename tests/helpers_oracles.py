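"""Independent oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
package (scalar loops, brute-force enumeration, projected gradient) so that
agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def objective_loops(x, s, graphs, l2, l1, gamma, mode):
    """Scalar-loop evaluation of the self-expressive objective.

    ``graphs`` is a list of (weight, adjacency) pairs; ``mode`` is "W" or "H".
    """
    x = np.asarray(x, float)
    s = np.asarray(s, float)
    n, m = x.shape
    k = s.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(m):
            if mode == "W":
                pred = sum(x[i, v] * s[v, j] for v in range(m))
            else:
                pred = sum(s[i, u] * x[u, j] for u in range(n))
            total += 0.5 * (x[i, j] - pred) ** 2
    for a in range(k):
        for b in range(k):
            total += 0.5 * l2 * s[a, b] ** 2 + l1 * abs(s[a, b])
    for weight, adj in graphs:
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if mode == "W":
                    # columns of S are the smoothed vectors
                    diff = sum((s[r, a] - s[r, b]) ** 2 for r in range(k))
                else:
                    # rows of S are the smoothed vectors
                    diff = sum((s[a, r] - s[b, r]) ** 2 for r in range(k))
                acc += adj[a, b] * diff
        total += 0.5 * weight * acc / 2.0  # sum A||.||^2 = 2 Tr(S L S^T)
    for a in range(k):
        total += gamma * s[a, a]
    return total


def gradient_fd(fun, s, step=1e-6):
    """Central finite-difference gradient of a scalar function of a matrix."""
    s = np.asarray(s, float)
    g = np.zeros_like(s)
    for idx in np.ndindex(*s.shape):
        sp = s.copy()
        sp[idx] += step
        sm = s.copy()
        sm[idx] -= step
        g[idx] = (fun(sp) - fun(sm)) / (2 * step)
    return g


def projected_gradient(x, graphs, l2, l1, gamma, mode, k, steps=100_000, seed=0):
    """Long-run projected gradient descent on the same convex objective.

    Independent optimizer: fixed step 1/L from a conservative Lipschitz
    bound, projection onto the non-negative orthant after every step.
    """
    x = np.asarray(x, float)
    gram = x.T @ x if mode == "W" else x @ x.T
    lips = np.linalg.norm(gram, 2) + l2
    laps = []
    for weight, adj in graphs:
        deg = np.diag(adj.sum(axis=1))
        lap = deg - adj
        laps.append((weight, lap))
        lips += weight * np.linalg.norm(lap, 2)
    eta = 1.0 / lips
    rng = np.random.default_rng(seed)
    s = rng.uniform(0, 0.01, size=(k, k))
    eye = np.eye(k)
    for _ in range(steps):
        if mode == "W":
            grad = gram @ s - gram
            for weight, lap in laps:
                grad = grad + weight * (s @ lap)
        else:
            grad = s @ gram - gram
            for weight, lap in laps:
                grad = grad + weight * (lap @ s)
        grad = grad + l2 * s + l1 + gamma * eye
        s = np.maximum(s - eta * grad, 0.0)
    return s


def auroc_pairs(scores, labels):
    """Brute-force AUROC: P(pos > neg) with ties counting one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def aupr_steps(scores, labels):
    """Step-wise precision-recall integral with tied thresholds grouped."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        picked = scores >= t
        tp = int(labels[picked].sum())
        precision = tp / int(picked.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def bfs_distance(edges, a, b):
    """Edge-count shortest path in an undirected graph given as pair list."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    if a == b:
        return 0
    frontier = {a}
    seen = {a}
    d = 0
    while frontier:
        d += 1
        nxt = set()
        for u in frontier:
            for v in adj.get(u, ()):
                if v == b:
                    return d
                if v not in seen:
                    seen.add(v)
                    nxt.add(v)
        frontier = nxt
    return None


def ranksum_exact_p(group, rest, alternative):
    """Exact one-tailed rank-sum p-value by enumerating all assignments."""
    pooled = list(group) + list(rest)
    n1 = len(group)
    ranks = _midranks(pooled)
    observed = sum(ranks[:n1])
    stats = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        stats.append(sum(ranks[i] for i in comb))
    stats = np.array(stats)
    if alternative == "greater":
        return float(np.mean(stats >= observed - 1e-12))
    return float(np.mean(stats <= observed + 1e-12))


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks
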