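"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with plain Python loops and math-module
arithmetic, deliberately avoiding the vectorized code paths (and, where
possible, the libraries) used by the package itself.
"""

from __future__ import annotations

import math
from itertools import combinations

# ---------------------------------------------------------------------------
# Nearest shrunken centroid
# ---------------------------------------------------------------------------


def nsc_fit_bruteforce(
    X: list[list[float]], labels: list[str], classes: tuple[str, str], delta: float = 0.0
) -> dict:
    """All NSC fit quantities computed gene-by-gene with explicit loops.

    ``X`` is genes x samples (list of rows).
    """
    n = len(labels)
    g = len(X)
    idx = {k: [j for j, l in enumerate(labels) if l == k] for k in classes}
    nk = {k: len(idx[k]) for k in classes}
    xbar = [sum(row) / n for row in X]
    cent = {k: [sum(row[j] for j in idx[k]) / nk[k] for row in X] for k in classes}
    s = []
    for i in range(g):
        ss = 0.0
        for k in classes:
            for j in idx[k]:
                ss += (X[i][j] - cent[k][i]) ** 2
        s.append(math.sqrt(ss / (n - len(classes))))
    s0 = sorted(s)[len(s) // 2] if len(s) % 2 == 1 else (
        (sorted(s)[len(s) // 2 - 1] + sorted(s)[len(s) // 2]) / 2
    )
    mk = {k: math.sqrt(1.0 / nk[k] - 1.0 / n) for k in classes}
    d = {k: [(cent[k][i] - xbar[i]) / (mk[k] * (s[i] + s0)) for i in range(g)] for k in classes}

    def soft(v: float) -> float:
        mag = max(abs(v) - delta, 0.0)
        return math.copysign(mag, v) if mag > 0 else 0.0

    d_shr = {k: [soft(v) for v in d[k]] for k in classes}
    shrunken = {
        k: [xbar[i] + mk[k] * (s[i] + s0) * d_shr[k][i] for i in range(g)] for k in classes
    }
    return {
        "xbar": xbar, "centroids": cent, "s": s, "s0": s0, "mk": mk,
        "d": d, "shrunken": shrunken, "nk": nk,
    }


def nsc_probabilities_bruteforce(
    fit: dict, x: list[float], classes: tuple[str, str], priors: dict[str, float]
) -> dict[str, float]:
    delta_k = {}
    for k in classes:
        acc = 0.0
        for i, xi in enumerate(x):
            acc += (xi - fit["shrunken"][k][i]) ** 2 / (fit["s"][i] + fit["s0"]) ** 2
        delta_k[k] = acc - 2.0 * math.log(priors[k])
    zmax = max(-0.5 * v for v in delta_k.values())
    w = {k: math.exp(-0.5 * delta_k[k] - zmax) for k in classes}
    tot = sum(w.values())
    return {k: w[k] / tot for k in classes}


# ---------------------------------------------------------------------------
# Average-linkage clustering
# ---------------------------------------------------------------------------


def upgma_bruteforce(points: dict[str, list[float]]) -> list[tuple[frozenset, frozenset, float]]:
    """Average-linkage merges computed from the definition: cluster distance
    is the mean of all pairwise point distances between the member sets."""

    def dist(a: str, b: str) -> float:
        return math.sqrt(sum((u - v) ** 2 for u, v in zip(points[a], points[b])))

    clusters: list[frozenset] = [frozenset([l]) for l in points]
    merges = []
    while len(clusters) > 1:
        best = None
        for A, B in combinations(clusters, 2):
            d = sum(dist(a, b) for a in A for b in B) / (len(A) * len(B))
            key = (d, tuple(sorted((min(A), min(B)))))
            if best is None or key < best[0]:
                best = (key, A, B)
        (d, _), A, B = best
        merges.append((A, B, d))
        clusters = [c for c in clusters if c not in (A, B)] + [A | B]
    return merges


# ---------------------------------------------------------------------------
# Hypergeometric upper tail
# ---------------------------------------------------------------------------


def hypergeom_tail_bruteforce(q: int, N: int, K: int, k: int) -> float:
    """P(X >= q) for X ~ Hypergeom(N, K, k) by exhaustive summation over all
    feasible 2x2 tables."""
    total = math.comb(N, k)
    acc = 0
    for j in range(max(q, 0, k - (N - K)), min(K, k) + 1):
        acc += math.comb(K, j) * math.comb(N - K, k - j)
    return acc / total


# ---------------------------------------------------------------------------
# Confusion counting
# ---------------------------------------------------------------------------


def confusion_bruteforce(verdicts: dict[str, str], truth: dict[str, str]) -> dict[str, int]:
    counts = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for chem, v in verdicts.items():
        if truth[chem] == "DDI":
            counts["tp" if v == "DDI" else "fn"] += 1
        else:
            counts["tn" if v == "non-DDI" else "fp"] += 1
    return counts


def zero_fn_cutoff_bruteforce(scores: dict[str, float], labels: dict[str, str]) -> float:
    """Largest threshold with zero false negatives, by enumerating every
    candidate threshold among the observed scores (and one above the max)."""
    candidates = sorted(set(scores.values()))
    candidates.append(max(candidates) + 1.0)
    best = None
    for t in candidates:
        fn = sum(1 for c, s in scores.items() if labels[c] == "DDI" and s < t)
        if fn == 0 and (best is None or t > best):
            best = t
    return best
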