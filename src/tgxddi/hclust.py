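"""Two-dimensional clustering (2-DC): average-linkage agglomeration and the
branch-membership call.

Profiles are clustered with UPGMA (average linkage) on Euclidean distances
between log2 fold-change vectors. The agglomeration is written out here
rather than delegated so that ties between equal merge distances are broken
deterministically: among pairs at the minimal distance, the pair whose
sorted (smallest-member-label, smallest-member-label) key is lexicographically
least is merged first, and a merged node lists its lexicographically smaller
child first. Average linkage is monotone, so merge heights never invert.

The classification rule formalizes "branches with" from the original visual
call: cluster the reference panel together with the single test profile,
walk up from the test leaf to the first ancestor whose complementary subtree
contains at least one reference profile, and call the test after that
subtree's class if it is pure (purity threshold 1.0 by default, configurable
down to a majority rule); a mixed subtree — including joining only at the
root with both classes below — is inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .profiles import DDI, INCONCLUSIVE, NON_DDI, ClassCall, FoldChangeProfile, ReferencePanel

TWODC_ANALYSIS = "2-DC"
DEFAULT_PURITY = 1.0


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration record: n leaves, n-1 merges.

    Leaf node ids are 0..n-1 in ``leaves`` order; the node created by merge
    ``i`` (0-based) has id ``n + i``. Each merge is (left id, right id,
    height), left child holding the lexicographically smaller smallest label.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != max(len(self.leaves) - 1, 0):
            raise ValueError("a dendrogram over n leaves needs exactly n-1 merges")

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def members(self, node: int) -> tuple[str, ...]:
        """Leaf labels under a node id."""
        n = len(self.leaves)
        if node < n:
            return (self.leaves[node],)
        left, right, _ = self.merges[node - n]
        return self.members(left) + self.members(right)

    def parent_of(self, node: int) -> int | None:
        n = len(self.leaves)
        for i, (left, right, _) in enumerate(self.merges):
            if node in (left, right):
                return n + i
        return None

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = len(self.leaves)

        def height(node: int) -> float:
            return 0.0 if node < n else self.merges[node - n][2]

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < n:
                return f"{self.leaves[node]}:{bl:g}"
            left, right, h = self.merges[node - n]
            return f"({render(left, h)},{render(right, h)}):{bl:g}"

        if n == 1:
            return f"{self.leaves[0]}:0;"
        root = n + len(self.merges) - 1
        left, right, h = self.merges[-1]
        return f"({render(left, h)},{render(right, h)});"


def _average_linkage(D: np.ndarray, labels: Sequence[str]) -> Dendrogram:
    """UPGMA over a precomputed distance matrix with label tie-breaking."""
    n = len(labels)
    if len(set(labels)) != n:
        raise ValueError("profile labels must be unique for clustering")
    # active cluster state: node id -> (size, smallest member label, row index)
    dist = D.astype(float).copy()
    active: dict[int, tuple[int, str]] = {i: (1, labels[i]) for i in range(n)}
    row_of = {i: i for i in range(n)}  # node id -> row in dist
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best_key: tuple | None = None
        best_pair: tuple[int, int] | None = None
        ids = sorted(active)
        for a_pos, a in enumerate(ids):
            for b in ids[a_pos + 1:]:
                d = dist[row_of[a], row_of[b]]
                lab = tuple(sorted((active[a][1], active[b][1])))
                key = (d, lab)
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (a, b)
        a, b = best_pair  # type: ignore[misc]
        h = float(best_key[0])  # type: ignore[index]
        if active[b][1] < active[a][1]:
            a, b = b, a  # left child carries the smaller smallest-label
        sa, sb = active[a][0], active[b][0]
        ra, rb = row_of[a], row_of[b]
        # Lance-Williams update for average linkage; reuse row ra for the merger
        new_row = (sa * dist[ra] + sb * dist[rb]) / (sa + sb)
        dist[ra] = new_row
        dist[:, ra] = new_row
        dist[ra, ra] = 0.0
        merges.append((a, b, h))
        lab = min(active[a][1], active[b][1])
        del active[a], active[b], row_of[a], row_of[b]
        active[next_id] = (sa + sb, lab)
        row_of[next_id] = ra
        next_id += 1
    return Dendrogram(leaves=tuple(labels), merges=tuple(merges))


def _profile_matrix(profiles: Sequence[FoldChangeProfile]) -> tuple[np.ndarray, list[str], list[str]]:
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    genes = sorted(profiles[0].genes)
    for p in profiles[1:]:
        if set(p.genes) != set(genes):
            raise ValueError(
                f"profile {p.chemical!r} has a different gene set than the others"
            )
    X = np.vstack([p.vector(genes) for p in profiles])
    return X, [p.chemical for p in profiles], genes


def cluster_profiles(profiles: Sequence[FoldChangeProfile]) -> Dendrogram:
    """Average-linkage dendrogram over profiles (Euclidean distance on log2fc)."""
    X, labels, _ = _profile_matrix(profiles)
    D = squareform(pdist(X, metric="euclidean"))
    return _average_linkage(D, labels)


def cluster_genes(profiles: Sequence[FoldChangeProfile]) -> Dendrogram:
    """Same agglomeration applied to the transposed matrix (leaves are genes);
    provides the row ordering for heatmap export."""
    X, _, genes = _profile_matrix(profiles)
    D = squareform(pdist(X.T, metric="euclidean"))
    return _average_linkage(D, genes)


def twodc_call(
    panel: ReferencePanel,
    x: FoldChangeProfile,
    purity: float = DEFAULT_PURITY,
) -> ClassCall:
    """Classify a test profile by the class of the branch it first joins.

    The score is the DDI fraction among the reference profiles in the joined
    subtree.
    """
    if not 0.5 <= purity <= 1.0:
        raise ValueError("purity threshold must lie in [0.5, 1]")
    label = x.chemical
    if label in set(panel.chemicals):
        label = f"{label} (test)"
        x = FoldChangeProfile(label, x.log2fc)
    profiles = panel.profiles() + [x]
    dend = cluster_profiles(profiles)
    labels = dict(panel.labels)

    node = dend.leaves.index(label)
    n = len(dend.leaves)
    while True:
        parent = dend.parent_of(node)
        if parent is None:
            # single test against an empty complementary subtree cannot occur
            return ClassCall(verdict=INCONCLUSIVE, score=0.0, analysis=TWODC_ANALYSIS)
        left, right, _ = dend.merges[parent - n]
        sibling = right if left == node else left
        refs = [m for m in dend.members(sibling) if m != label]
        if refs:
            classes = [labels[r] for r in refs]
            frac_ddi = classes.count(DDI) / len(classes)
            frac_max = max(frac_ddi, 1.0 - frac_ddi)
            if frac_max >= purity and frac_ddi != 0.5:
                verdict = DDI if frac_ddi > 0.5 else NON_DDI
            else:
                verdict = INCONCLUSIVE
            return ClassCall(verdict=verdict, score=frac_ddi, analysis=TWODC_ANALYSIS)
        node = parent
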