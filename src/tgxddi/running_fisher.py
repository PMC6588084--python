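"""Directional Running Fisher correlation between a gene signature and a
query fold-change profile, plus cutoff calibration.

The published algorithm family compares two ranked, directional gene lists
by scanning nested top-k prefixes and testing each prefix's overlap with a
Fisher exact (hypergeometric upper-tail) test. The operationalization here:

1. the signature is split into up- and down-regulated sub-signatures; the
   query genes are split by the sign of their log2 fold change and each part
   is ranked by |log2fc| descending (ties broken alphabetically);
2. for each of the four (signature part, query part) pairs, the one-sided
   Fisher exact P of the overlap is computed at every prefix k = 1..m of the
   query part against the fixed gene universe; the minimum P over k is
   Bonferroni-multiplied by the number of prefixes scanned and capped at 1;
3. the two concordant pairs (up/up, down/down) are combined into a
   positive-correlation P with Fisher's method, the two discordant pairs
   into a negative-correlation P;
4. the overall P is the smaller of the two, the direction its sign, and the
   reported score is the signed -log10(P) (positive direction > 0).

The commercial implementation this mirrors is proprietary; exact numeric
equality with its scores (e.g. any particular published cutoff value) is
not promised. The cutoff calibration reproduces the published procedure:
on a labeled score set, the threshold is the minimum score among true DDI
chemicals — the largest cutoff that eliminates false negatives under the
"DDI iff score >= cutoff" rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .nsc import NSCModel
from .profiles import DDI, NON_DDI, ClassCall, FoldChangeProfile

RF_ANALYSIS = "RF"
POSITIVE = "positive"
NEGATIVE = "negative"

_CONCORDANT = (("up", "up"), ("down", "down"))
_DISCORDANT = (("up", "down"), ("down", "up"))


@dataclass(frozen=True)
class DirectionalSignature:
    """Ordered directional gene signature.

    ``entries`` is a tuple of (gene, direction, rank weight) with direction
    +1 (up in DDI) or -1 (down), sorted by weight descending, ties broken
    alphabetically. ``universe_size`` is the count of measurable genes the
    signature was built against (the retained panel size by default).
    """

    entries: tuple[tuple[str, int, float], ...]
    universe_size: int

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty signature")
        genes = [g for g, _, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in signature")
        if any(d not in (1, -1) for _, d, _ in self.entries):
            raise ValueError("signature directions must be +1 or -1")

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def part(self, direction: str) -> frozenset[str]:
        want = 1 if direction == "up" else -1
        return frozenset(g for g, d, _ in self.entries if d == want)


@dataclass(frozen=True)
class RFResult:
    """Signed Running Fisher outcome for one (signature, query) comparison."""

    p_value: float
    direction: str
    signed_score: float
    component_pvalues: dict[str, float]


def make_signature(model: NSCModel, universe_size: int | None = None) -> DirectionalSignature:
    """Directional signature from a fitted NSC model.

    Direction per gene is the sign of (DDI shrunken centroid - non-DDI
    shrunken centroid); the rank weight is its magnitude. Genes whose
    centroid difference is exactly zero carry no direction and are dropped
    with a warning.
    """
    i_ddi = model.classes.index(DDI)
    i_non = model.classes.index(NON_DDI)
    diff = model.shrunken_centroids[:, i_ddi] - model.shrunken_centroids[:, i_non]
    entries = []
    for gene, d in zip(model.genes, diff):
        if d == 0:
            warnings.warn(
                f"gene {gene} has zero centroid difference; dropped from signature",
                stacklevel=2,
            )
            continue
        entries.append((gene, 1 if d > 0 else -1, abs(float(d))))
    entries.sort(key=lambda e: (-e[2], e[0]))
    return DirectionalSignature(
        entries=tuple(entries),
        universe_size=len(model.genes) if universe_size is None else int(universe_size),
    )


def prefix_tail_pvalues(
    sig_genes: frozenset[str] | set[str],
    query_ranked: Sequence[str],
    universe_size: int,
) -> np.ndarray:
    """Hypergeometric upper-tail P at every prefix k = 1..len(query_ranked).

    At prefix k with overlap q, P = P(X >= q) for X ~ Hypergeom(N=universe,
    K=|sig_genes|, n=k).
    """
    m = len(query_ranked)
    k = np.arange(1, m + 1)
    overlap = np.cumsum([g in sig_genes for g in query_ranked])
    return stats.hypergeom.sf(overlap - 1, universe_size, len(sig_genes), k)


def _pair_pvalue(
    sig_genes: frozenset[str],
    query_ranked: Sequence[str],
    universe_size: int,
) -> float:
    """Best prefix P Bonferroni-corrected for the number of prefixes scanned."""
    if not sig_genes or not query_ranked:
        return 1.0
    p = prefix_tail_pvalues(sig_genes, query_ranked, universe_size)
    return float(min(1.0, p.min() * len(query_ranked)))


def _fisher_combine(pvalues: Sequence[float]) -> float:
    chi2 = -2.0 * sum(math.log(p) for p in pvalues)
    return float(stats.chi2.sf(chi2, df=2 * len(pvalues)))


def running_fisher_score(
    sig: DirectionalSignature,
    query: FoldChangeProfile,
    universe_size: int | None = None,
) -> RFResult:
    """Signed -log10(P) correlation between the signature and a query profile.

    Genes with log2 fold change exactly zero carry no direction and enter
    neither query part. A comparison with no informative overlap anywhere
    yields P = 1, direction positive by convention, and score 0.
    """
    universe = sig.universe_size if universe_size is None else int(universe_size)
    if query.n_genes == 0:
        raise ValueError("empty query profile")
    if universe < len(sig.entries) or universe < query.n_genes:
        raise ValueError(
            "universe_size must be at least the signature size and the query size"
        )

    def ranked(sign: int) -> list[str]:
        items = [(g, v) for g, v in query.log2fc.items() if np.sign(v) == sign]
        items.sort(key=lambda t: (-abs(t[1]), t[0]))
        return [g for g, _ in items]

    q = {"up": ranked(1), "down": ranked(-1)}
    comp: dict[str, float] = {}
    for s_dir, q_dir in _CONCORDANT + _DISCORDANT:
        comp[f"{s_dir}_{q_dir}"] = _pair_pvalue(sig.part(s_dir), q[q_dir], universe)
    p_pos = _fisher_combine([comp["up_up"], comp["down_down"]])
    p_neg = _fisher_combine([comp["up_down"], comp["down_up"]])
    comp[POSITIVE] = p_pos
    comp[NEGATIVE] = p_neg

    if p_pos <= p_neg:
        direction, p = POSITIVE, p_pos
    else:
        direction, p = NEGATIVE, p_neg
    p = min(max(p, np.finfo(float).tiny), 1.0)  # keep -log10 finite
    score = -math.log10(p) * (1.0 if direction == POSITIVE else -1.0)
    return RFResult(
        p_value=p, direction=direction, signed_score=score, component_pvalues=comp
    )


def calibrate_cutoff(
    scores: Mapping[str, float],
    labels: Mapping[str, str],
) -> float:
    """Largest signed-score threshold with zero false negatives.

    Under the "DDI iff score >= cutoff" rule this is the minimum score among
    true-DDI chemicals in the labeled calibration set.
    """
    ddi_scores = [scores[c] for c in scores if labels[c] == DDI]
    if not ddi_scores:
        raise ValueError("calibration set contains no DDI chemicals")
    return float(min(ddi_scores))


def rf_call(result: RFResult | float, cutoff: float) -> ClassCall:
    """Dichotomous Running Fisher verdict: DDI iff score >= cutoff.

    Never inconclusive; a score exactly at the cutoff is DDI.
    """
    score = result.signed_score if isinstance(result, RFResult) else float(result)
    verdict = DDI if score >= cutoff else NON_DDI
    return ClassCall(verdict=verdict, score=score, analysis=RF_ANALYSIS)
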