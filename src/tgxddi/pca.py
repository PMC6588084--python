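"""PCA-based classification of test profiles against the reference panel.

The original analysis classified a test chemical by eye from a PCA
scatterplot of the reference profiles, calling the chemical after the class
cloud it fell into and "inconclusive" when it lay on the border. This module
formalizes that judgment as a one-dimensional rule:

* profiles are centered (not scaled) with the reference-panel gene means and
  decomposed by SVD (equivalent to prcomp's default);
* the separating component is the one maximizing the standardized class-mean
  separation |mean(DDI) - mean(non-DDI)| / pooled SD of the scores;
* the decision boundary is the midpoint of the two class means on that
  component, with an inconclusive band of halfwidth
  ``band_fraction x |mean separation|`` (default 0.1) around it.

Test profiles are projected with the stored centering and loadings; the
panel is not refit per test chemical by default (a refit-per-test option is
available at the pipeline level for fidelity to the original plots, which
included the test agent in the decomposition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import DDI, INCONCLUSIVE, NON_DDI, ClassCall, FoldChangeProfile, ReferencePanel

PCA_ANALYSIS = "PCA"
DEFAULT_BAND_FRACTION = 0.1


@dataclass(frozen=True)
class PCAModel:
    genes: tuple[str, ...]
    center: np.ndarray               # (g,) reference-panel gene means
    loadings: np.ndarray             # (g, c), orthonormal columns
    explained_variance: np.ndarray   # (c,), non-increasing
    separating_component: int
    boundary: float                  # midpoint of class means on that component
    band_halfwidth: float            # inconclusive band around the boundary
    ddi_side: float                  # sign of (DDI mean - boundary)


def fit_pca(panel: ReferencePanel, band_fraction: float = DEFAULT_BAND_FRACTION) -> PCAModel:
    """Fit the PCA decision model on the labeled reference panel."""
    if band_fraction < 0:
        raise ValueError("band_fraction must be >= 0")
    X = panel.matrix.to_numpy().T  # profiles x genes
    labels = panel.labels.to_numpy()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 profiles to fit a PCA model")
    for k in (DDI, NON_DDI):
        if (labels == k).sum() == 0:
            raise ValueError(f"reference panel has no {k} profiles")
    center = X.mean(axis=0)
    Xc = X - center
    if np.allclose(Xc, 0):
        raise ValueError("degenerate panel: all profiles identical (rank 0)")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention: largest-|loading| entry of each component positive
    loadings = Vt.T
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    scores = Xc @ loadings
    expl = S**2 / (X.shape[0] - 1)

    ddi = labels == DDI
    non = labels == NON_DDI
    sep = np.zeros(scores.shape[1])
    for j in range(scores.shape[1]):
        m1, m0 = scores[ddi, j].mean(), scores[non, j].mean()
        n1, n0 = ddi.sum(), non.sum()
        v1 = scores[ddi, j].var(ddof=1) if n1 > 1 else 0.0
        v0 = scores[non, j].var(ddof=1) if n0 > 1 else 0.0
        pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / max(n1 + n0 - 2, 1)
        gap = abs(m1 - m0)
        if pooled == 0:
            sep[j] = np.inf if gap > 0 else 0.0
        else:
            sep[j] = gap / np.sqrt(pooled)
    j = int(np.argmax(sep))
    m1, m0 = scores[ddi, j].mean(), scores[non, j].mean()
    boundary = 0.5 * (m1 + m0)
    band = band_fraction * abs(m1 - m0)
    side = float(np.sign(m1 - boundary)) or 1.0
    return PCAModel(
        genes=tuple(panel.genes),
        center=center,
        loadings=loadings,
        explained_variance=expl,
        separating_component=j,
        boundary=float(boundary),
        band_halfwidth=float(band),
        ddi_side=side,
    )


def transform(model: PCAModel, profiles: Sequence[FoldChangeProfile]) -> pd.DataFrame:
    """Component scores (profiles x components) under the stored centering."""
    rows = {p.chemical: (p.vector(model.genes) - model.center) @ model.loadings for p in profiles}
    cols = [f"PC{i + 1}" for i in range(model.loadings.shape[1])]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def pca_call(model: PCAModel, x: FoldChangeProfile) -> ClassCall:
    """Classify by the side of the 1-D boundary the projected score falls on.

    The score is the coordinate on the separating component; a score within
    the inconclusive band of the boundary yields ``inconclusive``.
    """
    v = x.vector(model.genes)
    score = float((v - model.center) @ model.loadings[:, model.separating_component])
    if abs(score - model.boundary) <= model.band_halfwidth:
        verdict = INCONCLUSIVE
    elif (score - model.boundary) * model.ddi_side > 0:
        verdict = DDI
    else:
        verdict = NON_DDI
    return ClassCall(verdict=verdict, score=score, analysis=PCA_ANALYSIS)
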