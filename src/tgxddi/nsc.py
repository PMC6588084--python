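"""Nearest shrunken centroid (NSC) classifier and the probability analysis (PA).

The model follows the classical shrunken-centroid construction for two
classes k in {DDI, non-DDI} over genes i:

    x_bar_i            overall per-gene mean over the reference panel
    x_bar_ik           per-class per-gene mean (class centroid)
    s_i^2              pooled within-class variance, sum of squares / (n - K)
    s0                 fudge factor, median of the s_i (guards tiny variances)
    m_k                sqrt(1/n_k - 1/n)
    d_ik               (x_bar_ik - x_bar_i) / (m_k (s_i + s0))
    d'_ik              soft threshold: sign(d_ik) (|d_ik| - delta)+
    x_bar'_ik          shrunken centroid: x_bar_i + m_k (s_i + s0) d'_ik

Classification uses the discriminant score

    delta_k(x) = sum_i (x_i - x_bar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k

and class probabilities p_k(x) = exp(-delta_k/2) / sum_l exp(-delta_l/2),
evaluated with a log-sum-exp shift so that scores with |delta| up to ~1e4 do
not overflow. The probability analysis (PA) assigns a class when its
membership probability strictly exceeds the threshold (default 0.90) and is
inconclusive otherwise.

With delta = 0 (the default: the gene panel is taken as given, not
re-selected) the shrunken centroids equal the raw class centroids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .profiles import CLASSES, DDI, INCONCLUSIVE, NON_DDI, ClassCall, FoldChangeProfile, ReferencePanel

PA_ANALYSIS = "PA"
DEFAULT_PA_THRESHOLD = 0.90


@dataclass(frozen=True)
class NSCModel:
    """Fitted nearest-shrunken-centroid state for the two-class problem."""

    genes: tuple[str, ...]
    classes: tuple[str, ...]
    overall_centroid: np.ndarray      # (g,)
    class_centroids: np.ndarray       # (g, K)
    shrunken_centroids: np.ndarray    # (g, K)
    pooled_sd: np.ndarray             # (g,)
    fudge_s0: float
    shrinkage_delta: float
    class_priors: np.ndarray          # (K,)
    class_sizes: np.ndarray           # (K,)

    @property
    def n(self) -> int:
        return int(self.class_sizes.sum())

    @property
    def m_k(self) -> np.ndarray:
        return np.sqrt(1.0 / self.class_sizes - 1.0 / self.n)

    @property
    def d_ik(self) -> np.ndarray:
        """Standardized centroid distances (before shrinkage)."""
        denom = self.m_k[None, :] * (self.pooled_sd + self.fudge_s0)[:, None]
        return (self.class_centroids - self.overall_centroid[:, None]) / denom

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "genes": list(self.genes),
            "classes": list(self.classes),
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "fudge_s0": self.fudge_s0,
            "shrinkage_delta": self.shrinkage_delta,
            "class_priors": self.class_priors.tolist(),
            "class_sizes": self.class_sizes.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NSCModel":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(
            genes=tuple(d["genes"]),
            classes=tuple(d["classes"]),
            overall_centroid=np.asarray(d["overall_centroid"], dtype=float),
            class_centroids=np.asarray(d["class_centroids"], dtype=float),
            shrunken_centroids=np.asarray(d["shrunken_centroids"], dtype=float),
            pooled_sd=np.asarray(d["pooled_sd"], dtype=float),
            fudge_s0=float(d["fudge_s0"]),
            shrinkage_delta=float(d["shrinkage_delta"]),
            class_priors=np.asarray(d["class_priors"], dtype=float),
            class_sizes=np.asarray(d["class_sizes"], dtype=int),
        )


def fit_nsc(
    panel: ReferencePanel,
    delta: float = 0.0,
    priors: str = "equal",
    *,
    s0: float | None = None,
) -> NSCModel:
    """Fit the NSC model on a labeled reference panel.

    Parameters
    ----------
    panel:
        Labeled fold-change panel; both classes need at least two profiles.
    delta:
        Soft-threshold shrinkage amount (>= 0). Default 0: no shrinkage, the
        biomarker gene panel is already fixed.
    priors:
        "equal" (0.5/0.5, matching the balanced reference design) or
        "proportional" (n_k / n).
    s0:
        Override for the fudge factor; default is the median pooled SD.
    """
    if delta < 0:
        raise ValueError("shrinkage delta must be >= 0")
    if priors not in ("equal", "proportional"):
        raise ValueError("priors must be 'equal' or 'proportional'")
    X = panel.matrix.to_numpy()  # genes x n
    labels = panel.labels.to_numpy()
    present = [k for k in CLASSES if (labels == k).sum() > 0]
    if len(present) < 2:
        raise ValueError("reference panel must contain both DDI and non-DDI profiles")
    masks = [labels == k for k in CLASSES]
    sizes = np.array([m.sum() for m in masks])
    if (sizes < 2).any():
        raise ValueError("need at least 2 profiles per class to estimate within-class spread")
    n = X.shape[1]
    K = len(CLASSES)

    xbar = X.mean(axis=1)
    centroids = np.column_stack([X[:, m].mean(axis=1) for m in masks])
    ss = np.zeros(X.shape[0])
    for k, m in enumerate(masks):
        ss += ((X[:, m] - centroids[:, [k]]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - K))
    s0_val = float(np.median(s)) if s0 is None else float(s0)
    if s0_val < 0:
        raise ValueError("s0 must be >= 0")
    if s0_val == 0 and (s == 0).any():
        raise ValueError(
            "gene(s) with zero pooled SD while s0 = 0; pass an s0 > 0 to regularize"
        )

    m_k = np.sqrt(1.0 / sizes - 1.0 / n)
    scale = m_k[None, :] * (s + s0_val)[:, None]
    d = (centroids - xbar[:, None]) / scale
    d_shr = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = xbar[:, None] + scale * d_shr

    pri = np.full(K, 1.0 / K) if priors == "equal" else sizes / n
    return NSCModel(
        genes=tuple(panel.genes),
        classes=CLASSES,
        overall_centroid=xbar,
        class_centroids=centroids,
        shrunken_centroids=shrunken,
        pooled_sd=s,
        fudge_s0=s0_val,
        shrinkage_delta=float(delta),
        class_priors=pri,
        class_sizes=sizes,
    )


def discriminant_scores(model: NSCModel, x: FoldChangeProfile) -> np.ndarray:
    """delta_k(x) for each class, in model.classes order."""
    v = x.vector(model.genes)
    w = (model.pooled_sd + model.fudge_s0) ** 2
    dist = (((v[:, None] - model.shrunken_centroids) ** 2) / w[:, None]).sum(axis=0)
    return dist - 2.0 * np.log(model.class_priors)


def class_probabilities(model: NSCModel, x: FoldChangeProfile) -> dict[str, float]:
    """Posterior class membership probabilities; positive and summing to 1."""
    delta_k = discriminant_scores(model, x)
    z = -0.5 * delta_k
    z = z - z.max()  # log-sum-exp shift: stable for |delta| up to ~1e4 and beyond
    p = np.exp(z)
    p /= p.sum()
    return dict(zip(model.classes, p.tolist()))


def pa_call(
    model: NSCModel,
    x: FoldChangeProfile,
    threshold: float = DEFAULT_PA_THRESHOLD,
) -> ClassCall:
    """Probability-analysis verdict: a class wins only if p > threshold.

    The reported score is the DDI membership probability.
    """
    if not 0.5 < threshold < 1.0:
        raise ValueError("PA threshold must lie in (0.5, 1)")
    p = class_probabilities(model, x)
    if p[DDI] > threshold:
        verdict = DDI
    elif p[NON_DDI] > threshold:
        verdict = NON_DDI
    else:
        verdict = INCONCLUSIVE
    return ClassCall(verdict=verdict, score=p[DDI], analysis=PA_ANALYSIS)
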