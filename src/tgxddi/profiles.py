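"""Shared containers: fold-change profiles, labeled reference panels, classifier calls.

The two chemical classes are ``DDI`` (DNA damage-inducing) and ``non-DDI``.
Per-analysis verdicts additionally allow ``inconclusive`` for chemicals that
sit on a decision border.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DDI = "DDI"
NON_DDI = "non-DDI"
INCONCLUSIVE = "inconclusive"

CLASSES: tuple[str, str] = (DDI, NON_DDI)
VERDICTS: tuple[str, str, str] = (DDI, NON_DDI, INCONCLUSIVE)


def _normalize_genes(index: Iterable[str]) -> pd.Index:
    """Upper-case gene symbols (all symbols are case-normalized on ingest)."""
    return pd.Index([str(g).strip().upper() for g in index], name="gene")


@dataclass(frozen=True)
class FoldChangeProfile:
    """Per-chemical vector of log2 fold changes over the biomarker genes.

    Parameters
    ----------
    chemical:
        Chemical (treatment) label. Distinct treatments of the same agent
        (e.g. two concentrations) carry distinct labels.
    log2fc:
        Series mapping gene symbol to log2 fold change relative to the
        matched vehicle control. All values must be finite.
    """

    chemical: str
    log2fc: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.log2fc, dtype=float)
        s.index = _normalize_genes(s.index)
        if s.index.has_duplicates:
            dups = sorted(s.index[s.index.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols in profile {self.chemical!r}: {dups}")
        if not np.isfinite(s.to_numpy()).all():
            bad = sorted(s.index[~np.isfinite(s.to_numpy())])
            raise ValueError(f"non-finite log2 fold change in profile {self.chemical!r}: {bad}")
        object.__setattr__(self, "log2fc", s)

    @property
    def genes(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def n_genes(self) -> int:
        return len(self.log2fc)

    def vector(self, genes: Sequence[str]) -> np.ndarray:
        """Values in the requested gene order; raises if any gene is missing."""
        genes = [g.upper() for g in genes]
        missing = sorted(set(genes) - set(self.log2fc.index))
        if missing:
            raise KeyError(
                f"profile {self.chemical!r} is missing genes required by the model: {missing}"
            )
        return self.log2fc.reindex(genes).to_numpy()


@dataclass(frozen=True)
class ReferencePanel:
    """Labeled set of fold-change profiles used for training and calibration.

    ``matrix`` is genes x profiles (columns are profile labels) and ``labels``
    maps each profile label to its class (``DDI`` or ``non-DDI``).
    """

    matrix: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        m = self.matrix.astype(float)
        m.index = _normalize_genes(m.index)
        labels = pd.Series(self.labels, dtype=object)
        if m.index.has_duplicates:
            raise ValueError("duplicate gene symbols in panel matrix")
        if set(m.columns) != set(labels.index):
            raise ValueError("panel matrix columns and label index disagree")
        labels = labels.reindex(m.columns)
        bad = sorted(set(labels) - set(CLASSES))
        if bad:
            raise ValueError(f"unknown class labels {bad}; expected one of {CLASSES}")
        if not np.isfinite(m.to_numpy()).all():
            raise ValueError("panel matrix contains non-finite values")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_profiles(
        cls, profiles: Sequence[FoldChangeProfile], labels: Mapping[str, str]
    ) -> "ReferencePanel":
        if not profiles:
            raise ValueError("empty profile list")
        genes = profiles[0].genes
        cols = {}
        for p in profiles:
            if set(p.genes) != set(genes):
                raise ValueError(f"profile {p.chemical!r} has a different gene set")
            cols[p.chemical] = p.log2fc.reindex(genes)
        matrix = pd.DataFrame(cols)
        lab = pd.Series({c: labels[c] for c in matrix.columns})
        return cls(matrix, lab)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def chemicals(self) -> list[str]:
        return list(self.matrix.columns)

    def profile(self, chemical: str) -> FoldChangeProfile:
        return FoldChangeProfile(chemical, self.matrix[chemical])

    def profiles(self) -> list[FoldChangeProfile]:
        return [self.profile(c) for c in self.matrix.columns]


@dataclass(frozen=True)
class ClassCall:
    """A single classifier verdict for one chemical.

    ``score`` is the analysis-specific quantity backing the verdict: the DDI
    membership probability (PA), the coordinate on the separating principal
    component (PCA), the DDI fraction of the joined branch (2-DC), or the
    signed -log10(P) (Running Fisher).
    """

    verdict: str
    score: float
    analysis: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"verdict must be one of {VERDICTS}, got {self.verdict!r}")
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite score in {self.analysis} call")
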