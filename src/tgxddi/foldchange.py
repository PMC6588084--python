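"""Cq tables to normalized log2 fold-change profiles.

Implements the standard delta-delta-Cq chain for TaqMan qPCR arrays:

* reference genes are ranked by the stability (standard deviation) of their
  Cq across all samples, and the most stable ones are averaged to normalize
  each sample (delta Cq);
* biomarker genes undetermined (or above the 40-cycle ceiling) in a majority
  of samples are excluded before any arithmetic;
* each treatment is normalized to its matched vehicle control
  (delta-delta Cq), and fold change = 2^(-ddCq), i.e. log2 fold change
  = -ddCq.

Biological replicates are averaged on the delta-Cq scale (arithmetic mean of
dCq), not on the linear fold-change scale. "Undetermined" Cq values are
carried as NaN; they count as unexpressed for filtering but are never used
in delta-Cq arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import FoldChangeProfile, _normalize_genes

#: qPCR cycle ceiling; Cq at or beyond this (or NaN) is treated as unexpressed.
DEFAULT_CQ_CEILING = 40.0

#: A gene is dropped when it is unexpressed in more than this fraction of samples.
DEFAULT_MAJORITY_FRACTION = 0.5

ROLES = ("treatment", "control")


@dataclass(frozen=True)
class CqTable:
    """Raw quantification-cycle values per (gene, sample) with sample metadata.

    Parameters
    ----------
    values:
        Genes x samples matrix of Cq values (cycles). NaN encodes an
        "undetermined" well (no threshold crossing within the run).
    samples:
        Sample sheet indexed by sample ID with columns ``chemical``, ``role``
        (treatment or control), ``vehicle`` (solvent label used to match
        treatments to controls) and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.astype(float)
        v.index = _normalize_genes(v.index)
        if v.index.has_duplicates:
            dups = sorted(v.index[v.index.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols in Cq table: {dups}")
        sheet = pd.DataFrame(self.samples).copy()
        required = {"chemical", "role", "vehicle"}
        missing_cols = required - set(sheet.columns)
        if missing_cols:
            raise ValueError(f"sample sheet is missing columns {sorted(missing_cols)}")
        if "replicate" not in sheet.columns:
            sheet["replicate"] = 1
        if set(sheet.index) != set(v.columns):
            raise ValueError("sample sheet IDs and Cq table columns disagree")
        sheet = sheet.reindex(v.columns)
        bad_roles = sorted(set(sheet["role"]) - set(ROLES))
        if bad_roles:
            raise ValueError(f"unknown sample roles {bad_roles}; expected {ROLES}")
        # every vehicle used by a treatment must have at least one control sample
        is_ctrl = sheet["role"] == "control"
        ctrl_vehicles = set(sheet.loc[is_ctrl, "vehicle"])
        treat_vehicles = set(sheet.loc[~is_ctrl, "vehicle"])
        orphans = sorted(treat_vehicles - ctrl_vehicles)
        if orphans:
            raise ValueError(f"no vehicle-control samples for solvents {orphans}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "samples", sheet)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, genes: Sequence[str]) -> "CqTable":
        genes = [g.upper() for g in genes]
        missing = sorted(set(genes) - set(self.values.index))
        if missing:
            raise KeyError(f"genes not in Cq table: {missing}")
        return CqTable(self.values.loc[genes], self.samples)


def _unexpressed_mask(values: pd.DataFrame, ceiling: float) -> pd.DataFrame:
    return values.isna() | (values > ceiling)


def rank_reference_genes(
    cq: CqTable,
    candidates: Sequence[str],
    *,
    ceiling: float = DEFAULT_CQ_CEILING,
) -> list[tuple[str, float]]:
    """Order candidate reference genes by Cq stability across all samples.

    Stability is the sample standard deviation of Cq pooled over every sample
    (treatments and controls alike); smaller is more stable. Ties are broken
    alphabetically. Candidates undetermined (or above ``ceiling``) in more
    than half of the samples are excluded with a warning.

    Returns
    -------
    list of (gene, stability score) in ascending score order.
    """
    if len(cq.sample_ids) < 2:
        raise ValueError("need at least 2 samples to assess Cq stability")
    genes = [g.upper() for g in candidates]
    missing = sorted(set(genes) - set(cq.values.index))
    if missing:
        raise KeyError(f"reference-gene candidate(s) not in Cq table: {missing}")
    scored: list[tuple[str, float]] = []
    for g in dict.fromkeys(genes):  # preserve order, drop duplicates
        row = cq.values.loc[g]
        undet = _unexpressed_mask(row.to_frame().T, ceiling).iloc[0]
        if undet.mean() > 0.5:
            warnings.warn(
                f"reference candidate {g} undetermined in "
                f"{100 * undet.mean():.0f}% of samples; excluded from ranking",
                stacklevel=2,
            )
            continue
        # two-pass numpy SD: exactly 0.0 for a constant gene
        sd = float(np.std(row[~undet].to_numpy(), ddof=1))
        scored.append((g, sd))
    scored.sort(key=lambda t: (t[1], t[0]))
    return scored


def filter_unexpressed_genes(
    cq: CqTable,
    panel: Sequence[str],
    *,
    ceiling: float = DEFAULT_CQ_CEILING,
    majority_fraction: float = DEFAULT_MAJORITY_FRACTION,
) -> tuple[list[str], list[str]]:
    """Split the biomarker panel into retained and excluded genes.

    A gene is excluded iff the fraction of samples in which its Cq exceeds
    ``ceiling`` (or is undetermined) is greater than ``majority_fraction``.
    Both returned lists are sorted; their union is the panel. Filtering is
    idempotent: re-filtering the retained list changes nothing.
    """
    genes = sorted({g.upper() for g in panel})
    missing = sorted(set(genes) - set(cq.values.index))
    if missing:
        raise KeyError(f"panel gene(s) not in Cq table: {missing}")
    frac = _unexpressed_mask(cq.values.loc[genes], ceiling).mean(axis=1)
    excluded = sorted(frac.index[frac > majority_fraction])
    retained = sorted(set(genes) - set(excluded))
    if not retained:
        raise ValueError("all panel genes are unexpressed; nothing to analyze")
    return retained, excluded


def compute_fold_changes(
    cq: CqTable,
    reference_genes: Sequence[str],
    panel: Sequence[str],
) -> list[FoldChangeProfile]:
    """Compute per-chemical log2 fold-change profiles by the ddCq method.

    dCq(gene, sample) = Cq(gene, sample) - mean(Cq of reference genes, sample);
    replicate samples are averaged on the dCq scale; ddCq(gene, chemical) =
    mean dCq(treatment) - mean dCq(matched vehicle control); log2 fold change
    = -ddCq (fold change = 2^-ddCq).

    Raises
    ------
    ValueError
        If a reference gene is undetermined in any sample, if a retained panel
        gene contains undetermined Cq (filter first), or if a chemical lacks a
        matched vehicle control.
    """
    refs = [g.upper() for g in reference_genes]
    genes = [g.upper() for g in panel]
    missing = sorted((set(refs) | set(genes)) - set(cq.values.index))
    if missing:
        raise KeyError(f"gene(s) not in Cq table: {missing}")
    ref_block = cq.values.loc[refs]
    if ref_block.isna().any().any():
        bad = sorted(ref_block.index[ref_block.isna().any(axis=1)])
        raise ValueError(f"reference gene(s) with undetermined Cq: {bad}")
    target = cq.values.loc[genes]
    if target.isna().any().any():
        bad = sorted(target.index[target.isna().any(axis=1)])
        raise ValueError(
            f"undetermined Cq in retained gene(s) {bad}; "
            "run filter_unexpressed_genes before computing fold changes"
        )

    ref_mean = ref_block.mean(axis=0)  # per sample
    dcq = target.sub(ref_mean, axis=1)

    sheet = cq.samples
    is_treat = sheet["role"] == "treatment"
    profiles: list[FoldChangeProfile] = []
    for chemical in sorted(sheet.loc[is_treat, "chemical"].unique()):
        t_ids = sheet.index[is_treat & (sheet["chemical"] == chemical)]
        vehicles = set(sheet.loc[t_ids, "vehicle"])
        if len(vehicles) != 1:
            raise ValueError(
                f"chemical {chemical!r} spans multiple vehicles {sorted(vehicles)}"
            )
        vehicle = vehicles.pop()
        c_ids = sheet.index[(~is_treat) & (sheet["vehicle"] == vehicle)]
        if len(c_ids) == 0:
            raise ValueError(
                f"no matched vehicle control for chemical {chemical!r} "
                f"(vehicle {vehicle!r})"
            )
        ddcq = dcq[t_ids].mean(axis=1) - dcq[c_ids].mean(axis=1)
        profiles.append(FoldChangeProfile(chemical, -ddcq))
    if not profiles:
        raise ValueError("Cq table contains no treatment samples")
    return profiles
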