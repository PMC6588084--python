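"""Readers and writers for the plain-text interchange formats.

* Cq table: CSV, first column gene symbol (or well ID when a plate layout is
  supplied), remaining columns sample IDs; "Undetermined"/empty cells become
  NaN. Companion sample sheet CSV with columns sample_id, chemical, role
  (treatment|control), vehicle, replicate.
* Plate layout: CSV mapping well -> assay (gene); a well-indexed Cq table is
  flattened to genes, averaging wells that carry duplicate assays.
* Fold-change matrix: TSV, genes x chemicals, log2 scale.
* Panel file: one gene symbol per line, optional second column with the
  expected direction (+1/-1).
* Labels: CSV with columns chemical, class.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .foldchange import CqTable
from .profiles import CLASSES, FoldChangeProfile, ReferencePanel

_NA_TOKENS = ["Undetermined", "undetermined", "UNDETERMINED", "NA", ""]


def read_plate_layout(path: str | Path) -> pd.Series:
    """Well -> gene mapping from a two-column CSV (header optional)."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.lower() for c in df.columns]
    if not {"well", "gene"} <= set(cols) and not {"well", "assay"} <= set(cols):
        # headerless file: first column wells, second assays
        df = pd.read_csv(path, dtype=str, header=None, names=["well", "gene"])
    else:
        df.columns = cols
        if "assay" in df.columns:
            df = df.rename(columns={"assay": "gene"})
    return pd.Series(df["gene"].str.upper().to_numpy(), index=df["well"].to_numpy())


def read_cq_table(
    cq_csv: str | Path,
    sample_sheet_csv: str | Path,
    plate_layout_csv: str | Path | None = None,
) -> CqTable:
    values = pd.read_csv(cq_csv, index_col=0, na_values=_NA_TOKENS, keep_default_na=True)
    if plate_layout_csv is not None:
        layout = read_plate_layout(plate_layout_csv)
        missing = sorted(set(values.index) - set(layout.index))
        if missing:
            raise KeyError(f"wells absent from plate layout: {missing}")
        values = values.groupby(layout.reindex(values.index).to_numpy()).mean()
    sheet = pd.read_csv(sample_sheet_csv, dtype={"sample_id": str}).set_index("sample_id")
    return CqTable(values, sheet)


def write_foldchange_tsv(
    profiles: Sequence[FoldChangeProfile] | ReferencePanel, path: str | Path
) -> None:
    if isinstance(profiles, ReferencePanel):
        matrix = profiles.matrix
    else:
        matrix = pd.DataFrame({p.chemical: p.log2fc for p in profiles})
    matrix.index.name = "gene"
    matrix.to_csv(path, sep="\t")


def read_foldchange_tsv(path: str | Path) -> list[FoldChangeProfile]:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError(f"non-finite log2 fold changes in {path}")
    return [FoldChangeProfile(str(c), matrix[c]) for c in matrix.columns]


def read_panel_file(path: str | Path) -> tuple[list[str], dict[str, int] | None]:
    """Gene list plus optional per-gene expected direction."""
    genes: list[str] = []
    directions: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        gene = parts[0].upper()
        genes.append(gene)
        if len(parts) > 1:
            directions[gene] = int(parts[1])
    return genes, (directions or None)


def read_labels_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    chem_col = cols.get("chemical", df.columns[0])
    class_col = cols.get("class", df.columns[1])
    labels = dict(zip(df[chem_col], df[class_col]))
    bad = sorted({v for v in labels.values() if v not in CLASSES})
    if bad:
        raise ValueError(f"unknown class labels {bad}; expected one of {CLASSES}")
    return labels


def write_labels_csv(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"chemical": list(labels), "class": [labels[c] for c in labels]}
    ).to_csv(path, index=False)
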