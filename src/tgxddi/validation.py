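"""Published classification outcomes for the TGx-DDI qPCR validation study.

The TGx-DDI biomarker's qPCR adaptation (data deposited under GEO accession
GSE121532) was built on a reference set of 28 agents (14 DDI, 14 non-DDI;
ethanol profiled at two concentrations under one label) and externally
validated on 24 chemicals (8 DDI, 16 non-DDI). The per-chemical aggregated
calls and class labels published for those sets are embedded here so the
metrics engine can be exercised against the study's reported performance
without any download.

Reference-set per-chemical calls are reconstructed from the study's named
misclassifications: under the three-pronged approach methotrexate (MTX) was
a false negative and 2-deoxy-D-glucose (2-DG) a false positive; under the
Running Fisher cutoff 2-DG was the only error.
"""

from __future__ import annotations

from .profiles import DDI, NON_DDI

# ---------------------------------------------------------------------------
# Reference set: 14 DDI / 14 non-DDI agents
# ---------------------------------------------------------------------------

REFERENCE_CLASSES: dict[str, str] = {
    "Cisplatin": DDI,
    "Methyl methanesulfonate": DDI,
    "Camptothecin": DDI,
    "Etoposide": DDI,
    "5-fluorouracil": DDI,
    "Methotrexate": DDI,
    "Arabinofuranosyl cytidine": DDI,
    "Hydroxyurea": DDI,
    "Gamma irradiation": DDI,
    "Bleomycin": DDI,
    "Hydrogen peroxide": DDI,
    "Cadmium chloride": DDI,
    "Potassium chromate": DDI,
    "Sodium arsenite": DDI,
    "Colchicine": NON_DDI,
    "Docetaxel": NON_DDI,
    "Paclitaxel": NON_DDI,
    "Vinblastine": NON_DDI,
    "Trichostatin A": NON_DDI,
    "Apicidin": NON_DDI,
    "HC Toxin": NON_DDI,
    "Oxamflatin": NON_DDI,
    "Tunicamycin": NON_DDI,
    "Thapsigargin": NON_DDI,
    "2-deoxy-D-glucose": NON_DDI,
    "Antimycin A": NON_DDI,
    "Heat shock": NON_DDI,
    "Ethanol": NON_DDI,
}

_REFERENCE_ERRORS = {
    # chemical -> wrong overall call, per classification approach
    "three_pronged": {"Methotrexate": NON_DDI, "2-deoxy-D-glucose": DDI},
    "rf_only": {"2-deoxy-D-glucose": DDI},
}

REFERENCE_CALLS: dict[str, dict[str, str]] = {
    approach: {
        chem: _REFERENCE_ERRORS[approach].get(chem, cls)
        for chem, cls in REFERENCE_CLASSES.items()
    }
    for approach in _REFERENCE_ERRORS
}

# ---------------------------------------------------------------------------
# External validation set: 8 DDI / 16 non-DDI chemicals
# ---------------------------------------------------------------------------

EXTERNAL_CLASSES: dict[str, str] = {
    "Bleomycin": DDI,
    "Busulfan": DDI,
    "Chlorambucil": DDI,
    "EMS": DDI,
    "ENU": DDI,
    "Hydroquinone": DDI,
    "Mitomycin C": DDI,
    "Nitrogen mustard": DDI,
    "Ampicillin": NON_DDI,
    "Erythromycin": NON_DDI,
    "Methyl carbamate": NON_DDI,
    "N-butyl chloride": NON_DDI,
    "Sunitinib malate": NON_DDI,
    "2,4-DNP": NON_DDI,
    "Cycloheximide": NON_DDI,
    "Dexamethasone": NON_DDI,
    "Donepezil": NON_DDI,
    "Esomeprazole": NON_DDI,
    "Exemestane": NON_DDI,
    "Olmesartan": NON_DDI,
    "Phenobarbital": NON_DDI,
    "Rabeprazole": NON_DDI,
    "Rotigotine": NON_DDI,
    "Staurosporine": NON_DDI,
}

# Published aggregated external calls. The three-pronged column missed
# busulfan and chlorambucil (false negatives) and called sunitinib malate,
# cycloheximide and exemestane DDI (false positives). Every scheme that
# includes the Running Fisher test produced the identical published column:
# all eight DDI chemicals plus the same three false positives.
_EXTERNAL_THREE_PRONGED: dict[str, str] = {
    chem: (
        DDI
        if (cls == DDI and chem not in ("Busulfan", "Chlorambucil"))
        or chem in ("Sunitinib malate", "Cycloheximide", "Exemestane")
        else NON_DDI
    )
    for chem, cls in EXTERNAL_CLASSES.items()
}

_EXTERNAL_RF: dict[str, str] = {
    chem: (
        DDI
        if cls == DDI or chem in ("Sunitinib malate", "Cycloheximide", "Exemestane")
        else NON_DDI
    )
    for chem, cls in EXTERNAL_CLASSES.items()
}

EXTERNAL_CALLS: dict[str, dict[str, str]] = {
    "three_pronged": _EXTERNAL_THREE_PRONGED,
    "rf_only": dict(_EXTERNAL_RF),
    "three_pronged_plus_rf": dict(_EXTERNAL_RF),
    "pa_rf": dict(_EXTERNAL_RF),
    "pca_rf": dict(_EXTERNAL_RF),
    "twodc_rf": dict(_EXTERNAL_RF),
}
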