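"""End-to-end orchestration: reference fitting, per-chemical calls,
aggregation, metrics, and artifact export.

Given a labeled reference panel and a set of test fold-change profiles, the
pipeline fits the NSC and PCA models, derives the directional signature and
the calibrated Running Fisher cutoff from the reference scores, produces
PA / PCA / 2-DC / RF calls per test chemical, aggregates them under every
combination scheme, and (when true classes are supplied) scores each scheme.
Everything is deterministic given (inputs, config): reruns produce
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__ as _version
from .hclust import cluster_genes, cluster_profiles, twodc_call
from .metrics import SCHEMES, PerformanceReport, build_call_matrix, performance
from .nsc import NSCModel, fit_nsc, pa_call
from .pca import PCAModel, fit_pca, pca_call, transform
from .profiles import ClassCall, FoldChangeProfile, ReferencePanel
from .running_fisher import (
    DirectionalSignature,
    calibrate_cutoff,
    make_signature,
    rf_call,
    running_fisher_score,
)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds and options; JSON round-trips losslessly."""

    pa_threshold: float = 0.90
    pca_band_fraction: float = 0.1
    pca_refit_with_test: bool = False
    twodc_purity: float = 1.0
    rf_cutoff: float | str = "calibrate"
    delta: float = 0.0
    priors: str = "equal"
    universe_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.pa_threshold < 1.0:
            raise ValueError("pa_threshold must lie in (0.5, 1)")
        if self.pca_band_fraction < 0:
            raise ValueError("pca_band_fraction must be >= 0")
        if not 0.5 <= self.twodc_purity <= 1.0:
            raise ValueError("twodc_purity must lie in [0.5, 1]")
        if isinstance(self.rf_cutoff, str) and self.rf_cutoff != "calibrate":
            raise ValueError("rf_cutoff must be a number or 'calibrate'")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class PipelineResult:
    call_matrix: pd.DataFrame
    reports: dict[str, PerformanceReport] | None
    nsc_model: NSCModel
    pca_model: PCAModel
    signature: DirectionalSignature
    rf_cutoff: float
    reference_rf_scores: dict[str, float]
    test_rf: dict[str, object] = field(default_factory=dict)


def run_pipeline(
    reference: ReferencePanel,
    tests: Sequence[FoldChangeProfile],
    config: RunConfig = RunConfig(),
    truth: Mapping[str, str] | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Classify test profiles against a labeled reference panel."""
    nsc_model = fit_nsc(reference, delta=config.delta, priors=config.priors)
    pca_model = fit_pca(reference, band_fraction=config.pca_band_fraction)
    signature = make_signature(nsc_model, universe_size=config.universe_size)

    ref_scores = {
        chem: running_fisher_score(signature, reference.profile(chem)).signed_score
        for chem in reference.chemicals
    }
    if config.rf_cutoff == "calibrate":
        cutoff = calibrate_cutoff(ref_scores, dict(reference.labels))
    else:
        cutoff = float(config.rf_cutoff)

    per_analysis: dict[str, dict[str, ClassCall]] = {"PA": {}, "PCA": {}, "2-DC": {}, "RF": {}}
    rf_results: dict[str, object] = {}
    for prof in tests:
        chem = prof.chemical
        per_analysis["PA"][chem] = pa_call(nsc_model, prof, threshold=config.pa_threshold)
        if config.pca_refit_with_test:
            refit = _refit_pca_with_test(reference, prof, config.pca_band_fraction)
            per_analysis["PCA"][chem] = pca_call(refit, prof)
        else:
            per_analysis["PCA"][chem] = pca_call(pca_model, prof)
        per_analysis["2-DC"][chem] = twodc_call(reference, prof, purity=config.twodc_purity)
        rf = running_fisher_score(signature, prof)
        rf_results[chem] = rf
        per_analysis["RF"][chem] = rf_call(rf, cutoff)

    call_matrix = (
        build_call_matrix(per_analysis, truth=truth)
        if tests
        else pd.DataFrame(columns=list(per_analysis) + list(SCHEMES))
    )

    reports: dict[str, PerformanceReport] | None = None
    if truth is not None and tests:
        truth = {p.chemical: truth[p.chemical] for p in tests}
        reports = {
            scheme: performance(
                {c: call_matrix.loc[c, scheme] for c in call_matrix.index}, truth
            )
            for scheme in SCHEMES
        }

    result = PipelineResult(
        call_matrix=call_matrix,
        reports=reports,
        nsc_model=nsc_model,
        pca_model=pca_model,
        signature=signature,
        rf_cutoff=cutoff,
        reference_rf_scores=ref_scores,
        test_rf=rf_results,
    )
    if outdir is not None:
        _write_artifacts(result, reference, tests, config, Path(outdir))
    return result


def _refit_pca_with_test(
    reference: ReferencePanel, prof: FoldChangeProfile, band_fraction: float
) -> PCAModel:
    """Refit the PCA decomposition with the test profile included (labels
    still come from the reference panel only); mirrors the original plots."""
    import numpy as np

    from .profiles import DDI, NON_DDI

    chem = prof.chemical if prof.chemical not in reference.chemicals else f"{prof.chemical} (test)"
    matrix = reference.matrix.copy()
    matrix[chem] = prof.log2fc.reindex(matrix.index)
    # the test profile carries no label: the decomposition/centering uses the
    # joint matrix, but class separation is measured on the labeled columns
    X = matrix.to_numpy().T
    center = X.mean(axis=0)
    Xc = X - center
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt.T
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    labels = reference.labels.to_numpy()
    ref_scores = (reference.matrix.to_numpy().T - center) @ loadings
    ddi = labels == DDI
    non = labels == NON_DDI
    sep = np.zeros(ref_scores.shape[1])
    for j in range(ref_scores.shape[1]):
        m1, m0 = ref_scores[ddi, j].mean(), ref_scores[non, j].mean()
        n1, n0 = int(ddi.sum()), int(non.sum())
        v1 = ref_scores[ddi, j].var(ddof=1) if n1 > 1 else 0.0
        v0 = ref_scores[non, j].var(ddof=1) if n0 > 1 else 0.0
        pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / max(n1 + n0 - 2, 1)
        gap = abs(m1 - m0)
        sep[j] = np.inf if (pooled == 0 and gap > 0) else (0.0 if pooled == 0 else gap / np.sqrt(pooled))
    j = int(np.argmax(sep))
    m1, m0 = ref_scores[ddi, j].mean(), ref_scores[non, j].mean()
    boundary = 0.5 * (m1 + m0)
    return PCAModel(
        genes=tuple(reference.genes),
        center=center,
        loadings=loadings,
        explained_variance=S**2 / max(X.shape[0] - 1, 1),
        separating_component=j,
        boundary=float(boundary),
        band_halfwidth=float(band_fraction * abs(m1 - m0)),
        ddi_side=float(np.sign(m1 - boundary)) or 1.0,
    )


def _write_artifacts(
    result: PipelineResult,
    reference: ReferencePanel,
    tests: Sequence[FoldChangeProfile],
    config: RunConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.call_matrix.to_csv(outdir / "calls.tsv", sep="\t")
    result.nsc_model.to_json(outdir / "nsc_model.json")

    rf_rows = []
    for chem in sorted(result.test_rf):
        rf = result.test_rf[chem]
        rf_rows.append(
            {
                "chemical": chem,
                "signed_score": rf.signed_score,
                "direction": rf.direction,
                "p_value": rf.p_value,
                "call": result.call_matrix.loc[chem, "RF"],
            }
        )
    pd.DataFrame(
        rf_rows, columns=["chemical", "signed_score", "direction", "p_value", "call"]
    ).to_csv(outdir / "rf_scores.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"chemical": sorted(result.reference_rf_scores),
         "signed_score": [result.reference_rf_scores[c] for c in sorted(result.reference_rf_scores)]}
    ).to_csv(outdir / "rf_reference_scores.tsv", sep="\t", index=False)

    scores = transform(result.pca_model, reference.profiles() + list(tests))
    scores.index.name = "chemical"
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t")

    (outdir / "reference_profiles.nwk").write_text(
        cluster_profiles(reference.profiles()).to_newick() + "\n"
    )
    (outdir / "reference_genes.nwk").write_text(
        cluster_genes(reference.profiles()).to_newick() + "\n"
    )

    if result.reports is not None:
        payload = {
            scheme: {**report.rounded(),
                     "unrounded": {
                         "sensitivity": report.sensitivity,
                         "specificity": report.specificity,
                         "accuracy": report.accuracy,
                         "balanced_accuracy": report.balanced_accuracy,
                     },
                     "tp": report.tp, "fp": report.fp, "tn": report.tn, "fn": report.fn}
            for scheme, report in result.reports.items()
        }
        (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))

    cfg_json = config.to_json()
    log = {
        "package": "tgxddi",
        "version": _version,
        "seed": config.seed,
        "rf_cutoff": result.rf_cutoff,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_reference": len(reference.chemicals),
        "n_test": len(tests),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
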