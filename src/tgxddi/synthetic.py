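"""Synthetic two-class qPCR data with the structure the classifiers assume.

DDI exposures carry a coherent gene signature — a fixed per-gene direction
(up or down) with mean |log2 fold change| equal to ``effect_size`` — while
non-DDI exposures are flat (noise only, optionally plus a small confounder
block emulating metabolically active non-genotoxicants). Noise is Gaussian
on the log2 scale. The Cq simulator inverts the delta-delta-Cq chain:
per-gene control Cq is drawn uniformly in [18, 30] and treatment Cq equals
control minus the target log2 fold change plus noise, with near-constant
reference genes and a block of unexpressed genes forced above the 40-cycle
ceiling so the full ingest path (reference ranking, expression filtering,
fold-change computation) is exercised.

Defaults mirror the study design this generator stands in for: a 64-gene
biomarker panel of which 3 genes are unexpressed on the array (61 retained),
6 candidate reference genes of which 2 are markedly more stable, and a
balanced 14 + 14 reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .foldchange import CqTable
from .profiles import DDI, NON_DDI, FoldChangeProfile, ReferencePanel


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic generator.

    effect_size is the mean |log2 fold change| of DDI-responsive genes;
    noise_sd the per-gene Gaussian SD applied on the log2 (and Cq) scale.
    """

    n_genes: int = 64
    n_reference_genes: int = 6
    n_ddi: int = 14
    n_nonddi: int = 14
    effect_size: float = 4.0
    fraction_up: float = 0.5
    noise_sd: float = 0.25
    n_unexpressed: int = 3
    confounder: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_reference_genes, self.n_ddi, self.n_nonddi) <= 0:
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be >= 0")
        if not 0.0 <= self.fraction_up <= 1.0:
            raise ValueError("fraction_up must lie in [0, 1]")
        if self.n_unexpressed >= self.n_genes:
            raise ValueError("n_unexpressed must leave at least one expressed gene")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def panel_genes(cfg: SimulationConfig) -> list[str]:
    width = len(str(cfg.n_genes))
    return [f"BM{i + 1:0{width}d}" for i in range(cfg.n_genes)]


def unexpressed_genes(cfg: SimulationConfig) -> list[str]:
    return panel_genes(cfg)[cfg.n_genes - cfg.n_unexpressed:]


def reference_genes(cfg: SimulationConfig) -> list[str]:
    return [f"REF{i + 1}" for i in range(cfg.n_reference_genes)]


def signature_directions(cfg: SimulationConfig) -> pd.Series:
    """Per-gene signature sign (+1 up in DDI, -1 down), fixed by the seed."""
    rng = _rng(cfg, 0)
    dirs = np.where(rng.random(cfg.n_genes) < cfg.fraction_up, 1.0, -1.0)
    return pd.Series(dirs, index=panel_genes(cfg))


def _draw_profiles(
    cfg: SimulationConfig,
    n_ddi: int,
    n_nonddi: int,
    rng: np.random.Generator,
    prefix: str = "",
) -> tuple[list[FoldChangeProfile], pd.Series]:
    genes = panel_genes(cfg)
    dirs = signature_directions(cfg).to_numpy()
    profiles: list[FoldChangeProfile] = []
    truth: dict[str, str] = {}
    conf_block = slice(0, max(cfg.n_genes // 8, 1))  # genes perturbed by the confounder
    for i in range(n_ddi):
        name = f"{prefix}DDI_{i + 1:02d}"
        fc = dirs * cfg.effect_size + rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
        profiles.append(FoldChangeProfile(name, pd.Series(fc, index=genes)))
        truth[name] = DDI
    for i in range(n_nonddi):
        name = f"{prefix}NON_{i + 1:02d}"
        fc = rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
        if cfg.confounder:
            fc[conf_block] += dirs[conf_block] * cfg.effect_size * 0.5
        profiles.append(FoldChangeProfile(name, pd.Series(fc, index=genes)))
        truth[name] = NON_DDI
    return profiles, pd.Series(truth)


def simulate_panel(cfg: SimulationConfig) -> tuple[ReferencePanel, pd.Series]:
    """Labeled reference panel of n_ddi + n_nonddi fold-change profiles."""
    profiles, truth = _draw_profiles(cfg, cfg.n_ddi, cfg.n_nonddi, _rng(cfg, 1))
    return ReferencePanel.from_profiles(profiles, dict(truth)), truth


def simulate_test_profiles(
    cfg: SimulationConfig,
    n_ddi: int,
    n_nonddi: int,
    seed: int | None = None,
) -> tuple[list[FoldChangeProfile], pd.Series]:
    """Held-out profiles sharing the panel's gene signature directions.

    Drawn from an independent noise stream so they never duplicate the
    training panel; ``seed`` defaults to the config seed.
    """
    stream = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed if seed is None else seed), 3])
    )
    return _draw_profiles(cfg, n_ddi, n_nonddi, stream, prefix="TEST_")


@dataclass(frozen=True)
class CqSimulation:
    """Cq table plus the ground truth it encodes."""

    cq: CqTable
    target_log2fc: pd.DataFrame  # expressed panel genes x chemicals
    truth: pd.Series             # chemical -> class
    reference_genes: tuple[str, ...]


def simulate_cq_table(cfg: SimulationConfig, n_replicates: int = 2) -> CqSimulation:
    """Cq table inverting the ddCq chain for the configured panel.

    Reference genes get per-sample noise SDs of ``noise_sd`` scaled by
    [0.01, 0.01, 1.0, 1.5, 2.0, ...]: the first two are near-constant, so
    stability ranking should select them. Unexpressed genes read 41 cycles
    (above the 40 ceiling) in every sample. At noise_sd = 0 the ddCq chain
    recovers ``target_log2fc`` exactly.
    """
    rng = _rng(cfg, 2)
    genes = panel_genes(cfg)
    refs = reference_genes(cfg)
    unexpr = set(unexpressed_genes(cfg))
    expressed = [g for g in genes if g not in unexpr]
    dirs = signature_directions(cfg)

    chems = [f"DDI_{i + 1:02d}" for i in range(cfg.n_ddi)] + [
        f"NON_{i + 1:02d}" for i in range(cfg.n_nonddi)
    ]
    truth = pd.Series(
        {c: (DDI if c.startswith("DDI") else NON_DDI) for c in chems}
    )
    target = pd.DataFrame(
        {
            c: (dirs.loc[expressed] * cfg.effect_size if truth[c] == DDI else 0.0)
            for c in chems
        },
        index=pd.Index(expressed, name="gene"),
        dtype=float,
    )

    control_base = pd.Series(rng.uniform(18.0, 30.0, len(genes)), index=genes)
    ref_base = pd.Series(rng.uniform(18.0, 25.0, len(refs)), index=refs)
    ref_scale = np.array([0.01, 0.01] + [1.0 + 0.5 * i for i in range(len(refs) - 2)])

    sample_rows = []
    columns: dict[str, pd.Series] = {}

    def make_sample(sample_id: str, chem: str, role: str, rep: int, fc: pd.Series) -> None:
        cq = pd.Series(index=genes + refs, dtype=float)
        cq[genes] = (
            control_base[genes]
            - fc.reindex(genes).fillna(0.0)
            + rng.normal(0.0, cfg.noise_sd, len(genes))
        )
        cq[refs] = ref_base + rng.normal(0.0, 1.0, len(refs)) * cfg.noise_sd * ref_scale
        cq[list(unexpr)] = 41.0
        columns[sample_id] = cq
        sample_rows.append(
            {"sample_id": sample_id, "chemical": chem, "role": role,
             "vehicle": "DMSO", "replicate": rep}
        )

    zero = pd.Series(0.0, index=genes)
    for rep in range(1, n_replicates + 1):
        make_sample(f"CTRL_r{rep}", "vehicle", "control", rep, zero)
    for chem in chems:
        fc = zero.copy()
        fc[expressed] = target[chem]
        for rep in range(1, n_replicates + 1):
            make_sample(f"{chem}_r{rep}", chem, "treatment", rep, fc)

    values = pd.DataFrame(columns).reindex(genes + refs)
    sheet = pd.DataFrame(sample_rows).set_index("sample_id")
    return CqSimulation(
        cq=CqTable(values, sheet),
        target_log2fc=target,
        truth=truth,
        reference_genes=tuple(refs),
    )
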