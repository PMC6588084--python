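# tgxddi

Classification of chemicals as DNA damage-inducing (DDI) or non-DDI from
qPCR expression profiles of the TGx-DDI transcriptomic biomarker.

The TGx-DDI biomarker is a 64-gene expression signature, derived in TK6
human lymphoblastoid cells, that separates genotoxic (DDI) from
non-genotoxic (non-DDI) chemical exposures. Measuring it with TaqMan qPCR
arrays instead of whole-transcriptome microarrays makes the biomarker
usable in any molecular biology lab; this package implements the complete
analysis chain for that setting, for genetic toxicologists and
bioinformaticians screening chemicals:

1. **ΔΔCq fold changes** — reference genes are ranked by Cq stability
   (SD across all samples), unexpressed genes (Cq > 40 in a majority of
   samples) are excluded, and per-chemical log2 fold changes are computed
   as log2FC = −ΔΔCq with ΔΔCq = ΔCq(treatment) − ΔCq(matched vehicle
   control), ΔCq = Cq − mean(reference-gene Cq).
2. **Four classifiers** against a labeled reference panel:
   * **NSC probability analysis (PA)** — nearest shrunken centroids
     (d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s0)), soft-thresholded by Δ), with a
     class assigned when the posterior membership probability exceeds 0.90;
   * **PCA** — projection onto the principal component best separating the
     two class clouds, with a midpoint boundary and an inconclusive band;
   * **2-D clustering (2-DC)** — average-linkage/Euclidean agglomeration;
     the test chemical takes the class of the branch it first joins;
   * **Running Fisher** — a directional rank-based correlation between the
     biomarker signature and the query profile: nested top-k prefixes of
     the ranked query are tested for overlap with the up/down signature by
     one-sided Fisher exact tests, combined into a signed −log10(P); the
     decision cutoff is calibrated on the reference set as the largest
     threshold with zero false negatives.
3. **Aggregation and metrics** — one DDI call from any analysis makes the
   overall call DDI; otherwise one non-DDI call makes it non-DDI;
   sensitivity/specificity/accuracy/balanced accuracy are reported with
   inconclusive verdicts counted as incorrect.

A synthetic-data module generates two-class Cq tables and fold-change
panels (coherent up/down signature for DDI, flat profiles for non-DDI,
Gaussian log2-scale noise, stable reference genes, an unexpressed-gene
block) so the whole pipeline is testable without any download. The real
qPCR dataset the defaults emulate is available from GEO as GSE121532.

## Worked example

```python
from tgxddi import (SimulationConfig, simulate_panel, simulate_test_profiles,
                    run_pipeline)

cfg = SimulationConfig(effect_size=4.0, noise_sd=0.25, seed=11)
panel, _ = simulate_panel(cfg)                      # 14 DDI + 14 non-DDI
tests, truth = simulate_test_profiles(cfg, 3, 3, seed=12)
result = run_pipeline(panel, tests, truth=dict(truth))
print(f"RF cutoff: {result.rf_cutoff:.1f}")
print(result.call_matrix[["PA", "PCA", "2-DC", "RF", "three_pronged"]])
```

prints

```
RF cutoff: 30.7
                  PA      PCA     2-DC       RF three_pronged
chemical
TEST_DDI_01      DDI      DDI      DDI      DDI           DDI
TEST_DDI_02      DDI      DDI      DDI      DDI           DDI
TEST_DDI_03      DDI      DDI      DDI      DDI           DDI
TEST_NON_01  non-DDI  non-DDI  non-DDI  non-DDI       non-DDI
TEST_NON_02  non-DDI  non-DDI  non-DDI  non-DDI       non-DDI
TEST_NON_03  non-DDI  non-DDI  non-DDI  non-DDI       non-DDI
```

The RF cutoff (30.7) is the smallest signed −log10(P) among the DDI
reference profiles — the largest threshold that produces no false
negatives on the reference set. Every test chemical is called correctly by
all four analyses at this strong effect size, so the aggregated
three-pronged verdicts match the simulated truth. `result.reports`
contains per-scheme confusion counts and percentages.

A command-line interface mirrors the library
(`tgxddi simulate | foldchange | train | classify | runfisher | evaluate`);
see `tgxddi --help`.

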