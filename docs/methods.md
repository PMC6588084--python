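# Methods

This note documents the models and procedures implemented in `tgxddi`, the
choices made where the underlying analysis left the design open, and what
the synthetic data used for testing does and does not establish.

## The classification problem

A test chemical's expression profile over the TGx-DDI biomarker genes
(log2 fold changes relative to a matched vehicle control, measured at 4 h
in TK6 cells) is compared to a labeled reference panel of DDI and non-DDI
exposures. Four statistical analyses each produce a per-chemical verdict
in {DDI, non-DDI, inconclusive}; verdicts are aggregated conservatively
(one DDI call wins). The package treats the gene panel as given: it does
not re-derive the biomarker by cross-validated gene selection, which is
the original signature-discovery contribution, not this tool's.

## ΔΔCq fold changes

`foldchange` implements the standard comparative-Cq chain. Decisions:

* **Reference-gene stability** is the sample SD of raw Cq pooled over all
  samples (treatments and controls). The SD is computed two-pass so a
  constant gene scores exactly 0; ties rank alphabetically.
* **Replicates** are averaged on the ΔCq scale (arithmetic mean), the
  standard practice for comparative Cq; averaging on the linear 2^−ΔCq
  scale would bias fold changes upward under noise. Technical replicates
  are accepted but not required.
* **Undetermined Cq** is carried as NaN. For the unexpressed-gene filter
  a cell counts as unexpressed when it is NaN *or* above the 40-cycle
  ceiling; a gene is excluded when the unexpressed fraction strictly
  exceeds 0.5 (both parameters configurable). Undetermined values never
  enter ΔΔCq arithmetic — computing fold changes over an unfiltered panel
  that still contains NaN is an error, not an imputation.
* **Control matching** is by the vehicle-solvent label in the sample
  sheet; a treatment whose solvent has no control sample is an error at
  ingest. Gene symbols are upper-cased on ingest everywhere.

## Nearest shrunken centroids and the probability analysis

`nsc` implements the classical two-class shrunken-centroid model: pooled
within-class SD s_i with n − K degrees of freedom, fudge s0 = median(s_i),
m_k = sqrt(1/n_k − 1/n), standardized distances d_ik soft-thresholded by
Δ, and Gaussian discriminant scores δ_k(x) = Σ_i (x_i − x̄'_ik)²/(s_i+s0)²
− 2 log π_k converted to posteriors with a log-sum-exp shift (stable for
|δ| far beyond 1e4). Defaults:

* **Δ = 0.** The 64-gene panel was already selected by NSC upstream, so
  no further shrinkage is applied when re-fitting on qPCR profiles; Δ is
  exposed for experimentation.
* **Equal priors** (0.5/0.5), matching the balanced 14 + 14 reference
  design; proportional priors are available.
* Profiles enter as log2 fold changes without centering or rescaling —
  class centroids are plain per-gene averages of the reference profiles.
* The PA threshold is a strict "> 0.90" on the membership probability;
  neither class exceeding it yields inconclusive. The reported score is
  always the DDI probability.
* Distinct treatments of one agent (e.g. two ethanol concentrations) are
  separate training observations under separate profile labels.

Model state serializes to JSON; floats round-trip exactly.

## PCA classifier

The original analysis read class membership off a scatterplot. The
formalization here — the module's chief deliberate design decision — is a
one-dimensional rule: profiles are centered (not scaled, matching prcomp
defaults) with the reference-panel means and decomposed by SVD; the
separating component maximizes |mean(DDI) − mean(non-DDI)| / pooled
within-class SD of the scores; the boundary is the midpoint of the class
means, and scores within 0.1 × |mean separation| of the boundary are
inconclusive. The band fraction has no published value; 0.1 was chosen
once as a visually "on the border" margin and is configurable. By default
test profiles are projected with the stored centering (a fixed, reusable
model); `pca_refit_with_test` refits the decomposition with the test
profile included, for fidelity to the original plots which re-ran PCA per
test chemical. Component signs follow a largest-loading-positive
convention so runs are reproducible.

## Two-dimensional clustering

UPGMA (average linkage) on Euclidean distances between log2 fold-change
vectors, written out explicitly so ties between equal merge distances
break deterministically by lexicographic label pair. The "branches with"
judgment is formalized as first-join purity: cluster the reference panel
plus the single test profile, find the first ancestor of the test leaf
whose complementary subtree contains reference profiles, and call the
test by that subtree's class when pure. The purity threshold defaults to
1.0 (any mixing → inconclusive) and can be relaxed to a majority rule.
Joining only at the root with both classes below is inconclusive. One
test chemical is clustered at a time. Gene-axis clustering (for heatmap
row ordering) applies the same algorithm to the transposed matrix.
Dendrograms export to Newick with merge-height branch lengths.

## Running Fisher correlation

The commercial implementation of the rank-based signature-correlation
test is proprietary, so the published scheme is operationalized as: split
the signature (direction per gene = sign of the DDI − non-DDI shrunken
centroid difference, weight = its magnitude) and the query (by sign of
log2FC, ranked by |log2FC|, ties alphabetical) into up/down parts; for
each of the four part pairs scan every prefix k = 1..m of the query part,
take the minimal hypergeometric upper-tail P of the prefix/signature
overlap given the gene universe, and Bonferroni-multiply by the number of
prefixes scanned (capped at 1); combine the two concordant pairs by
Fisher's method into a positive-correlation P and the two discordant
pairs into a negative one; report the smaller as signed −log10(P). Exact
numeric equality with the proprietary scores (including any particular
published cutoff value) is not promised — the classification *procedure*
is what is reproduced. The universe defaults to the retained panel size
(the genes actually measured on the array) and is configurable to a
platform-wide count. Degenerate inputs: zero-log2FC genes carry no
direction and join neither query part; no informative overlap anywhere
gives P = 1, direction positive by convention, score 0; P is floored at
the smallest positive double so scores stay finite.

The cutoff calibration mirrors the published procedure: on the labeled
reference scores, the cutoff is the minimum score among true-DDI
chemicals — the largest threshold with zero false negatives under the
"DDI iff score ≥ cutoff" rule (ties at the cutoff are DDI). The RF call
is always dichotomous.

## Aggregation and metrics

Any DDI call → DDI; else any non-DDI call → non-DDI; else inconclusive.
Supported schemes: three-pronged (PA+PCA+2-DC), RF alone, three-pronged
+RF, and each single analysis +RF. In metrics an inconclusive overall
verdict counts as an incorrect call for the chemical's true class, so
TP+FN and TN+FP always equal the class sizes; this convention is required
for the confusion counts to match the published per-analysis rates (e.g.
a PA sensitivity of 5/8 when one true-DDI chemical was inconclusive).
Percentages are rounded half-up to integers (87.5 → 88); balanced
accuracy is computed from the unrounded sensitivity and specificity
before rounding (90.625 → 91).

The published per-chemical aggregated calls and class labels of the qPCR
validation study (GEO GSE121532) are embedded in `tgxddi.validation`;
reference-set calls are reconstructed from the study's named
misclassifications. Where the study's prose total ("18 accurately
classified") disagrees with its own counts (6/8 + 13/16 = 19), the counts
are used; where a figure caption's class split (13/15) disagrees with the
design table (14/14), the design table is used.

## Synthetic data

The generator emulates the structure the classifiers assume: a fixed
per-gene signature direction (fraction up-regulated 0.5 by default), DDI
profiles at ±effect_size per gene plus N(0, noise_sd²) on the log2 scale,
non-DDI profiles as pure noise (an optional half-strength confounder
block on one-eighth of the genes, off by default, emulates
misclassification-prone metabolic modulators). Defaults are the emulated
study's design: 64 panel genes with 3 unexpressed (61 retained), 6
candidate reference genes of which 2 are near-constant, 14 + 14 reference
profiles. Effect size 4 and noise SD 0.25 describe a strong, clean
signature — the regime in which the parameter-recovery checks require
each classifier to reach balanced accuracy ≥ 0.95 over 200 held-out
profiles. The Cq simulator inverts the ΔΔCq chain (control Cq uniform in
[18, 30], treatment = control − target log2FC + noise) and is exact at
zero noise.

What the synthetic data does **not** capture: gene–gene correlation,
chemical-specific response heterogeneity, qPCR efficiency differences,
plate/batch effects, and heavy-tailed technical noise. Passing the
recovery checks therefore demonstrates the correctness and calibration of
the machinery under its own assumptions, not field performance on real
chemical exposures.

## Problem sizes and determinism

Test-suite and acceptance-script simulations use 28-profile training
panels and 200-profile test sets — the scale of the emulated study — and
small random instances (5-gene panels, universes ≤ 30, 6-profile
clusterings) for the brute-force oracle comparisons. All randomness flows
through seeded NumPy generators; pipelines rerun byte-identically given
the same inputs, configuration and seed.

## Known limitations

* The Running Fisher scores are one faithful operationalization of the
  published scheme, not a clone of the proprietary engine; calibrated
  cutoffs are therefore dataset- and implementation-specific.
* The PCA band width and 2-DC purity threshold formalize visual
  judgments; different choices move borderline chemicals between
  "inconclusive" and a class.
* With a single test profile the 2-DC walk reduces to the test leaf's
  first merge; joint clustering of many unknown chemicals at once is not
  the supported workflow (one test at a time, as in the emulated study).
* No qPCR efficiency correction or melt-curve QC; Cq values are taken at
  face value.
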