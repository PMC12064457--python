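# Methods

This note records the models and procedures the package implements, the
parameter choices that matter, what the synthetic cohort does and does
not emulate, and the numerical decisions a maintainer would otherwise
have to reverse-engineer.

## Measurement model and preprocessing

A liquid-urine ATR-FTIR measurement is treated as

    A(ν) = s · Σ_b amp_b · exp(−(ν − c_b)² / 2σ_b²)
         + offset + slope·(ν − ν_mid) + fringe(ν) + ε(ν)

per replicate: a sum of Gaussian absorption bands scaled by a
multiplicative scatter factor `s` (uncontrolled effective path length on
the ATR crystal), a linear baseline, an etalon-type sinusoidal fringe,
and white noise whose standard deviation is `noise_sd/√scans`
(24-scan co-addition emulated as noise reduction rather than simulated
interferograms). Real bands are Voigt-like rather than Gaussian; the
Gaussian choice keeps closed-form expectations for every planted effect
and is immaterial to the pipeline's statistics.

Preprocessing follows the standard chemometric chain, in the order in
which the physical artefacts enter:

1. technical replicates are averaged (they share the patient's
   composition and differ only in measurement artefacts);
2. the double-distilled-water reference spectrum is subtracted at fixed
   unit scale — no automated scaling, as the liquid film is
   water-dominated in both sample and reference;
3. ten Savitzky–Golay smoothing passes followed by one first-derivative
   pass, both with a second-degree polynomial. The window length is 11
   points (1 cm⁻¹ grid); it is not dictated by the protocol and is
   configurable. Derivatives are reported with respect to the
   wavenumber axis (negated once per order on the descending storage
   convention). Edges use polynomial extension (the first/last full
   window's fit), so any polynomial of degree ≤ 2 is reproduced exactly
   everywhere — this is also what makes the brute-force per-window
   least-squares oracle an exact test.
   A derivative order of 0 skips the derivative pass entirely, so the
   zero-work configuration is the identity.
4. SNV row normalisation with the sample (ddof = 1) standard deviation —
   the dominant chemometric convention; the alternative differs only by
   a row-constant factor.

## Latent-variable evaluation

OPLS uses the canonical Trygg–Wold deflation: per component, the unit
predictive weight `w ∝ X'y`, scores `t = Xw`, loading `p = X't/t't`,
orthogonal weight `w_o ∝ p − (w'p)w`, and removal of `t_o p_o'`. Each
orthogonal score is orthogonal to the centred response by construction,
asserted numerically at 1e-8. Twenty components are extracted by
default; extraction stops early with a warning if no orthogonal
variation remains. The filter is fitted on the training fold only and
applied to held-out data through the stored training means — fitting it
on the whole dataset (the published description) is available as
`paper_mode` and is used only for comparison, since whole-data fitting
leaks test-fold structure. The filtered matrix is assessed by PLS
regression (NIPALS, 2 components, scikit-learn backend) of the 0/1
label, scored by R², accuracy at the 0.5 decoded threshold, and ROC AUC.

A measured property worth recording: after 20 orthogonal components
essentially every spectral column carries the shared predictive score
(column-label correlations ≈ 0.95 across the whole grid). OPLS
therefore *improves* the latent-space evaluation while *destroying*
per-wavenumber feature identity. For this reason the forest and the
Shapley attribution operate on the preprocessed (non-OPLS) matrix; the
OPLS filter serves the PLS branch.

## Classification protocol

Stratified 70/30 split with largest-remainder per-class allocation
(206/103 at 0.30 gives exactly 62 + 31 = 93 test samples), seeded and
reproducible; class weights `w_c = N/(2 n_c)`; random forest with the
tuned configuration (21 trees, depth ≤ 4, min split 8, min leaf 2, Gini;
Gini and entropy were interchangeable in tuning and behave
indistinguishably here). All randomness flows from declared seeds; the
protocol seed is 333. The evaluation surface computes every metric from
the confusion counts with both classes as positive label; 0/0 ratios
are reported as 0 with a degeneracy flag so cross-validation never
aborts. Grid search (10-fold stratified, support-weighted F1 scorer,
ties broken by declared grid order), a four-family model comparison
(shared 5-fold splits) and a learning curve are provided as audit
instruments.

## Attribution and biomarker selection

Shapley values are computed exactly per tree with the path-dependent
polynomial-time algorithm (EXTEND/UNWIND bookkeeping over root-to-leaf
paths) on the class-1 probability, averaged over the ensemble; the
implementation is validated against an exponential-time
subset-enumeration oracle on small ensembles, and additivity
(base + Σφ = predicted probability) is asserted on every fitted forest
in the tests.

Wavenumbers are ranked by mean |φ|. Selection is greedy with a merge
window: a candidate within `merge_window` of an already-selected
wavenumber is skipped. The default window is 10 cm⁻¹ — about half the
FWHM of a σ = 6 cm⁻¹ band on the 1 cm⁻¹ grid — so one physical band
yields one selected frequency; a 2 cm⁻¹ window (enough to merge
adjacent grid points such as 1773/1774) is available where genuinely
adjacent peaks must be resolved. The relevance floor defaults to 1 % of
the maximum importance; the count of wavenumbers above it is reported
but is cohort-specific by nature.

Selected frequencies are confirmed on the raw water-subtracted
absorbances (pre-derivative, pre-SNV) by two-group Kruskal–Wallis tests
at α = 0.05 — a Shapiro–Wilk gate on the top selected column documents
the non-normality motivating the nonparametric route — with the group
direction taken from medians. Stability re-runs split + fit +
attribution across seeds and reports per-seed top-k lists and their
mean pairwise Jaccard overlap.

## Synthetic cohort: what is planted and why

Structure copies the study: 206 controls, 103 cancers (with the
subtype composition 29/10/31/32/1 carried as metadata), 3 replicates,
24 scans, 4000–400 cm⁻¹ at 1 cm⁻¹ (3601 points). Background: water O–H
stretch (~3350 cm⁻¹) and H–O–H bend (~1640 cm⁻¹), urea (~1460 cm⁻¹) and
creatinine (~1160 cm⁻¹) bands with between-patient variability; the
standalone water reference contains the water bands only.

Each biomarker is planted as two components centred on the nominal
wavenumber:

- a **narrow band** (σ = 6 cm⁻¹) whose *position* separates the classes
  (control at centre + δ/2, cancer at centre − δ/2, δ = 4.5 cm⁻¹).
  A first derivative of a symmetric band has a node at its centre, so a
  pure intensity difference carries *no* derivative-space signal there;
  a position difference is the mechanism that puts the derivative-space
  class signal extremum exactly at the band centre. Disease-associated
  IR bands are known to shift as well as change intensity.
- a **broad envelope** (σ = 20 cm⁻¹) whose *intensity* separates the
  classes (control higher). This carries the raw-absorbance group
  difference at the centre that the Kruskal–Wallis confirmation and the
  "control-higher" direction rest on, while its symmetric derivative
  contributes nothing at the centre.

Between-patient variability includes band amplitude, position
(≈ 0.2–1 cm⁻¹) and width jitter, baseline offset/slope, scatter
(0.97–1.03) and fringes (amplitude 6 mAU, period 30–45 cm⁻¹). The
fringes matter: ten smoothing passes suppress white noise by an order
of magnitude in derivative space while the raw-space confirmation sees
it at full strength, so broadband-correlated baseline structure is the
only realistic noise source that sets the derivative-space SNR without
destroying the raw-space effect size.

Effect sizes are calibrated once (see `analysis/00_calibrate_effect.py`)
to a pooled Cohen's d ≈ 2.5 at the band centres on raw water-subtracted
absorbance (achieved ≈ 2.5 at 1773, ≈ 2.1–2.3 at 2093 across cohort
draws), which places the pipeline's classification metrics at the
published levels.

What the generator does **not** model: Voigt/Lorentzian line shapes,
ATR penetration-depth dispersion, atmospheric CO₂/water-vapour lines,
urine dilution and dietary composition variance, pH-dependent band
repositioning beyond white jitter, and instrument drift between
sessions. Passing tests therefore certify the *pipeline's statistics*
under a controlled measurement model, not clinical performance on real
urine spectra.

## Numerical choices and degenerate inputs

- Grids are strictly descending, uniform to 1e-9 cm⁻¹; files parsed at
  text precision (1e-6) are re-canonicalised with `linspace`.
- SNV of a zero-variance row, single-class metric inputs, off-grid
  wavenumber lookups (beyond one grid spacing) and fold counts
  exceeding the minority class all raise typed errors naming the
  offending quantity; 0/0 metric cells inside cross-validation are
  flagged, not fatal.
- Kruskal–Wallis on identical values returns H = 0, p = 1 instead of
  erroring, so wavenumber scans never abort. The χ² p-value at very
  small samples (N = 12) deviates from the exact permutation p by up to
  ≈ 0.07 — measured by exhaustive enumeration and pinned in the tests.
- Ranking tie-break: ascending column index; grid-search tie-break:
  declared grid order. Both for determinism.

## Known limitations

- **Per-column attribution granularity.** The derivative chain makes
  neighbouring columns of one band highly redundant (clusters ±3–4 cm⁻¹
  wide). The 21-tree, depth-4 forest draws √p ≈ 60 of 3601 features per
  node, so only a handful of split events land inside each band's
  cluster, and the per-column Shapley maximum wanders by ±3–4 cm⁻¹
  between reruns even though the empirical per-column effect-size
  maximum sits at the centre (±1 cm⁻¹) in every tested cohort. Band-level
  selection (merge window 10 cm⁻¹) is stable across seeds; grid-point-
  level selection is reproducible only to a few cm⁻¹. A larger ensemble
  or a column-integrating ranker would sharpen this, at the cost of
  leaving the study's tuned configuration.
- The null-cohort false-positive scan is overdispersed relative to
  binomial because wavenumber columns share patient-level baseline and
  fringe factors; the test averages over independent cohorts.
- The PLS "accuracy" threshold (0.5 on the decoded label scale) is a
  convention; class-imbalanced thresholds are out of scope.
- Whether the 20 orthogonal components were tuned or conventional in
  the original protocol is unknown; they are treated as fixed.
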