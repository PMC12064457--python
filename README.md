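# uroftir

Chemometric screening of **liquid urine ATR-FTIR spectra** for binary
cancer detection: spectral preprocessing, orthogonal latent-variable
filtering, random-forest classification and Shapley-based spectral
biomarker discovery — exercised end-to-end on a synthetic cohort that
copies the structure of a 309-patient gynaecological-oncology study
(206 benign controls, 103 cancer patients, three technical replicates per
patient, 24 scans averaged per replicate, 4000–400 cm⁻¹).

Mid-infrared spectra of untreated liquid urine are dominated by water,
yet carry weak solute absorptions that shift with disease state. The
question this pipeline answers is whether a standard chemometric stack
can (a) classify cancer vs. benign from such spectra and (b) point to the
wavenumbers that carry the signal — here the planted marker bands at
**1773 cm⁻¹** (carbonyl / amide I region) and **2093 cm⁻¹** (nitrile /
amine N–H region), both *more* absorbing in controls than in cancer.

## The method

For patient $i$ with replicate spectra $a_{ir}(\nu)$ and a
double-distilled-water reference $w(\nu)$:

1. **Averaging & background** — $x_i(\nu) = \tfrac1R\sum_r a_{ir}(\nu) - w(\nu)$.
2. **Savitzky–Golay conditioning** — ten smoothing passes (order-2
   polynomial, 11-point window), then one first-derivative pass
   ($\partial A/\partial\nu$), removing additive baselines.
3. **SNV** — each row is centred and scaled to unit standard deviation,
   removing multiplicative scatter: $x \mapsto (x-\bar x)/s_x$.
4. **OPLS → PLS evaluation** — orthogonal projections to latent
   structures (Trygg–Wold deflation, 20 orthogonal components, fitted on
   the training fold) strip label-orthogonal variation before a
   2-component PLS regression of the 0/1 label; scored by $R^2$,
   thresholded accuracy and ROC AUC, with and without the filter.
5. **Random forest** — stratified 70/30 split (largest-remainder
   allocation, protocol seed 333), inverse-frequency class weights
   $w_c = N/(2n_c)$, and the tuned configuration: 21 trees, maximum depth
   4, minimum split 8, minimum leaf 2, Gini impurity.
6. **Attribution** — exact path-dependent tree-Shapley values of the
   class-1 probability (additive: $\phi_0+\sum_j\phi_{ij}=P(1\mid x_i)$);
   wavenumbers ranked by mean $|\phi|$, merged top-3 selection (bands
   within 10 cm⁻¹ count once).
7. **Confirmation** — Kruskal–Wallis rank tests of the selected
   wavenumbers on the *raw* water-subtracted absorbances (a Shapiro–Wilk
   gate justifies the nonparametric route), with the control-vs-cancer
   direction from group medians.

Because the clinical spectra are not publicly available, the package
ships a first-class synthetic cohort generator (`uroftir.synthetic`):
Gaussian water/urea/creatinine bands, etalon-type baseline fringes,
per-patient amplitude/position/width variability, scan-noise averaging,
and two planted marker bands whose position and intensity separate the
classes (calibrated to a raw-absorbance effect size of roughly
Cohen's d ≈ 2.5 at the band centres).

## Worked example

```python
from uroftir import generate_cohort, cohort_to_set, run_pipeline, PipelineConfig

cohort = generate_cohort()                 # 206/103 cohort, seed 333
raw = cohort_to_set(cohort)                # average replicates, subtract water
report = run_pipeline(raw, PipelineConfig())

m = report.forest_metrics
print(m.accuracy, m.weighted_f1, m.precision)
print(report.attribution.selected_top)
print({w: r["direction"] for w, r in report.attribution.kw_results.items()})
```

On the shipped default cohort this prints (93-sample held-out split,
confusion counts tp=31, tn=61, fp=1, fn=0):

```
0.989247311827957 0.9892687657300962 {1: 0.96875, 0: 1.0}
[1774.0, 1785.0, 2094.0]
{1774.0: 'control-higher', 1785.0: 'control-higher', 2094.0: 'control-higher'}
```

i.e. 98.9 % accuracy and weighted F1, perfect control-class precision,
and top Shapley frequencies at 1774 and 2094 cm⁻¹ — one grid point from
the planted 1773/2093 cm⁻¹ markers — all confirmed significantly higher
in controls by Kruskal–Wallis on the raw absorbances
(p < 10⁻⁴²). The PLS evaluation gives $R^2 = 0.93$ without and $0.98$
with the OPLS filter (AUC 1.0 in both cases).

The numbered drivers under `analysis/` run each stage as a narrative
(generation, preprocessing checks, latent models, classification with
model comparison and learning curve, attribution with stability, and the
null-cohort negative control) and write their tables under `results/`.

A `uroftir` console script wraps the same pipeline for on-disk cohorts
(`uroftir generate`, `uroftir preprocess`, `uroftir run`,
`uroftir report`; data-point-table `.dpt` spectra + `metadata.csv` +
`water.dpt`).

## Layout

```
src/uroftir/      spectra.py (.dpt I/O, replicate averaging, background)
                  preprocess.py (Savitzky-Golay, SNV)
                  latent.py (OPLS, PLS, R2, ROC/AUC)
                  classify.py (split, weights, forest, metrics, comparison)
                  treeshap.py (exact tree-Shapley values)
                  attribute.py (ranking, merging, Kruskal-Wallis, PCA, bands)
                  synthetic.py (cohort generator), pipeline.py, cli.py
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   model assumptions, parameter choices, limitations
```
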