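# Methods

`nucitox` quantifies how much the *method* used to measure cell viability —
a metabolic assay (XTT), manual trypan-blue counting (TB), or image-based
nuclei counting (Hoechst stain or an H2B-mRuby nuclear reporter) — changes
the dose-response metrics derived from a drug screen, and implements the
image-analysis chain that explains the main source of disagreement:
drug-induced changes in per-cell mitochondrial activity. Everything is
validated against synthetic data with known ground truth; this note records
the models, the defaults, and what the synthetic validation does and does
not establish.

## Dose-response model and metrics

True surviving cell number under a drug follows a constrained logistic in
concentration,

    N(c) = N0 * (1 - emax * occ(c)),      occ(c) = (c/IC50)^h / (1 + (c/IC50)^h)

with `emax = 1` (full kill at saturation) as the default; `emax < 1` models
cytostatic agents whose cell numbers floor at `(1 - emax) * N0`. Viability
is normalized to the vehicle control as percent; XTT wells are
blank-corrected with medium+reagent wells first. Values above 100% are kept
(metabolic assays genuinely over-report at some sub-toxic doses); negative
values are floored at zero and logged.

**IC50** is fitted by least squares of `V(c) = 100 / (1 + (c/IC50)^h)` on
`x = log10 c` — top and bottom asymptotes fixed at 100 and 0, so only the
midpoint and hill slope are free. The optimizer is multi-start (a grid of
midpoint/slope starts screened by residual sum of squares, the best three
polished with an analytic-Jacobian trust-region fit, tolerance 1e-10 on the
RSS). If the fitted midpoint exceeds the largest tested concentration the
IC50 is *censored* at `> c_max`; correlation analyses rank censored values
above every numeric IC50, tied among themselves. This cap is deliberately
more stable than reporting the extrapolated midpoint, and the stability
matters for the consistency results below.

**AUC** is the trapezoidal integral of mean viability over the tested
`log10 c` range, divided by the range width — i.e. mean viability on a
0–100 scale. The log axis was chosen because doses are log-spaced and the
integral is then invariant to re-labelling of units; a linear-axis variant
would change absolute values but not within-study comparisons.

## The XTT bias model

The XTT readout is modelled as `N(c) * phi(c)`: signal per cell times cell
number. The per-cell factor is occupancy-scaled by default,

    phi(c) = 1 + (phi_max - 1) * occ(c)

so untreated cells show no bias and the distortion of *apparent* viability,
`(phi_max - 1) * occ * (N/N0)`, peaks mid-curve — matching the empirical
observation that metabolic over-reporting is largest at doses that only
partially suppress proliferation. A constant-factor variant
(`phi_toxic_only=False`) is kept for closed-form tests. Combined with
`emax < 1`, a cytostatic metabolic-boosting drug produces XTT curves that
plateau above 50% apparent viability while counting methods cross it — the
mechanism behind censored XTT IC50s.

## Cross-method consistency study conditions

The simulated screening panel (`sample_consistency_panel`) uses 4 methods ×
4 cell lines × 8 drugs, 2 replicates, 5% XTT coefficient of variation.
Per-drug dose windows are 8 points spanning 2.2 decades, centred within
±0.4 decades of the drug's typical potency (real screens choose ranges from
literature, not from the line being tested); per-line IC50s scatter
log-normally (SD 0.5 decades) around that potency. Three of the eight drugs
are potent cytostatic metabolic boosters (`emax` 0.5–0.75, `phi_max`
1.6–2.5, potency drawn from the low end) — mirroring the cell-cycle
inhibitors and kinase inhibitors that drive method disagreement in
practice; the rest are cytotoxic with at most mild bias. Trypan-blue values
are Poisson counts of a ~200-cell hemocytometer aliquot (manual counting is
far noisier than the well population); imaging methods count Poisson nuclei
per field (6 fields/well, ~100 nuclei per control field), with the
H2B-mRuby count binomially thinned by the line's transduction fraction.

Under these conditions the mean pairwise Spearman correlation of AUC across
methods exceeds that of IC50 in ~90% of panels. The driver is one-sided:
censoring turns potent-but-plateauing XTT curves into top-tied IC50 ranks
that disagree with counting methods, while AUC degrades only linearly with
the bias. When the biased drugs happen to be weak, IC50 rankings survive
censoring and the two metrics tie — which is why the advantage is a
frequency over panels, not a uniform ordering.

## Image pipeline

*Illumination correction* fits a 2-D polynomial (total degree 1–4, default
2) by iteratively re-weighted least squares with upper-side sigma clipping
(2.5 SD, 3 iterations): bright foreground pixels are excluded from the
background surface, which is then subtracted and the result clipped at
zero. A constant image returns all zeros rather than erroring.

*Nuclei segmentation* is Sauvola local adaptive thresholding: foreground
iff `value > m * (1 + k*(s/R - 1))` with local mean/SD in an odd square
window (default `2*expected_diameter + 1`), `k = 0.2`, `R` = half the
16-bit range, computed with reflective border padding — plus an absolute
intensity floor (2% of the dynamic range) because the pure Sauvola rule
marks flat dark background as foreground. Components are labelled
8-connected, filtered by equivalent diameter `2*sqrt(area/pi)` (CellProfiler
convention), and relabelled 1..n in raster order of first pixel. There is
no declumping/watershed step: touching nuclei merge, a known limitation
(tightly clumping lines under e.g. dasatinib will be under-counted).

*Two-scale reconciliation* combines masks segmented at expected cell
diameters 35 px and 150 px. Each cell must contain a same-scale nucleus
(>50% of nucleus area inside; best inside-fraction wins, ties to the lowest
label). A big cell is discarded as a misidentified cluster when at least
`min_small_cells = 2` retained small cells lie inside it (>50% of the small
cell's area) and jointly cover at least `T = 0.5` of its area; otherwise
the big cell is kept and those small cells are dropped. Contested pixels
between surviving objects go to the object retained earlier in pipeline
order (small before big). The 50% thresholds are package choices — the
upstream procedure is described only qualitatively — and both are exposed
as parameters.

*Mitochondria metrics*: each mitochondria region is assigned to the cell
with maximal pixel overlap (ties to the lowest cell id); metric pixels are
the region's pixels inside the owning cell, so mitochondria area never
exceeds cell area. Per cell: integrated intensity over those pixels ("total
mitochondria activity") and integrated/area ("normalized mitochondria
activity", undefined when the cell owns no mitochondria pixels). The sum of
per-cell integrals equals the total assigned signal exactly, by
construction.

## Statistics

Spearman (Pearson of mid-ranks; permutation-exact p for n ≤ 10, t
approximation above), Mann-Whitney U (mid-rank ties; enumeration-exact p
when both groups ≤ 8 and tie-free, else normal approximation with tie and
continuity correction) and Benjamini-Hochberg step-up q-values are
implemented from their rank definitions and cross-checked against
scipy/statsmodels in the tests. All tests are two-sided. The analysis unit
for group comparisons is the **per-image mean**: nuclei or cells within one
field share acquisition conditions and are pseudoreplicates, so the API for
the reporter analysis accepts image-level values only. The exact-test limit
of 8 per group trades runtime against exactness; at 6 images per group the
exact two-sided test's attainable level at nominal 0.05 is 38/924 ≈ 0.041,
i.e. the test is slightly conservative.

## Synthetic microscopy fields

Cells are non-overlapping disks in two size populations (nucleus diameters
14/40 px, cell diameters 35/150 px by default) placed on a jittered grid —
placement fails explicitly if the requested count cannot fit. Channels:
nuclei, tubulin (whole cell), mitochondria (a random speckle subset of the
cytoplasm at fixed per-pixel intensity, fraction 0.15 of cytoplasm area),
and a nuclear reporter with log-normal per-nucleus brightness (sigma 0.2)
plus a per-image random effect (sigma 0.05 on the log scale) in the
table-level generator. All channels sit on a quadratic polynomial
background with Gaussian photon noise (SD 30 counts) and are quantized to
16-bit. The generator stores exact per-cell truth (areas, integrated
mitochondria intensity, reporter brightness).

What this does **not** emulate: textured chromatin, out-of-focus light,
cell shape irregularity, overlapping/clumped cells, mitochondrial network
morphology, or fluorescent drugs bleeding into the reporter channel (the
doxorubicin artifact — a no-reporter control-channel subtraction hook
exists but is off by default). Passing the synthetic benchmarks therefore
demonstrates correctness of the *algorithms* under their stated geometric
assumptions, not segmentation performance on real micrographs.

## Reporter-shift detection

Per-nucleus median intensities are divided by the plate's DMSO grand mean
(so DMSO normalizes to 1 and global exposure scaling cancels), collapsed to
per-image means, tested per drug × concentration against DMSO by
Mann-Whitney, and corrected across the panel by Benjamini-Hochberg. The
power study uses 30 drugs (two shifted 1.5×), 6 images per group, 150
nuclei per image; the shared DMSO group induces positive dependence between
tests, which BH tolerates. Detection is "unique" when exactly the planted
drugs are called at q < 0.05.

## Problem sizes

Defaults throughout (100 fit simulations, 50 panels, 20 segmentation
fields, 5 mitochondria fields, 2000 null replicates, 100 power and 200
specificity runs) were chosen so the full validation completes in a few
minutes on one CPU while keeping Monte-Carlo error comfortably below the
margins being tested.

## Known limitations

- No declumping: merged nuclei under-count dense or clumpy cultures.
- The IC50 censoring convention discards between-line ordering among
  censored keys; alternatives (extrapolated midpoints) are less stable.
- "Mean IC50" in the deviation ledger is the geometric mean across cell
  lines (log2 deviations then sum to zero within a drug/method); an
  arithmetic-mean option exists and moves borderline twofold calls.
- The outlier ledger reproduces published screen counts only when fed that
  screen's IC50 table; no such table ships with the package.
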