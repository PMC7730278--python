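# Methods

This note documents the models and procedures implemented in `invresist`,
the defaults that matter, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being modelled

An isogenic series: one parental line and k − 1 derived sublines ordered
by selection dose (default: A2780 plus six paclitaxel-selected sublines).
Two assays feed the pipeline:

1. **Cytotoxicity**: 96-well plates read at 570 and 600 nm after a redox
   viability indicator, three replicate plates per line × drug, eight
   drug concentrations per plate in four wells each. Concentration units
   are drug-native (PTX in nM, CDDP in µM) and each line uses its own
   dilution series, chosen so the 90–20% viability range is covered
   without extrapolation.
2. **Bulk mRNA-seq**: a gene × sample count matrix over the ordered
   series, two biological replicates per line.

## Viability and IC50

Per-well percent reduction uses the two-wavelength formula with the
indicator's published molar extinction coefficients (oxidised:
80 586 at 570 nm, 117 216 at 600 nm; reduced: 155 677 at 570 nm, 14 652 at
600 nm):

    %reduction = (ε_ox600·A570 − ε_ox570·A600)_well /
                 (ε_red570·A600 − ε_red600·A570)_blank × 100

and %viability = 100 × reduction_treated / mean reduction_control. The
blank normaliser makes the transform affine-exact: a well whose reduction
is half the control level reads exactly 50%.

The concentration grid inverts the empirical curve by linear interpolation
between the two bracketing observations at each requested viability level
(90, 80, …, 20%): x = x1 + (x2 − x1)(y − y1)/(y2 − y1). Brackets are
scanned from the lowest concentration; on a non-monotone curve the first
crossing is used and a warning records the ambiguity. Levels outside the
observed range are undefined by default (`extrapolate=True` extends the
terminal segment) because the assay's per-line dilution ranges are designed
to avoid extrapolation. IC50 is the 50% grid entry; it is deliberately
interpolation-based, not a nonlinear 4PL fit — the four-parameter logistic
lives only in the simulator as the generating truth.

Derived quantities: pIC50 = −log10(IC50 in molar); RI = subline/parent
IC50 for the selecting drug; SI = parent/subline IC50 for the bystander
drug; consecutive fold changes child/parent (RI kind) or parent/child (SI
kind). Reported values are rounded to 2 decimals half-away-from-zero; all
algebraic identities (fold products = end-to-end index) hold on unrounded
values to 1e-9.

## Dose-response comparison

Well-level viability for a pair of lines is modelled linearly in dose with
a line-specific intercept and slope, the slope varying from plate to plate
(plate = random-effect group). Two inferential routes are reported:

- **Random-slope comparison** (`compare_lmm`): for this balanced design
  the mixed model's fixed slope contrast equals the classical two-stage
  estimate — the difference of mean per-plate OLS slopes — and the pooled
  two-sample t on per-plate slopes (df = plates_a + plates_b − 2) is the
  exact small-sample test of the slope difference *for any value of the
  plate-slope variance*. We report that p-value and its t-based 95% CI.
  A Wald z on the mixed-model interaction was evaluated and rejected: with
  only 2 × 3 slope groups it was conservative (≈ 0.04) when the plate-slope
  variance is zero and anti-conservative (0.07–0.13) when it is positive.
  The REML mixed model (statsmodels `MixedLM`) is still fitted for the
  reported slope and intercept estimates; a non-converged fit flags the
  result. Dose enters on the linear scale by default (`log_conc` option).
- **pIC50 t-test** (`compare_ttest_pic50`): pooled-variance two-sided
  Student t on per-plate pIC50 replicates (pIC50, not IC50, because the
  log scale is the approximately normal one). Two zero-variance groups
  with equal means give p = 1 by convention.

Calibration of both tests (empirical type-I error at α = 0.05 under the
null, 1000 simulations of the plate design) is recomputed by the test
suite and the acceptance script.

## Differential expression

- **Filter**: keep genes with CPM > 5 in at least 2 samples, applied once
  across all samples so every contrast shares one gene universe.
- **Transform**: log2((count + 0.5)/(libsize + 1) × 1e6). The library
  size defaults to the column sum; the series pipeline passes
  median-of-ratios *effective* library sizes instead (DESeq-style size
  factors rescaled to column-total magnitude). The robust version matters
  here: a planted (or biological) one-sided effect mass inflates raw
  totals of the affected lines by double-digit percents, which under plain
  total-count scaling shifts every null gene and inflates the empirical
  FDR several-fold. With a large null majority the median ratio estimates
  the composition factor consistently.
- **Moderated t** (`fit_de`): per gene, log2FC is the difference of group
  means of log-expression; the pooled residual variance s² (df = n1+n2−2)
  is shrunk toward a scaled-inverse-chi-square prior whose df d0 and scale
  s0² are estimated by moment-matching the log-variances (digamma/
  trigamma inversion). The posterior variance (d0·s0² + df·s²)/(d0 + df)
  enters the t statistic with df + d0 degrees of freedom. Limits are
  exposed for verification: `prior_df=0` reproduces the ordinary
  two-sample t; `prior_df=inf` with a fixed `prior_var` reproduces the
  pooled z-test. Observation-level precision weights (a mean–variance
  trend) are *not* fitted: with two replicates per line the trend estimate
  is unstable, and the homogeneous-variance prior is adequate at realistic
  sequencing depth (shallow libraries reintroduce Poisson
  heteroscedasticity and mildly inflate FDR).
- **FDR**: Benjamini–Hochberg step-up by default ("q-value" here means
  the BH-adjusted p); a single-lambda Storey estimate is available via
  `method="storey"`. NaN p-values propagate with a warning.
- **DEG sets**: q below threshold, optionally |log2FC| above a bound,
  split by sign. DEG-count vs |ΔRI|/|ΔSI| association uses Spearman rank
  correlation (≥ 4 pairs; constant vectors are an error).

## Trend classification and scaffold

A gene's trajectory is the sign of its log2FC across the ordered
subline-vs-parent contrasts. |log2FC| < 0.1 is treated as sign 0 and
inherits the previous nonzero sign (leading zeros inherit the first
nonzero); the dead zone prevents replicate noise from relabelling flat
genes as "variable". Classes: all + → consistently up; all − →
consistently down; exactly one − → + reversal → rising (switch index =
first contrast of the new sign); exactly one + → − reversal → descending;
otherwise variable. An all-zero trajectory is variable with an explicit
flag. The five classes partition any gene list by construction.
Classification uses signs only, not per-contrast significance, mirroring
how trend heat maps colour all selected genes in all contrasts.

The scaffold is the conjunction set: q < 0.001 **and** |log2FC| > 2 in
every contrast (so it is invariant to contrast order), annotated with the
trend class and a direction summary (consistently up → "up", consistently
down → "down", else "nonconsistent"). Note the q < 0.001 bar is only
reachable at adequate depth and gene count — with duplicate libraries the
BH-adjusted floor scales like p_min·m/R, and shallow toy simulations can
have an empty scaffold without anything being wrong.

Shared-DEG matrices count pairwise intersections of per-contrast DEG sets,
upregulated above the diagonal, downregulated below, the contrast's own
DEG total on the diagonal; partition totals aggregate unordered pairs that
involve an "early" contrast versus pairs entirely within the "late" group.
The early/late split is supplied by the user as an empirical observation,
not inferred by a change-point criterion.

PCA operates on samples as observations: genes centred, no unit-variance
scaling, components from the SVD of the centred matrix (exact
reconstruction, explained-variance fractions from squared singular
values). Hierarchical clustering defaults to Euclidean distance with
average linkage (configurable); leaf order and a Newick export support
heat-map rendering.

## Network and enrichment

The scaffold network is the induced subgraph of a supplied scored edge
list (scores in [0, 1]) on the scaffold genes, keeping edges with score ≥
0.4 by default — the common medium-confidence convention for combined
interaction scores; the threshold used by any given upstream database
export is the user's to set. Self-loops are dropped; edges naming genes
outside the set are dropped with a warning. Nodes carry the trend
direction and degree; hubs are nodes with degree ≥ 7 (the degree range
observed for the motivating study's hub proteins), sorted by degree then
id. Enrichment is the one-sided hypergeometric upper tail per term
(annotation intersected with the chosen universe, empty terms skipped)
with BH q-values across terms; the recommended universe is the set of
genes surviving the expression filter, not the whole genome.

## Synthetic data: what it emulates, and what not

- **Plates**: the exact plate geometry (columns 1/12 blanks, 2/11
  drug-free controls, 3–10 the eight concentrations in four wells each),
  true viability from a 4PL with asymptotes 100/0, v(IC50) = 50 and
  configurable Hill slope; additive Gaussian per-well viability noise
  truncated to [−5, 120] (default SD 3 percentage points, loosely
  calibrated to the small replicate scatter of the motivating assay —
  per-well raw data are not published, so this is an order-of-magnitude
  choice). Absorbance pairs are generated by inverting the reduction
  formula, so the viability transform is exact by construction; plate
  effects on absorbance (edge effects, drift) are not modelled.
  Default concentration grids are doubling series centred on each line's
  true IC50, emulating per-line dilution design.
- **Counts**: NB(mean = library-size-scaled expression, dispersion α;
  var = µ + αµ²), baseline log2 CPM uniform on [3, 9], default dispersion
  0.05 and library size 25 M ± 10%, seven lines × two replicates. Planted
  classes follow the five-pattern scheme at full effect |log2FC| = 3;
  rising/descending switches are drawn uniformly from contrasts 2..k−1 so
  the classifier is tested away from any fixed switch stage; class
  proportions default to the motivating study's mix (a 997-gene
  significant set split 190:295:138:174:200 inside 11 588 expressed
  genes). Not emulated: mean–variance trends, batch effects, isoform
  structure, correlated genes — so recovery results certify the pipeline's
  logic, not its behaviour under every real-data pathology.
- **Networks**: planted hubs receive exactly `hub_degree` partners among
  non-hubs; non-hub degrees stay strictly below the hub threshold; scores
  uniform on [0, 1]. Degree structure only — no community structure or
  score-degree correlation.

All generators draw from a single `numpy` Generator seeded from
`SimConfig.seed` (stream-split by a CRC-based stable hash), so outputs are
bit-reproducible across processes.

## Problem sizes and numerical choices

The test suite and acceptance script use 2000-gene simulations at the
default depth for DE/trend recovery, 1000-replicate null simulations for
test calibration, 100-gene networks with 6 planted hubs, and universes of
8–12 genes for exact enrichment enumeration; these sizes give stable
stochastic bounds while keeping runs short. Other numerics: trigamma
inversion by Newton iteration to 1e-10 relative tolerance; interpolation
identities asserted to 1e-9; rounding of reported indices is
half-away-from-zero at 2 decimals; a gene with zero standard error and
zero fold change scores a null statistic rather than NaN.

## Known limitations

- The IC50 is a secant inversion of the empirical curve: its accuracy is
  bounded by the curvature of the true dose-response between bracketing
  concentrations (~6% worst-case on the default doubling grids at Hill
  slope 1), which is the method's intended behaviour, not an estimator to
  be tuned.
- With two replicates per line, the per-contrast moderated t leans heavily
  on the variance prior; strongly heteroscedastic genes (very low counts)
  are the first place calibration degrades.
- The linear dose-response model for curve comparison is a local
  approximation of a sigmoid; it is used for slope comparison, not for
  prediction, and per-line dose ranges make slopes scale-dependent — the
  comparison answers "do these curves fall at different rates over their
  own tested ranges".
- The enrichment model treats annotation terms as independent gene sets;
  no term-graph propagation is performed.
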