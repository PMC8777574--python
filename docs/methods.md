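# Methods

This note documents the statistical model behind `woodvar`, the
conventions the implementation pins down where the method leaves room,
what the synthetic generator does and does not emulate, and the
numerical choices that matter.

## The sampling hierarchy and the nested ANOVA

The data model is a four-level nested sampling design for a
heterogeneous bulk material measured by diffuse-reflectance FT-NIR:
hourly **lots** of material, **subsamples** scooped from each lot,
**replicate tubes** filled from each subsample, and individual
**scans** acquired inside each tube. Every scan is an absorbance
spectrum on a common wavenumber axis (cm⁻¹).

For each level the contribution to total variability is measured by

```
SSQ_lvl = Σ_{n=1}^{N_lvl} (x_{n,lvl} − x̄_{lvl−1})²,
MSQ_lvl = SSQ_lvl / D_lvl,   D_lvl = N_lvl − N_{lvl−1},  N_0 = 1,
```

computed independently per wavenumber. Two conventions exist and the
package implements both:

* **Unweighted (default).** `x_{n,lvl}` is the mean of unit *n*'s
  deepest-level rows; `x̄_{lvl−1}` is the *unweighted* mean of the
  parent's child-unit means (the grand mean of the lot means at the
  top); deviations enter with weight 1. This is the formula as printed
  above, taken literally. Under it, per-lot subsample-level SSQs sum
  exactly to the global subsample-level SSQ.
* **Count-weighted (`weighted=True`).** Classical nested ANOVA: parent
  references are row (count-weighted) means and each squared deviation
  is multiplied by the unit's descendant count. The level SSQs then
  telescope to the total sum of squares about the grand mean in any
  design (tested to 1e-8 relative on a balanced design).

The conventions coincide for balanced designs only at the deepest
level. For the bound-water-content reference data, the study-scale MSQ
triple (≈3.2 at lot, ≈0.39 at subsample, ≈7e-4 at duplicate level, on
data whose overall sd is ≈0.7 %) is only arithmetically consistent with
the count-weighted convention — the unweighted lot-level MSQ is the
variance of the 16 lot means and can never exceed the total variance.
`bwc_nested_anova` therefore defaults to `weighted=True`; the spectral
decompositions default to the unweighted form.

Degrees of freedom always use *actual* unit counts from the labels
(e.g. 126 replicate tubes instead of 128 after data loss), never the
nominal design. A level without replication is reported with
`MSQ = NaN` and listed in `undefined` rather than silently dropped;
`compute_dof` on an explicit design raises instead, naming the level.
Rows containing non-finite values are dropped with a warning before
decomposition; nothing is imputed.

## Preprocessing

The pipeline order is fixed: **trim → artifact screen → MSC**.

* Trimming keeps wavenumbers in [3 880, 9 000] cm⁻¹ by default; outside
  this window the spectra are noisy or uninformative for
  lignocellulose.
* The artifact screen flags scans that are air or plastic-lid
  acquisitions (a manually started measurement can begin before the
  sample is in place). A scan is flagged when its Pearson correlation
  with the median spectrum is below 0.5 *or* its mean absorbance is
  below 0.05; constant scans (undefined correlation) are always
  flagged. Both thresholds are configurable. The defaults separate
  near-flat air scans and chemically alien lid spectra without any
  training data; on synthetic injections the screen achieves
  recall = precision = 1.0 at study-scale rates (~0.2 % of scans).
* MSC regresses each scan on the global mean spectrum of all retained
  scans (one correction before a cross-lot analysis, not per lot) and
  replaces it by `(x − a)/b`. The fitted model stores the reference so
  held-out scans can be corrected consistently. A scan with zero
  peak-to-peak range, or exactly zero slope against the reference, has
  no defined correction and is excluded with a warning. MSC with a
  fixed reference is idempotent to 1e-10.

## PCA, ellipses, replicate distances

PCA is computed by SVD of the mean-centered matrix, with a
deterministic sign convention (the largest-magnitude element of every
loading column is positive) so results are reproducible across runs and
platforms. Requested components beyond the numerical rank are dropped
with a warning; an input whose leading singular value is at rounding
level raises a degenerate-input error (callers such as the pipeline
catch and record it). Explained-variance fractions are relative to the
total variance of the centered input.

Two PCAs are used: on per-lot MSQ vectors at a chosen level (rows =
lots), and on replicate-tube mean spectra (rows = lot × subsample ×
tube, 16 × 8 = 128 for the study design — the tube level is the finest
level at which mean spectra are meaningful replicate summaries).

Per-lot spread in the first-two-score plane is summarised by a
**standard-error ellipse**: center at the lot's mean score, axes along
the eigenvectors of the lot's local 2 × 2 score covariance (ddof = 1),
radii sd/√n along each axis. This describes the uncertainty of the
lot's mean position, not a coverage region (no Hotelling/χ² scaling).
The **replicate distance** is the Euclidean distance between the two
tube points of a subsample in the same plane; its per-lot mean
correlates positively with the lot's replicate-level MSQ (tested via
Spearman over pooled seeds).

## Sampling design by resampling

The design study asks: how many subsamples, tubes and scans does one
lot need before its measured variability stabilises? Five constraint
levels define the selection pool and balance:

| level | pool | balance |
|---|---|---|
| A | one subsample | equal scans per tube (tubes act as groups) |
| B | one subsample | tubes pooled, free draw |
| C | two subsamples | equal scans per subsample |
| D | three subsamples | equal scans per subsample |
| E | all subsamples | free draw |

For each `n` in the level's grid (defaults 25–150 for A up to 25–1 000
for E), `n` scans are drawn without replacement, the nested ANOVA is
recomputed on the selection with its level-implied grouping, the
per-wavenumber MSQ is reduced to one scalar, and the whole thing is
repeated 100 times; the spread (sd) of the summary over repetitions is
the quantity of interest. Remainders of non-divisible `n` go to groups
in sorted label order (deterministic). By default each repetition also
draws the subsample combination uniformly from all possibilities, so
the estimate pools over the arbitrary subsample choice;
`ResamplingSpec.subsamples` fixes a combination instead. Note that
combination pooling adds an `n`-independent variance floor — the
spread-shrinks-with-`n` property is a statement about scan-sampling
noise and is tested with a fixed combination.

**Summary statistic.** The method's description leaves the reduction of
the per-wavenumber MSQ to one number open. The package default is the
*total mean square* of the selection — the sum of squares about the
selection's grand mean divided by `n − 1`, averaged over wavenumbers —
for two reasons: (i) an exhaustive level-E draw then reproduces the
lot's overall variability *exactly* (the reference line of the study is
internally consistent with the resampling), and (ii) it makes the
characteristic undershoot of the one-subsample levels a structural
fact: a selection confined to one subsample contains no
between-subsample variance, so its total mean square plateaus below the
lot reference no matter how many scans are drawn. A scan-level-MSQ
summary cannot show this — under subsample grouping it excludes
between-subsample variance at *every* level. `"scan"`, `"all_levels"`
and `"max"` remain selectable. For `k` equally represented subsamples
out of `m`, the expected between-subsample contribution scales as
`(k−1)/k` against the reference's `(m−1)/m`, so the undershoot gap
shrinks quickly once two or more subsamples are covered — which is
exactly why two subsamples with a moderate scan count already describe
a lot adequately.

`recommend_design` makes the "almost constant" plateau criterion
explicit: the recommended `n` per level is the smallest whose
repetition sd is within a relative tolerance (default 10 %) of the sd
at the largest `n`; a level whose spread rises back out of that band is
marked unstable, and a level whose plateau mean falls more than a
margin (default 5 %) below the overall-variability reference is flagged
as undershooting. The overall pick is the stable, non-undershooting
level with the smallest recommended `n`.

## The synthetic generator

`woodvar.simulate` emulates the study conditions: 16 lots × 4
subsamples × 2 tubes × 210 scans on a 3 700–14 885 cm⁻¹ grid at
8 cm⁻¹ steps. Spectra are a baseline (0.15 AU) plus Gaussian absorption
bands at standard lignocellulose assignments (cellulose 6 797, 4 760,
4 397, 4 281; hemicellulose 4 285, 4 740; lignin 4 004, 4 280; water
5 189 and 6 950; glue/urea-resin 5 805, 5 624, 4 617, 4 440 cm⁻¹),
widths 40–120 cm⁻¹. Composition varies through log-normal
peak-amplitude multipliers `exp(e_lot + e_sub + e_tube + e_scan)` with
independent Gaussian effects per unit and configurable per-level
variances (defaults 0.020 / 0.003 / 0.005 / 0.001 — lot variance
dominant, subsample slightly below tube, mirroring the study-scale
pattern). Each scan then receives multiplicative scatter
(log-sd 0.08), an additive offset (sd 0.03) and white noise (sd 0.003),
so MSC has something real to correct.

Bound water content is drawn per sample as
`8.0 % + lot effect + subsample effect` with sds 0.632 and 0.441 %,
duplicate measurement noise sd 0.0267 % — values derived from the
study-scale BWC variance components under the count-weighted
convention (lot MSQ 3.20 with 8 observations per lot ⇒
σ_lot = √(3.20/8), and analogously down the hierarchy); they imply an
overall sample sd of ≈0.78 %. The water-band amplitude of a sample's
scans is scaled by `BWC/8.0`, coupling reference chemistry to spectra
(correlation > 0.9 when only BWC varies). A per-lot scale factor on the
subsample BWC sd lets tests inflate a single lot's water variability on
purpose. Artifact scans replace a configurable fraction
(count = ⌊rate·n + 0.5⌋) with near-flat low-absorbance "air" profiles
or high-absorbance "lid" profiles with alien band positions.

What the generator does **not** emulate: radiative-transfer physics of
diffuse reflectance, instrument line shapes, detector drift over a
session, correlated (non-white) noise, and the long-tailed BWC outliers
real waste wood produces (effects are Gaussian). Passing tests
therefore demonstrate correctness of the statistical machinery under a
controlled data-generating process, not robustness to every
instrumental pathology of real spectra.

## Numerical choices and test scales

* Quartiles for Tukey fences use linear interpolation between order
  statistics; fences are `Q1 − k·IQR`, `Q3 + k·IQR` with `k = 3.0` by
  default (conservative screening). Outliers are reported, never
  removed automatically.
* Wavenumber axes are stored ascending; descending input (files or
  arrays) is flipped on load together with the matrix columns.
* CSV round-trips use round-trip float parsing so write → read → write
  is byte-identical.
* Determinism: every stochastic operation takes a seed or
  `numpy.random.Generator`; identical configuration implies
  bit-identical output, including the resampling stage.
* Test problem sizes: the oracle-equivalence suite uses 100 random
  hierarchies of at most 3 × 3 × 2 × 5 units against a literal
  loop-and-dictionary implementation of the formulas (1e-12 relative);
  ordering-recovery runs 20 seeds of the full 16 × 4 × 2 × 210 design
  on the trimmed grid; the resampling property uses 20 seeds of a
  single 4 × 2 × 210 lot with the grid endpoints {25, max}; the
  replicate-distance property pools 50 seeds of an eight-lot design
  with replicate variances spanning two decades. The acceptance script
  runs one full study-shaped simulation end to end plus a six-seed
  ordering sweep at 30 scans per tube and the complete level A–E grids
  at 100 repetitions.

## Known limitations

* The unweighted MSQ convention is not additive across levels; use
  `weighted=True` when an exact decomposition of total variance is
  needed.
* Ellipses and distances are computed in the first two score
  dimensions (configurable); structure in higher components is not
  summarised.
* `recommend_design` under combination pooling can see an almost flat
  spread curve (the combination variance floor) and then recommends the
  smallest grid point; fix the combination when the scan-count question
  is the one being asked.
* The deposited study dataset is only supported through a CSV
  conversion contract (`woodvar.io.load_study_archive`); its native
  layout is not parsed directly.
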