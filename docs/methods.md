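# Methods

## Scope

`seedhsi` implements an online near-infrared hyperspectral-imaging (NIR-HSI)
pipeline for seed viability sorting: radiometric calibration of raw
line-scan cubes, chemometric preprocessing, a PLS-DA classifier with a
shifted decision threshold, pixel-wise chemical imaging, a streaming sort
loop, and the downstream verification statistics (germination rates,
moisture content, one-way ANOVA on composition assays). Because no real
seed dataset ships with the package, a synthetic scene generator supplies
ground truth for every stage; it is first-class, tested code, not a
fixture.

## Radiometric model and calibration

A pushbroom camera over a conveyor yields a cube of raw counts
(lines x pixels x bands) on a wavelength grid inside 900–1700 nm.
Two-point calibration converts counts to relative reflectance

    R = (X_raw - X_dark) / (X_ref - X_dark)

where `X_ref` is a white (Teflon) reference frame and `X_dark` a shuttered
frame, both (pixels x bands). The quotient is clipped to [0, 1.2]: sample
pixels can specularly exceed the diffuse white reference, and the cap
bounds those excursions without hiding genuine calibration faults (a
non-positive `X_ref - X_dark` anywhere is an error naming the pixel and
band, never a silent clip). Cubes carry a state tag
(`raw -> reflectance -> preprocessed`) that can only move forward, plus an
append-only provenance list naming every transform applied.

## Spatial cleaning and segmentation

Each band is filtered with a 3x3 spatial median (reflect padding at the
image edge). Seed regions come from thresholding the band-mean image
(default cut 0.2 against a ~0.06-reflectance belt), 4-connected component
labelling, and removal of components below `min_area` (default 20 px —
about a fifth of the smallest simulated seed footprint, and comfortably
above speck noise). Regions are reported in scan-line order with 0-based
(line, pixel) coordinates and half-open bounding boxes. This automatic
rule stands in for interactive region-of-interest drawing, which is not
reproducible; with the default generator noise it recovers footprints
exactly on noise-free scenes and count-exactly at the default noise level.

## Row preprocessing

Eight row-wise transforms are available: none, mean/max/range
normalisation, MSC, SNV, and first/second Savitzky–Golay derivatives.
Conventions that matter for porting:

- SNV uses the sample (n−1) standard deviation.
- MSC regresses each spectrum on a frozen reference — by convention the
  calibration-split mean — and returns `(x − b)/a`.
- Savitzky–Golay derivatives use window 11, polynomial order 2 by default,
  differentiate with respect to the band index (delta = one sample), and
  keep full length via polynomial edge fitting.
- Degenerate rows (zero variance under SNV, constant under range
  normalisation, non-positive maximum, zero mean) are errors at the table
  level; in pixel-wise imaging such pixels are instead floored to a
  nonviable score of 0 and counted in an anomaly tally, because one bad
  pixel must not abort a sort run.

## PLS-DA

The classifier is PLS1 regression of the fixed class code (0 nonviable,
1 viable) on centered spectra, fitted by NIPALS deflation. Per component:
weight `w` from the X–y covariance (normalised), score `t = Xw`, loadings
`p = X't/t't`, `q = y't/t't`, then X and y are deflated. The regression
vector is `b = W (P'W)^{-1} q`; prediction is `(x − x̄)b + ȳ`. Convergence
uses a sign-invariant weight distance (the weight direction of a
univariate-y fit is fixed after one pass but its sign can alternate with
`q`) with tolerance 1e-8 and a 500-iteration cap; at full rank the
deflated X sits at the float rounding floor and the direction jitters
near 1e-10, so a tighter tolerance misreports non-convergence. Exactness
checks: at `n_lv = rank(X)` the coefficient equals the least-squares
solution (1e-6), and predictions match an independent reference PLS
implementation on random 40x25 problems (1e-6).

Latent-variable count is chosen by venetian-blind 10-fold cross-validation
(rows shuffled once with the given seed, fold f = every 10th row) as the
argmin of misclassification error at threshold 0.5; ties go to the fewest
components.

## Decision threshold and its shift

Scores are cut at threshold `t`; a score strictly above `t` is viable, a
tie goes nonviable — deliberately conservative, since the sorter's purpose
is to reject anything borderline. Starting from 0.5, `t` is raised on a
0.01 grid (matching the precision such shifted thresholds are reported
at, e.g. 0.52–0.55) until the calibration samples at or above `t` are
pure viable to the requested target; evaluating purity with `>=` while
classifying with `>` makes a sample sitting exactly on a candidate cut
push the threshold one step higher. An empty accepted group counts as
pure; an unreachable target returns the grid maximum flagged
`reached=False`. The returned threshold is non-decreasing in the purity
target, and raising `t` can only shrink the false-viable count.

Metrics use viable as the positive class; `Acc.v` is correctly accepted
viable seeds over all truly viable seeds.

## Outlier screen

Hotelling's T² on the first two principal components of the column-centered
spectra, with the F-based ellipse bound `2(n−1)/(n−2) F_{2,n−2}(c)` at
confidence `c` (default 0.989). On bivariate normal data the flagged
fraction is ~1.1% by construction; this is verified by simulation.

## Chemical imaging and per-seed calls

Every masked pixel's spectrum is preprocessed with the model's own row
transform before projection — the model was fitted on preprocessed
spectra, so projecting raw pixels through `b` would mix conventions.
The score map is binarised at the model threshold, speckle removed by
4-connected area opening with the same `min_area` as segmentation (one
knob, consistent speck handling), and a seed is called viable when its
viable-pixel fraction reaches `viable_fraction` (default 0.5, with `>=`
at the boundary). On noise-free scenes this pixel-vote route agrees with
classifying the seed's mean spectrum; both routes are implemented and the
pixel route is the default because it tolerates within-seed heterogeneity.

## Streaming runtime

The online loop consumes the cube in frames of `frame_height` lines.
Each line is calibrated on arrival and median-filtered with a one-line
lookahead so the result is bit-identical to whole-cube filtering (reflect
padding is applied explicitly at stream start and end). Seed blobs grow
across line and frame boundaries by column-overlap stitching
(4-connectivity); a blob with no pixels in the current line is closed,
classified pixel-wise, and emitted as a sort event with a decision time
(closure line / line rate) and an actuation time (decision time +
nozzle distance / belt speed, default nozzle 150 mm past the field of
view — the rig geometry is configurable because no standard value
exists). Blobs still open at stream end are closed and flagged.
Frame height is a buffering knob only: decisions are exactly equal to
batch processing for every height, which is the loop's core correctness
property and is tested at heights 1, 8, 64 and full.

Timing is simulated, never wall-clock: at 49 mm/s belt speed and 17 ms
exposure the belt advances 0.833 mm per line and the camera delivers
58.8 lines/s.

## Downstream statistics

Moisture content is gravimetric on a wet-weight basis,
`MC% = (Ww − Wd)·100/Ww`. The one-way ANOVA is the textbook
sum-of-squares decomposition with p from the F distribution; identical
groups return F = 0, p = 1 rather than 0/0. Group comparisons
(viable vs nonviable per variety) are run per analyte with no
multiple-testing correction — the comparison tables this mirrors apply
none, and the package documents rather than silently changes that.
Germination reports give per-predicted-group rates in percent; an empty
group reports n/a (NaN), never 0.

## Synthetic scene generator

What it emulates — and the defaults, chosen once as plausible for a
benchtop NIR rig and seedlot:

- **Optics/radiometry**: smooth lamp profile peaking near 1300 nm
  (~3000 counts over dark), dark current 100 counts with per-pixel
  fixed-pattern noise (sd 2), 1% per-pixel gain variation, additive
  sensor noise sd 8 counts, uint16 quantisation. Calibration therefore
  genuinely inverts a two-point gain model rather than being a no-op.
- **Geometry**: axis-aligned elliptical seed footprints with aspect
  1.5–2.0 (watermelon-seed-like), jittered on a grid layout that
  guarantees disjoint footprints; an unplaceable layout is an error.
- **Spectra**: a smooth baseline (0.52 + gentle rise) minus three
  Gaussian absorption valleys at 1415, 1475 and 1605 nm (width 9 nm),
  tied respectively to carbohydrate, protein and moisture levels of a
  latent per-seed chemistry triple, plus a broad 0.022-deep intensity
  deficit over 1425–1670 nm for low-chemistry (nonviable-like) seeds.
  Valley depths at the class means: 0.15/0.13/0.17 (viable) vs
  0.08/0.06/0.10 (nonviable). These numbers are free parameters of the
  simulator — no real-seed contrast is published to calibrate them —
  and a single `contrast` factor scales all class differences.
- **Classes and chemistry**: chemistry levels are Normal(0.70, 0.10) for
  viable and Normal(0.40, 0.10) for nonviable seeds, clipped to
  (0.02, 0.98). Germination is Bernoulli with probability
  logistic(10·(score − 0.55)) of the mean chemistry, giving ~85% for a
  typical viable seed and ~20% for a nonviable one.
- **Scatter**: per-seed multiplicative factor lognormal(0, 0.05),
  additive offset Normal(0, 0.01), linear spectral tilt Normal(0, 0.005)
  — exactly the distortions MSC/SNV/derivative preprocessing exist to
  remove. Scanning both seed faces is emulated by rendering each seed
  twice with independent scatter draws and a small side-B offset
  (sd 0.01).
- **Assays**: wet weight 60 mg (CV 8%), moisture fraction
  0.04 + 0.08·moisture level, peak areas 12 + 30·level % with sd 1.5
  measurement noise; `noise_scale = 0` collapses everything to
  class-conditional constants.

What it does **not** emulate: radiative transfer or optical point-spread,
seed-coat texture, touching or overlapping seeds, belt vibration,
temperature drift, dormancy (germination depends only on the latent
score). Passing tests therefore demonstrate the pipeline's internal
correctness and its behaviour under the stated noise model — not
performance on real seed spectra, which are not distributed with the
system this re-implements.

## Problem sizes

The end-to-end checks train on 300 seeds per class (both faces, 1200
spectra) rendered as a batch of 50-seed scenes, with smaller 60-per-class
batches for the contrast sweep; downstream statistics use 200 replicate
assay tables of 40 seeds. These sizes give stable statistics while
keeping a full run of the suite and the acceptance script in the
low minutes on one CPU.

## Known limitations

- The ±0.5 class-membership notation of the source method is read as a
  single cut between the two class codes; the symmetric per-class band
  reading would differ only for scores far outside [0, 1].
- The streaming blob tracker assumes 4-connectivity; diagonal-only
  contacts count as separate seeds, in both batch and streaming modes
  (consistently, so equivalence holds).
- Model serialisation (YAML) stores coefficients in full double
  precision but is not a compact format; it favours inspectability.
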