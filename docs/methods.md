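# Methods

## The measurement model

A scratch-wound (or debridement) assay produces a cell-free gap whose
area shrinks as the epithelium heals. woundkin works on the normalized
time course: gap percent `%_t = 100 · A_t / A_0`, so every series starts
at exactly 100 and complete closure is 0. The kinetic statistic is the
**healing rate constant**, the arithmetic decline of gap percent per
hour within one kinetic phase,

    k = (%_t − %_{t+w}) / w        [Δ%/h],

positive for a closing wound (window `w` = 6 h by default). Closure is
modelled piecewise-linearly in percent: either a single phase
(monophasic, one rate `k1`) or two phases joined continuously at a
breakpoint `t_b` (biphasic, `k1` then `k2`), the pattern produced by
growth-factor– or lumican-stimulated corneal epithelium, where an
initial migration-dominated phase is followed by a faster phase once
proliferation resumes. The model is linear in percent, i.e. the rate
definition is taken literally; an exponential (semi-log-linear)
variant is deliberately not offered, because the two cannot both match
the arithmetic Δ%/h definition and mixing them would change the
reported constants.

## Fitting and model selection

**Monophasic** fits are ordinary least squares of `%_t` on `t`;
`k1 = −slope`.

**Biphasic** fits use the continuous hinge

    %(t) = a − k1·t                          t ≤ t_b
    %(t) = a − k1·t_b − k2·(t − t_b)         t > t_b

with `t_b` restricted to observed interior times having at least three
observations on each side (the boundary point counts for both). For
each candidate the problem is linear in `(a, k1, k2)` and solved in
closed form; the candidate with minimal SSE wins, earliest breakpoint
on ties. The exhaustive grid search is deterministic and directly
checkable against an independent per-candidate re-fit, which the test
suite does.

**Classification** uses the extra-sum-of-squares F-test
(`F = ((SSE_mono − SSE_bi)/2) / (SSE_bi/(n−4))`, referred to
F(2, n−4)) at `alpha = 0.05`, with the additional biological
constraint `k2 > k1`: a biphasic label is only meaningful when the
second phase accelerates. A decelerating two-segment curve, however
well it fits, is reported monophasic. Series with fewer than 6 usable
points fall back to the monophasic fit without a test.

**Goodness of fit** is `R² = 1 − SSC/TSS` with SSC the sum of squared
distances of the points from the fitted curve and TSS from the
horizontal line through the mean of the observations. A perfect fit is
exactly 1; flat data with nonzero residuals have no defined value and
raise an error rather than returning a misleading number. For simple
line fits this construction coincides with the squared Pearson
correlation, a property the tests exercise.

**Trimming.** Points recorded after the gap first reaches the closure
floor (default 2 %) sit on a saturation floor and violate the linear
phase model; `trim_to_closure` keeps the prefix up to and including the
first sub-floor point. The floor is configurable.

## Edge-band and migration geometry

Coordinates are continuous Cartesian µm; when derived from masks the
origin is the image top-left with y downward, and positions are
8-connected-component area centroids (blobs under 4 px are discarded as
noise). Wound edges are simple polylines; point distances are exact
minimum Euclidean point-to-segment distances (computed by shapely).

* `band_fraction` counts cells within `band_um` (default 100 µm, the
  conventional wound-edge band) of the edge, closed boundary
  (`distance ≤ band`), and reports the positive fraction; an empty band
  is NaN, never 0. The band is measured from the current front by
  default — marker counts are made on the healing culture — but the
  original edge can be selected.
* `migration_distance` samples the front uniformly by arc length
  (default 50 stations) and takes each station's distance to the
  original edge. For straight parallel edges this equals the single
  transect measurement used on cornea cut views; for curved fronts it
  averages over the front instead of depending on where the transect is
  drawn.

## Group statistics

Per-condition values (rate constants per replicate, band fractions,
migration distances) are summarized as mean ± sample SD (n−1). Groups
are compared with one-way ANOVA (between/within sums of squares) and
Bonferroni post-hoc pairwise pooled-variance t-tests: adjusted
p = min(1, raw p × number of pairs). The degenerate all-constant case
is defined as F = 0, p = 1. The rate-constant report prints, per
condition, n, k1 mean ± SD, k2 mean ± SD over the replicates labelled
biphasic ("N.A." when none), and the raw pooled-t p-value against a
chosen reference condition; Bonferroni-adjusted all-pairs values are
available through `bonferroni_pairwise`.

## The synthetic generator and what it does not emulate

`simulate_closure` draws replicate curves from the hinge model plus
additive Gaussian noise on the percent scale (default SD 2 percentage
points — a stipulation, since real scratch-assay measurement error
depends on the segmentation software; it is a parameter, not a claim),
clipped below at 0, with the t = 0 point re-pinned to exactly 100 to
mirror the normalization convention. Sampling runs every `dt_h`
(default 3 h, the routine time-lapse protocol) until `t_max_h`
(default 24 h) or until the noiseless curve reaches 0; the closure
sample is kept. Generators are pure functions of (parameters, seed).

One structural consequence matters for study design: with phase-1 rates
near 5 %/h and phase-2 rates near 15 %/h, the wound closes 1.5–2.5 h
after a 12-h breakpoint, so a 3-h grid places at most one sample in the
entire second phase and `k2` is then not identifiable — the hinge fit
degrades gracefully (it returns the best admissible breakpoint, one
grid step early, with a shrunken `k2`). Wherever the package's own
validation needs the second rate recovered, it therefore samples finely
enough to put several points in the shortest phase: hourly for the
noiseless and classification checks, and, in the acceptance script, the
largest grid step that leaves at least eight phase-2 samples above the
closure floor (derived from the closure arithmetic, per condition).
Real experiments with short fast phases need the same consideration.

`simulate_cell_field` scatters cells uniformly over the two monolayer
slabs flanking a central vertical gap and assigns marker positivity by
a two-level probability (in-band vs out-of-band). It does not model
cell shape, crowding, intensity, staining artifacts, or gradients of
positivity with distance — so passing band tests demonstrates correct
counting geometry and statistics, not robustness to segmentation error.
`simulate_debridement` produces straight parallel edge pairs with
zero-truncated Gaussian displacement; it does not model irregular
fronts, so migration tests validate the sampling/distance machinery,
not front segmentation.

## Numerical choices

* Least squares via `numpy.linalg.lstsq`; SSE below a relative 1e-12
  threshold snaps to exactly 0 so the "perfect fit ⇒ R² = 1" contract
  survives floating-point residue.
* Breakpoint ties (equal SSE) resolve to the earliest candidate.
* Grid lookup tolerance for observed times is 1e-9 h.
* Band membership uses a closed boundary; centroids are area centroids
  so pixel-center offsets cancel.
* ANOVA with zero within- and between-group variance returns (0, 1);
  zero within-group variance with separation returns (inf, 0).

## Known limitations

* No image segmentation: gap areas and edges enter as numbers,
  polylines, or binary masks produced elsewhere.
* The linear-in-percent phase model is a choice; data following
  exponential closure will show systematic residuals that the F-test
  may read as biphasic structure.
* `k2` for conditions whose second phase is shorter than ~3 sampling
  intervals is structurally biased low (see above); the package reports
  what the grid supports rather than extrapolating.
* Pairwise comparisons assume pooled variances, matching the classical
  ANOVA/Bonferroni workflow; no Welch or mixed-effects options.
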