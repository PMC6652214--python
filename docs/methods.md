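# Methods

This note documents the models, numerical choices and limitations behind
`phenoprofiles`, in the spirit of the methods documentation of packages
like statsmodels or msprime. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The synthetic field generator

No imagery is deposited with the field study this package emulates, so the
generator is a first-class, tested component: it defines the conditions
under which every downstream stage is validated.

**Field design.** Plots are axis-aligned 2 m × 2.4 m rectangles (three
planting rows at 0.6 m spacing) abutting across the field's width and
separated by 0.8 m alleys along its length; the default column count fits
a ~27 m-wide breeding strip. Seeding density is 6 plants m⁻². Each plot
carries one genetic-background label (mixed / TEM / TST by default), drawn
with near-exact proportions from a seeded generator. Rectangles are
half-open (left/bottom edge inclusive) so shared edges assign
unambiguously.

**Growth.** Per-plot height trajectories follow a 3-parameter logistic
h(t) = K / (1 + exp(−r (t − t₀))). The study observes only five time
points (24, 45, 57, 74, 81 days after sowing), so the simplest monotone
saturating curve suffices. Default curves give the tropical/subtropical
(TST) pool a taller asymptote and later inflection than the temperate
(TEM) pool (K = 290 vs 240 cm, t₀ = 62 vs 52 d), with the mixed pool in
between; plots get ~4% multiplicative Gaussian variation of K and 2 cm
observation noise. A seeded 19.4% of plots is flagged abnormal
(lodging), matching the exclusion rate of the emulated trial.

**Scene rendering.** Terrain is a smooth sinusoidal relief (default 8 cm
amplitude over 40 m) on a constant base elevation. Plants sit on the
plot's planting rows at the seeding density and are rendered as truncated
(flat-topped) paraboloid crowns whose flat top lies exactly at the plot's
true height. Crown radius grows with height
(R = 0.04 + 0.30·h, capped at 0.45 m; flat inside 0.8·R), which produces
the two regimes the analysis needs:

* at the first campaign (h ≈ 5–10 cm) crowns are small and most soil is
  exposed, the regime the ground classifier requires;
* by mid-season crowns merge into closed flat-topped hedgerows, so the
  plot-wise maximum of the rendered surface — and hence the mean of block
  maxima — equals the true height.

Spectra are two-class: canopy pixels greener than red (0.35/0.18), soil
pixels redder than green (0.20/0.30), optional Gaussian band noise. A
pixel renders as vegetation only where the canopy surface reaches 85% of
the local plant's full height: crown-edge pixels are mixed soil/leaf in
real imagery and keep a negative green-red index. Only the NGRDI sign
matters downstream; the band means are free parameters.

**Point clouds.** Points fall uniformly over the footprint with Poisson
count (density × area), take the surface height at their location (ground
where exposed, canopy elsewhere) plus optional vertical noise, and carry
true class labels for validation.

**What the generator does not emulate.** Photogrammetric reconstruction
error, tassels (the main cause of late-season underestimation on real
fields), within-plot height heterogeneity beyond a single plant height per
plot, occlusion and point-density variation with canopy structure, and
georeferencing error. Passing round-trip tests therefore demonstrate
correctness of the extraction pipeline, not robustness to those real-data
effects.

## Ground classification and DEM

The adaptive-TIN classifier seeds with the lowest point of each 0.20 m
cell (duplicate (x, y): lowest z, ties by input order), triangulates the
seeds, and iteratively adds any point whose vertical distance to the TIN
facet below it is ≤ 3 cm *and* whose segment to the facet's nearest vertex
makes an angle ≤ 1.5° with the facet plane, until a pass adds nothing.
Defaults (0.20 m / 0.03 m / 1.5°) are the working values for cm-scale
maize-field clouds at low vegetation cover and are exposed as parameters.

Numerical choices:

* Each pass evaluates all candidates against the pass's fixed TIN and
  accepts them in a batch; this is equivalent to ordering candidates by
  distance within the pass, because the TIN is only rebuilt between
  passes, and it keeps the classifier deterministic and vectorizable.
* A candidate outside the TIN's horizontal hull is tested against the
  extended plane of a facet incident to its nearest TIN vertex; otherwise
  hull-edge points on perfectly flat ground would never classify.
* The angle uses sin θ = |n̂ · s| / |s| with n̂ the facet normal and s the
  segment to the nearest facet vertex.

The DEM interpolates ground points linearly (barycentric on the ground
Delaunay triangulation); cells outside the hull — the blanks left by
removing non-ground points — are filled from the nearest ground point, so
no nodata remains in the field extent.

Known limitation (shared with the field method): a seeding cell containing
no true ground point seeds the TIN on canopy, and low crown-edge points
within the distance/angle tolerances can join the ground class. The
classifier is only intended for low-cover early-season clouds.

## Plot-height extraction

CSM = DSM − DEM cellwise, negative values clamped to zero (they are DEM
noise, not vegetation absence), nodata propagated. The vegetation mask is
NGRDI > 0 by default — justified by soil negativity rather than a tuned
threshold — and exposed as a parameter. Masked CSM cells are aggregated
over non-overlapping square blocks by maximum (default window 0.25 m,
about one crown); empty blocks are nodata. Taking the mean of local maxima
keeps every plant in the plot in the calculation while suppressing
low-level canopy returns that bias a plain mean downward; results are
window-sensitive on heterogeneous canopies, so the window is a config
knob. Per plot, the height is the mean of block values whose centers fall
in the plot's half-open rectangle, converted to cm.

Validation regresses estimated on reference heights by ordinary least
squares and reports R², the RMSE of the regression residuals, slope and
intercept.

## Temporal traits

AGRPH and CRPH carry one value per adjacent-day interval, indexed by the
interval's start day; the CRPH denominator is the final (fifth) PH
observation. CRPH values telescope: their sum is
(PH_last − PH_first)/PH_last × 100 exactly, which the tests assert.

Cleaning order is fixed: drop abnormal plots first, then derive AGRPH and
CRPH, then winsorize each trait per time point (column-wise) at the
2nd/98th percentiles — traits have strongly date-dependent scales, so
global winsorization would mix dates. Percentiles use linear interpolation
between order statistics. Winsorization preserves the profile count and
never leaves the observed range; applying it twice is a fixed point up to
the small shift of the percentile estimate on capped data (asserted within
2% of a column standard deviation).

## Fuzzy c-means and model selection

Fitting alternates the centroid update v_i = Σ_j u_ij^m x_j / Σ_j u_ij^m
and the membership update u_ij = 1 / Σ_k (d_ij/d_kj)^{2/(m−1)} until the
maximum membership change falls below 1e−6 or 500 iterations, and keeps
the best of 5 seeded Dirichlet initializations by objective. The objective
is non-increasing (alternating minimization), memberships stay normalized
to 1e−9, and converged centroids satisfy the weighted-mean fixed point —
all asserted. A point coinciding with one or more centroids splits its
membership equally among them; a cluster whose total weight vanishes keeps
its previous centroid rather than dividing by zero. Profiles are not
standardized before clustering by default (all coordinates of a trait
share units); per-column z-scoring is available as the ``standardize``
switch of the cluster-size scan.

Validity indices follow their classical formulations: Bezdek's partition
coefficient PC = (1/N)ΣΣu² and partition entropy PE = −(1/N)ΣΣ u ln u
(natural log, making the [0, ln C] bound exact); Xie–Beni
XB = ΣΣ u^m d² / (N·min_{i≠k}‖v_i−v_k‖²); Fukuyama–Sugeno
FS = ΣΣ u^m (d² − ‖v_i − x̄‖²) with x̄ the grand mean; Gath–Geva fuzzy
hypervolume FHV = Σ_i √det F_i with the u^m-weighted fuzzy covariance F_i,
and partition density PD = S/FHV where S sums memberships of points inside
the unit Mahalanobis ball of their cluster. Singular covariances are
regularized by an eigenvalue floor (1e−12 of the trace) with a warning —
this happens for degenerate clusters of repeated points. PE, XB, FS, FHV
propose their arg-min over the scan range; PC and PD their arg-max.

The majority rule is an unweighted vote with a 50% threshold: the count
proposed by strictly more than half the indices wins. Without a majority
the smallest count among the plurality winners is returned with a flag;
the emulated study never hits this case, but the rule must be total.

## Dominance

Hard assignment takes the maximum-membership cluster (ties to the lowest
index, flagged). For a cluster × background count table,
ClusterProportion = NG_incluster/NC_total and
TotalProportion = NG_incluster/NG_total. Dominance requires
ClusterProportion ≥ 1/3 and TotalProportion ≥ 2/3 — both non-strict,
matching the displayed inequalities of the rule rather than its prose
("more than"), and boundary behavior is unit-tested. If several
backgrounds qualify in one cluster, the highest ClusterProportion wins and
all qualifiers are reported. Empty clusters yield missing proportions.

## Pipeline and problem sizes

All randomness flows from the config seed; identical config and seed give
byte-identical outputs and manifest hashes. Every stage can run from the
serialized outputs of the previous stage. The default test and example
scenes use 8–48 plots at 2.5–5 cm raster cells and ~0.01–0.05 points/cm²
cloud density — the package's chosen desk-scale problem sizes, which keep
the full synthetic round trip under a minute while exercising every code
path; the generator scales to the full 800-plot, cm-resolution, 14
points/cm² regime of a real campaign with the same code.

## File formats

GeoTIFF rasters are written with `tifffile` carrying the
ModelPixelScale/ModelTiepoint georeference tags (plus an ESRI ASCII-grid
text alternative); point clouds are whitespace-delimited `x y z [class]`
text; tables are CSV; configs YAML; manifests and reports JSON. The
coordinate frame is a single local planar frame in meters, origin at the
field's southwest corner, x east, y north, cell-center registration.
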