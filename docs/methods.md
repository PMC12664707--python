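# Methods

This note records the models, conventions, numerical choices and
limitations behind `srsmetrics`, in the package's own terms. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Conventions

Arrays are indexed `(z, y, x)` with coordinates attached to voxel centers;
lengths are mm, volumes cc (1 cc = 1000 mm³), dose Gy. Structure masks
store fractional per-voxel occupancy in [0, 1]; a target as small as
0.04 cc spans only ~40 voxels at 1 mm spacing, so sub-voxel occupancy is
essential throughout. Analytic shapes are voxelized by averaging an
indicator over 3×3×3 subvoxel centers.

## The cumulative DVH and its queries

`compute_cdvh` builds the cumulative curve directly from the sorted
occupancy-weighted voxel doses — no histogram binning, hence no bin-width
free parameter. Queries (`volume_at`, `dose_at_volume`, `dose_at_percent`)
interpolate linearly between adjacent sorted voxel doses, which makes the
dose-at-volume query and the isodose-volume curve mutually inverse on
strictly decreasing segments (relative tolerance 10⁻⁴ by construction).
Plateaus (uniform-dose regions) resolve to the plateau dose itself,
reading "minimum dose of the hottest v cc" as an infimum. The curve equals
the structure volume exactly at threshold 0.

**Sub-voxel refinement of structure DVHs.** Pairing a boundary voxel's
*whole-voxel* dose with its *fractional* occupancy smears near-extreme
dose statistics of small structures by a substantial fraction of the
per-voxel dose range (several percent of the near-minimum dose for a 7 cc
target in a steep gradient). Structure DVHs are therefore accumulated at 3
subvoxels per axis: the dose field is linearly interpolated and paired
with a *re-sharpened* occupancy, reconstructed by classifying each
subvoxel against the structure's 0.5-level boundary surface (below). The
evaluation-region DVH is intentionally *not* refined: a (near-)binary
region has no partial boundary to resolve, center-sampled doses are
unbiased there, and interpolation would only add chord bias where the dose
profile has a kink. Total volume is preserved exactly in both cases.

## Boundary surfaces and margin offsets

`expand_mask` offsets a structure boundary by a signed distance (positive
outward), as required for the GTV ± 2 mm evaluation structures. The
boundary is the 0.5 level of the fractional occupancy, extracted as a
point cloud:

1. zero-pad, refine ×2 (linear), Gaussian-smooth (σ = 0.8 refined voxels)
   and triangulate with marching cubes;
2. Newton-project vertices and face centroids onto the smooth 0.5 level
   set (removes interpolation scatter, leaving ~0.01 mm);
3. push each sample outward by `0.90 h² H`, where `H` is the local mean
   curvature estimated from the field and `h` the mean voxel size. The
   constant 0.90 absorbs the known inward bias of the 0.5 level of
   box-filtered occupancy on convex boundaries plus the Gaussian
   pre-smoothing; it was calibrated once on analytically voxelized spheres
   over R/h ∈ [3, 20] at two grid spacings (residual bias ≤ 0.013 mm) and
   is not a tuning knob.

Each subvoxel center then gets the unsigned distance to the nearest
surface sample (KD-tree, restricted to a band around the boundary), signed
by the interpolated occupancy; the offset region `{sd ≤ d}` is thresholded
with one-subvoxel anti-aliasing and block-averaged back to fractional
occupancy. On 1 mm spheres this reproduces offset-sphere volumes within
~1% for ±2 mm offsets (tolerances asserted: 2% expansion, 3% contraction
and round trip). The 2 mm contraction is only constructed for structures
of at least 0.496 cc; below that the dependent metrics report
not-applicable.

## Metric definitions

All Gy/cc/mm-valued metrics and all ratio indices are documented in the
API reference (`MetricReport.ABBREVIATIONS` maps report fields to the
field's customary abbreviations). Points worth recording:

* The near-extreme doses use 0.01 cc units (`D_(V-0.01cc)`, `D_0.01cc`)
  for targets above 0.20 cc and the percent doses (`D_95%`, `D_5%`) at or
  below it, where 0.01 cc would exceed 5% of the target.
* The heterogeneity percentage is the near-minimum dose relative to the
  near-maximum dose (100%); when the prescription is assigned to the
  near-minimum dose, as in the phantom default, this equals "PD relative
  to D_near-max".
* `TV_PIV` (target volume within the prescription isodose volume) is the
  GTV DVH evaluated at PD, so the identities `PCI · rPCI = 1` and
  `rPCI · (TV_PIV/V_GTV)² = mPITV` hold exactly, and the PITV evaluated at
  the GTV D_eIIV equals 1 within 10⁻³ on any plan — the "false perfection"
  that motivates the coverage-adjusted and absolute metrics.
* PIV spillage is reported both set-theoretically (`V(PIV \ GTV)`, the
  normal-tissue exposure, primary) and arithmetically (`V_PIV − V_GTV`);
  the two differ by the uncovered GTV volume.
* If the half-reference isodose volume reaches the grid boundary, GI and
  AGD values are lower bounds; they are flagged (`TruncationWarning`, and
  the `truncated` list in reports) rather than silently reported.
* The evaluation region for IIDV/D_eIIV defaults to the whole dose grid; a
  body mask may be supplied. The choice is recorded in every output.

## The analytic phantom

The radial dose model about a focus point:

* interior (`r ≤ R`): `D(r) = D_c − (D_c − D_b)(r/R)^p` — a center boost
  with boundary dose `D_b` and center dose `D_c = c·D_b`;
* exterior: `d ln D / d ln r = −k (r/R)^η`, i.e. a power-law falloff of
  exponent `k` for η = 0 and `D(r) = D_b exp(−(k/η)((r/R)^η − 1))` for
  η > 0. Positive η makes the local log-log falloff exponent grow with
  distance, as in measured plans where dose-halving distances are roughly
  constant in millimetres (equal-mm halving implies an increasing log-log
  slope).

Every isodose region is a ball around the focus, so isodose radii,
IIDVs, D_eIIV, GI, AGD and spillages all have closed forms. Two optional
deviations from perfect conformity keep cohort analyses non-degenerate
while preserving the closed forms:

* a **dose-focus offset** δ relative to the target center: target
  coverage, conformity and spillage become sphere–sphere lens volumes
  (still closed-form). Without it a concentric phantom is perfectly
  conformal — coverage ≡ 100%, spillage ≡ 0, PCI ≡ 1 — and every
  conformity-related trend is degenerate.
* the **falloff curvature** η: with a single exponent all four GI
  variants are identically `2^(3/k)`; η > 0 separates them in the
  empirically observed direction (the higher the target coverage by the
  reference IDS, the lower the GI) and, for η > 1, makes the AGD from the
  D_eIIV surface exceed the AGD from the prescription surface.

Both default to off, so the spec-level oracle identities
(`mGI = 2^(3/k)`, `AGD = r_ref (2^(1/k) − 1)`, `D_eIIV(V_GTV) = D_b`)
hold exactly for the plain model. The prescription dose is either an
explicit fraction of `D_b` or, by default, the clinical near-minimum rule
applied to the voxelized target DVH. Dose is sampled at voxel centers (as
TPS dose grids are); voxel-averaging would smear the profile kink at the
target surface. Optional multiplicative log-normal dose noise (seeded) is
available for robustness experiments; the grid auto-sizes to contain every
half-reference isodose any metric probes, and an explicit extent that
cannot contain the 50% prescription isodose raises an error.

### Oracle tolerances

Closed-form expectations carry a priori tolerances reflecting 1 mm
voxelization: 3% relative for ratios and volumes, 0.1 mm for distances,
with two principled extensions:

* quantities defined by an isodose surface within one voxel of the target
  boundary resolve a sub-voxel sliver; they get an absolute floor of half
  a subvoxel-thick shell over the target surface, `4πR²(h/3)/2` (the
  geometric information limit of the lattice at the DVH refinement used);
* volumes derived from a rule-based prescription dose inherit the PD's
  own 3% tolerance scaled by `d ln V / d ln D = 3/k`.

A convergence property is asserted alongside: halving the grid spacing
reduces the mean |voxelized − closed form| error.

## The synthetic cohort

`make_cohort` draws stratified log-uniform target volumes over
0.04–48.09 cc (one sample per log stratum, so the sample is log-uniform
yet covers the range at one-stratum resolution) and maps them through a
volume-dependent parameter schedule. The schedule is a *tuning choice*
designed so that cohort-level analyses have recoverable structure:

* the falloff exponent `k(V)` peaks (6.0) at 0.72 cc with a locally steep
  kink (±0.3 decades at 1.2 log-units/decade, gentler beyond, floor 1.2):
  the dose falloff outside the target — and hence the AGD and the
  GTV+2 mm marginal-dose ratio — is steepest/shortest there, and the
  volume-split rank correlations change sign at that volume;
* the internal heterogeneity `c(V) = D_c/D_b` peaks (1.7) at 1.71 cc with
  the same kink shape, so the near-min/near-max percentage is lowest
  (most heterogeneous) and the GTV−2 mm dose ratio highest there; the
  resulting prescription-IDS percentages span ~88% (0.04 cc) down to
  ~44% at the peak;
* curvature η = 2.1 and a radius-scaled focus offset δ = 0.15 + 0.08·R mm
  give the GI-variant ordering and the AGD(D_eIIV) > AGD(PD) direction a
  consistent, detectable margin, with D_eIIV coverage rising from ~89% to
  ~94% across the volume range;
* targets ≤ 3 cc are voxelized at 0.5 mm (larger ones at 1 mm): small
  targets are cheap to refine, and the finer lattice keeps extremum
  recovery well above the voxelization noise floor of the flat AGD dip.

The kink constants were fixed by solving the closed-form oracle curves for
the required extremum locations and detectability margins before the
voxelized pipeline was run against them.

What the generator does **not** emulate: MLC/arc delivery and beam models,
Monte Carlo dose noise spectra, irregular or multi-focal targets,
anatomy-dependent falloff anisotropy, and the DVH shoulder shapes of real
optimizer output. Passing the cohort tests therefore demonstrates that the
*metric and statistics machinery* recovers structure that is present, not
that real cohorts have this structure.

## Statistics

* Spearman and Wilcoxon wrap `scipy.stats` (tie-corrected; the signed-rank
  test is exact for n ≤ 25 without tied absolute differences, normal
  approximation otherwise; zero differences discarded; all-zero input
  yields a NaN marker). Constant input to the rank correlation yields a
  NaN marker (undefined), not an exception.
* The Jonckheere–Terpstra trend test is implemented from its
  Mann–Whitney-sum definition, `J = Σ_{i<j} #(x_i < x_j) + ½#(x_i = x_j)`
  over ordered group pairs. The p-value is by seeded permutation (default
  9999 reassignments, vectorized over a fixed sort order when the pooled
  values are tie-free; add-one estimator `(1 + #extreme)/(P + 1)`), with a
  normal approximation from the exact null moments as an alternative
  method. Alternatives: increasing, decreasing, two-sided (centered on the
  null mean). The permutation test's null rejection rate is asserted ≈ α
  within binomial error, and the statistic is cross-checked against a
  brute-force pair-count oracle.
* Split correlations include the threshold row on *both* sides (the
  splits are ≤ and ≥); sides with fewer than 4 pairs are NaN-marked.
* `find_extremum` reports the target volume of the extremal row; ties
  report the smallest volume with a tie flag.
* Significance uses the three-level scale p < 0.05 (*), < 0.01 (**),
  < 0.001 (***); no multiple-testing correction is applied.

## I/O

The native array-plan dialect is NIfTI arrays plus a JSON sidecar with
units, geometry, prescription and the evaluation-region choice; round
trips are lossless (bit-identical dose). DICOM-RT support reads an RT Dose
(DoseGridScaling, GridFrameOffsetVector, native grid — no resampling) with
an RT Structure Set whose CLOSED_PLANAR contours are rasterized to
fractional occupancy by 4× supersampled point-in-polygon testing; frames
of reference are checked. The writer emits a minimal standard-conformant
pair (contours from the 0.5-level of the occupancy, per axial slice);
holes within a slice contour are not modelled. Reports round volumes to 3
decimals (cc), doses to 2 (Gy) and distances to 1 (mm).

## Known limitations

* Quantities whose defining isodose hugs the target boundary (D_eIIV
  coverage and spillage, near-minimum doses of concentric plans where the
  profile kink sits exactly on the boundary) carry voxelization
  uncertainty at the half-subvoxel-shell level; the oracle tolerances
  make this explicit rather than hiding it.
* The evaluation-region default (whole grid) makes IIDVs grid-dependent
  for doses near zero; all shipped metrics probe doses where the isodose
  volume is contained (or flagged when truncated).
* Statistical wrappers inherit scipy's tie handling; the JT permutation
  falls back to a slower generic path when pooled values contain ties.
* DICOM-RT reading assumes axial, axis-aligned geometry (identity
  orientation) and uniform slice spacing.
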