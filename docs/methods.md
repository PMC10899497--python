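# Methods

This note documents the model, the numerical choices, and — in most detail —
what the synthetic cohort generator does and does not emulate, so that
results obtained on synthetic cohorts are read with the right amount of
confidence.

## Scalp coordinates and geometry

The CPC system parameterizes the scalp by two arc-length proportions:
`p_NZ` along the nasion → inion geodesic (through the vertex) and `p_AL`
along the left → right preauricular geodesic constrained through the
sagittal point selected by `p_NZ`. On a triangulated scalp both geodesics
are realized as plane/mesh intersection curves: the sagittal plane contains
NZ, IZ and the head's up-axis (the normal of the fiducial plane, oriented
towards the scalp bulk); the coronal plane contains AL, AR and the sagittal
point. The intersection segments are stitched into a polyline and
parameterized by cumulative arc length. On an icosphere the polyline is
inscribed in the true great circle, so the radial error is bounded by the
chord sagitta L²/8R — about 0.05 mm at subdivision 4 on a 92 mm head, well
below the 0.5 mm accuracy we test against the closed-form spherical
construction. The plane-slice curves are cached per head (the sagittal curve
once, coronal curves per distinct `p_NZ`), which makes scanning a 493-node
grid cheap.

Search spaces are rectangular CPC grids with **step 0.01** (about 2.8 mm on
an adult-sized head) inclusive of both endpoints; the default frontal grid
`p_NZ ∈ [0.15, 0.43] × p_AL ∈ [0.27, 0.43]` has 29 × 17 = 493 nodes, and a
temporoparietal grid `[0.52, 0.80] × [0.10, 0.26]` the same count. Nodes can
be masked to those whose cortical projection falls within a radius
(default 20 mm) of anatomical ROI centers in MNI space; grid step, ranges
and masking radius are all configurable.

Scalp → cortex projection casts the inward surface normal (barycentrically
interpolated area-weighted vertex normals, oriented outward by a centroid
test) against the cortex mesh with a vectorized Möller–Trumbore
intersection. If no intersection occurs within 80 mm — possible on partial
cortical caps — the nearest cortex vertex to the ray is returned and the
result flagged, rather than failing. MNI transforms are plain affine maps of
cortical points.

## E-field surrogate

Full FEM field modelling is out of scope; the surrogate assigns voxel x the
weight `exp(−tang²/2σ²) · exp(−depth/λ)`, where `tang` is the distance from
the coil axis and `depth` the scalp-normal distance beyond the coil
center's cortical projection (clamped at zero above it). Defaults σ = 10 mm
(the focality scale of a 70 mm figure-of-8 coil), λ = 20 mm; weights are
max-normalized and entries below 5 % of the maximum dropped, giving a sparse
support of a few dozen voxels on the default mask. The surrogate is
isotropic: coil orientation is carried as metadata and does not currently
shape the field. Externally simulated field-magnitude volumes can be
imported instead (nearest-neighbour resampling onto the mask grid, then the
same normalization and floor), so orientation-sensitive FEM fields enter
through that path.

## Connectivity and the lazy seed-map identity

Preprocessing offers per-voxel OLS nuisance regression and a zero-phase
4th-order Butterworth band-pass (0.01–0.1 Hz). The filter's reflect padding
is sized to three periods of the low band edge; scipy's default pad of a few
samples is far too short for infra-slow cut-offs and leaves visible edge
transients. Runs are concatenated raw, cropped to the requested scan
duration (leading volumes; `floor(minutes·60/TR)`), filtered, and
standardized to zero mean and unit population variance per voxel. Constant
voxels are flagged and zeroed so they drop out of correlation sums.

For standardized data `Z` (V × T) and sum-normalized weights `w̃`, the
E-field-weighted average of correlation rows is `S = Z(Zᵀw̃)/T` — exact,
including the self-correlation `r(v,v) = 1`, with O(VT) cost and no V × V
matrix. Stacking many placements' weights into a sparse matrix turns a
whole search space into two matrix products, which is what makes the
duration-stability sweeps tractable. No Fisher transform is applied
anywhere; NTA and the similarity indices are plain Pearson correlations.

## NTA, targeting, stability

`NTA = −corr(S, P)` is computed over all in-mask voxels by default; an
exclusion set is accepted but empty unless requested. Nodes whose scoring
fails (e.g. empty E-field support at a grid edge) are flagged invalid and
skipped by targeting; only an entirely invalid map is an error.

The classic target is the argmax (ties: lowest (i, j) lexicographically).
The cluster target thresholds at the (100 − x) percentile of valid-node
values (rank-based, hence invariant to any strictly increasing transform of
the map; linear interpolation; default x = 5), labels connected components
under the hexagonal six-neighborhood {(±1,0), (0,±1), (−1,1), (1,−1)}
(four- and eight-neighborhoods available), picks the largest cluster (ties:
larger NTA sum, then lowest minimum node), and returns the center-of-gravity
with mass = NTA excess over the threshold (uniform fallback when all
excesses vanish; a geometric-centroid flag exists). The cluster target need
not be a grid node.

Stability between two sessions uses three indices: mean per-placement
correlation of stimulation networks, correlation of NTA maps, and the
intraindividual distance between the two targets' cortical projections in
MNI space, with ~1 cm (10 mm, configurable) as the stability criterion.
Across subjects the interindividual distance is the mean pairwise MNI
distance (a distance-to-centroid variant is available behind a flag), and
the inter/intra ratio summarizes the balance of desirable between-subject
spread against within-subject noise. Sessions are paired day-1 versus
day-2, one pair per subject.

## Synthetic cohorts

The generator's purpose is to provide cohorts with *known* ground truth on
which the whole pipeline — geometry, E-fields, connectivity, targeting,
stability — can be validated. A subject's BOLD signal is a latent-factor
Gaussian process

    x(t) = A s(t) + local_sd · G w(t) + noise_sd · ε(t)

with three components, all band-limited to 0.01–0.1 Hz:

- **Networks.** `A` holds K = 5 topographies: K − 1 focal von Mises–Fisher
  bumps on the spherical cortex (concentration κ = 200, ≈ 5 mm half-width)
  plus one **multi-focal pathology network** (five bumps at κ = 30 spread
  over the posterior head), mimicking the multi-focus character of
  meta-analytic disorder maps. The latent covariance C is the identity with
  a single negative entry (−0.9) coupling the target network (index 0,
  centred under the default frontal search grid) to the pathology network,
  so the NTA-optimal placement sits over the target network by
  construction. Per subject, every bump center is rotated by a Gaussian
  angle (sd `jitter_deg`, default 6°), which is the sole source of
  desirable between-subject variation.
- **Local connectome.** `G` is a sparse Gaussian spatial smoother
  (length 12 mm, unit row norms), giving every voxel short-range
  correlations that travel with a seed. Without it, every seed map near a
  network peak is proportional to the same network pattern and the NTA
  surface is flat — the optimization would be ill-posed no matter how clean
  the scan.
- **Observation noise.** Independent per voxel, sd `noise_sd` relative to
  unit-amplitude bumps, default 3.0. The default is chosen so that 7-minute
  scans behave like the unstable regime reported for real data — roughly
  half the cohort exceeds the 1 cm criterion with the classic method — while
  28-minute scans with the cluster method are uniformly stable.

The implied voxel covariance `A C Aᵀ + local_sd²·G Gᵀ + diag(noise_var)` is
available in closed form, so noiseless NTA maps and **planted targets**
(classic argmax and cluster center-of-gravity of the noiseless map) are
exact. The pathological map is the implied-correlation row of the pathology
peak computed from the *signal-level* covariance (observation noise
excluded): it stands for a meta-analytic group map and is therefore
invariant to scan-noise settings.

Three simulation details matter for duration studies and were each the fix
for a measurable artifact:

1. Band-limited signals are rescaled by the filter's analytic white-noise
   gain, not by each realization's sd — pinning realized variances makes
   complete runs statistically special relative to partial-run crops.
2. Each run is filtered with a three-period burn-in on both sides and only
   the stationary interior retained; filtering a short segment directly
   lets the boundary padding inflate the realized autocorrelation (the null
   sd of a sample correlation came out 1.6× the exact value at T = 600
   before this fix).
3. A session's two 1200-volume runs are cut from one continuous 2400-volume
   realization, so re-concatenation and cropping introduce no splice
   artifacts. Independently simulated runs are still available by calling
   `simulate_bold` per run.

Runs are reproducible from `(base_seed, subject, session)`; subject models
from `(base_seed, subject)`.

**What passing on synthetic cohorts does and does not show.** The generator
reproduces the statistical structure the duration-stability question hinges
on — band-limited autocorrelation (T_eff ≈ 2·bandwidth·duration, so a
28-minute scan carries only ≈ 300 effective samples), seed-map geometry,
anti-correlated disorder topography, and between-subject topographic
variation. It does not emulate head-geometry variation (all subjects share
one spherical head), motion or physiological artifacts, scanner drift,
multi-band acquisition effects, realistic cortical folding (and hence
realistic E-field/scalp-cortex geometry), or real pathology topography.
Absolute similarity and distance values therefore do not transfer to real
data; the qualitative contrasts (longer scans stabilize, cluster beats
argmax, inter/intra ratio peaks for cluster at the longest duration) are the
meaningful outputs.

## Numerical choices and degenerate inputs

- Percentile thresholds use linear interpolation over valid nodes only.
- Ties in the classic argmax and in largest-cluster selection are broken
  deterministically (lexicographic node order) so repeated runs are
  bit-identical.
- Constant maps make Pearson correlation undefined and raise, as do empty
  supra-threshold sets, empty E-field supports after flooring, all-constant
  time series, and bands at or above Nyquist.
- Scan durations are cropped to `floor(minutes·60/TR)` leading volumes
  (7/14/21/28 min at TR 0.72 s → 583/1166/1750/2333 volumes); a configurable
  offset supports sensitivity checks on which segment is used.
- The target-recovery experiments compare each method against its own
  noiseless planted optimum: the cluster center-of-gravity carries a small
  deterministic offset from the classic argmax that is a property of the
  estimator, not an estimation error.
- Problem sizes used by the test suite and the acceptance script — default
  mask ≈ 1470 voxels (6 mm grid, ±2 mm shell, chosen to keep a 12-subject ×
  2-session × 4-duration sweep desk-scale), 493-node search space, 12
  subjects — are the package's default study conditions; all are
  configurable upward.

## Known limitations

- The E-field surrogate ignores coil orientation and tissue conductivity;
  quantitative field realism requires imported FEM volumes.
- CPC geodesics assume a roughly convex scalp between fiducials; deeply
  folded or incomplete scalp meshes may produce multiple slice components,
  of which the one nearest the fiducials is used.
- The stability framework assumes exactly two sessions per subject;
  additional sessions are ignored beyond the first two.
- Interindividual distance is a mean over pairwise distances, which grows
  with noise as well as with true spread; at very high noise the inter/intra
  ratio comparison between methods becomes seed-sensitive.
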