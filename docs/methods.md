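# Methods

## The measurement problem

The late embryonic *Drosophila* ventral nerve cord (VNC) carries three
bilateral pairs of Fasciclin 2 (Fas 2)-positive longitudinal fascicles
(medial, intermediate, lateral).  Once per segment these fascicles adopt a
compact, stereotyped transverse configuration — a *3D node* — and disperse
between nodes.  `vncorr` quantifies this architecture from a calibrated 3D
image stack by comparing transverse sections along the anterior–posterior
(AP) axis: sections that recur (the nodes) correlate strongly after rigid
alignment, dispersed internodal sections do not.  The derived readouts are
the internodal distance, the AP offset from a node to the internodal
correlation minimum, the AP asymmetry statistic `r`, and ROI/mask
fluorescence densities.

## Pipeline

1. **Isotropic rescale** (`preprocess.rescale_isotropic`) — linear
   interpolation to a single pitch (default: the finest native pitch),
   preserving physical extents to within one voxel.
2. **Crop and split** — manual crop box, or Otsu threshold of the AP
   maximum-intensity projection with a 2-voxel margin; optional
   hemisegment split at the ML midline (midline column assigned to the
   left half so the halves always reassemble).
3. **AP binning with per-bin MIP** (`preprocess.bin_and_project`) — the AP
   axis is cut into bins of nominally 1.65 μm; each bin's planes are
   collapsed by a voxelwise maximum.  `planes_per_bin =
   round(bin_length / pitch)`, so the realized bin length is an integer
   multiple of the pitch (e.g. 11 planes of 0.15 μm = 1.65 μm exactly;
   3 planes of 0.6 μm = 1.8 μm).  A trailing partial bin is dropped, not
   padded, to avoid a systematically dimmer final section.
4. **Pairwise rigid registration** (`register`) — for each section pair,
   the intensity centroids are aligned first; a rigid transform
   (translation + optional rotation about the section centre) is then
   refined by maximizing Mattes mutual information (SimpleITK,
   dense sampling, regular-step gradient descent, minimum step 1e-6, at
   most 500 iterations).  Dense metric sampling makes the optimization
   deterministic.  If the refined transform scores a *lower* overlap
   Pearson correlation than the centroid start, the start is returned,
   flagged unconverged — MI ascent does not guarantee correlation ascent,
   and the matrices must never degrade below prealignment.
5. **Correlation score** (`register.correlation_score`) — Pearson
   correlation of the fixed section against the resampled moving section
   over their overlap, clipped to [0, 1].  Out-of-field samples are
   zero-filled and excluded from the overlap (never wrapped).  Pairs with
   under 50 % overlap or constant overlap intensity yield NaN, the
   missing-value sentinel.  The figures' 0–1 colour scale never names its
   score; post-registration Pearson correlation is the standard reading of
   "image cross-correlation" and is what this package computes (the raw MI
   metric value per pair is also stored for comparison).
6. **Correlation matrix** (`corrmatrix`) — entry (i, j) is the registered
   correlation of sections i and j.  Only the upper triangle is computed
   and mirrored: this halves cost and enforces the symmetry that the score
   obeys only up to registration asymmetry (empirically a few 1e-3).
7. **Node detection** (`traces.detect_nodes`) — nodes are peaks of the
   mean off-diagonal row correlation, filtered by prominence (default
   0.05) and minimum separation (default half the estimated period).  The
   segmental period itself is estimated from the first autocorrelation
   peak of that profile (`estimate_period`), which is robust to individual
   missed peaks.  The profile is padded with its minimum so first/last
   segment nodes touching the matrix edge remain detectable; a boundary
   candidate is kept only if it reaches the height of the interior node
   peaks (within a quarter of the weakest interior peak's drop), which
   rejects internodal limbs truncated by the volume boundary.  Detected
   bins are then refined (`refine_node_bins`) to maximize each node's mean
   correlation with the other nodes — a sharper criterion than the row
   profile, whose peaks are broadened by the near-diagonal band.  The
   published analysis identified nodes manually; automated detection plus
   refinement replaces that step, and manual node indices are accepted
   everywhere a node list is consumed.
8. **Traces** (`traces`) — a node's trace is the mean correlation along
   the node row ± 1 row, with diagonal entries excluded ("± 1 row" could
   also be read as a ±1 column band; the row reading is implemented, and
   `extract_trace` exposes the column window for the alternative).  Traces
   from different nodes are rebased to a common origin, shifted by integer
   bins to maximize overlap with the running reference inside the
   25–57 μm window, and averaged with the sample (n−1) standard deviation
   (embryo counts in this kind of data are small, n = 6–10).  Shifts are
   integer bins only: traces live on the bin grid, and sub-bin shifting
   would interpolate correlation scores.
9. **Architecture metrics** (`traces.internodal_metrics`) — node positions
   are trace maxima, refined to sub-bin precision by a 3-point parabolic
   fit (detection itself stays on the grid); internodal distances are
   successive differences; each internode's node→minimum offset is the
   refined argmin position minus the preceding node position (positive =
   posterior; AP increases anterior→posterior and voxel centres sit at
   (index + 0.5)·pitch, which fixes the sign unambiguously).

## The asymmetry statistic r

With `gradient` the spatial derivative of the correlation trace along AP,

    r = (max(gradient) − |min(gradient)|) / ((max(gradient) + |min(gradient)|) / 2)

so |r| ≤ 2, r = 0 for a mirror-symmetric profile, and mirroring the
profile flips the sign exactly.  Measurement noise is handled by in-silico
resampling (`asymmetry.resample_r`): each trace position is redrawn from
Normal(mean_i, sd_i) and clipped to [0, 1] (correlation scores are
bounded), 500 replicates by default.  Per replicate, each internode —
delimited by the mean trace's peaks and split at its minimum — contributes
a least-squares line per limb; the replicate's max gradient is the largest
recovery-limb slope and its min gradient the steepest descent-limb slope.
A finite-difference global-extrema variant (`method="extrema"`) is kept
for sensitivity analysis.  The reported r is the replicate mean.

The difference-from-zero test (`test_r_zero`, default `mann_whitney`)
compares the replicate sample against its sign-flipped mirror.  Because
sample and mirror are perfectly dependent, the textbook independent-sample
null for U is wrong here (its variance is half the true one, inflating
type-I error to ≈ 0.17 at any sample size); the p-value is therefore taken
from an exact sign-flip randomization of the same U statistic (1999
resamples, fixed internal seed), which is calibrated under the null of
symmetry about zero — the suite verifies a rejection rate near 0.05 over
200 seeded runs.  A conventional one-sample Wilcoxon (`signed_rank`) is
also provided.

## Synthetic phantoms

`phantom.generate_phantom` renders the architecture with known ground
truth.  Geometry: nodes at (k + ½)·period along AP; three fascicle anchors
per hemiside, mirrored about the ML midline.  Between nodes each fascicle
centerline wanders from its anchor along a random per-internode direction,
scaled by a piecewise-linear envelope that is zero inside node windows,
rises to `dispersion_amp` at the envelope peak and decays to the next
node.  The peak sits at `(1 − a)·period/2 + a·min_offset` where
`a = dispersion_asymmetry`: a = 0 gives a symmetric triangular internode,
a = 1 puts the correlation minimum immediately at `min_offset` posterior
to the node (the wild-type configuration).  Centerlines are rasterized as
Gaussian tubes of `fascicle_radius`; node windows are multiplied by
`node_enrichment`; then PSF blur, optional Poisson noise (at an internal
scale of 100 photons per intensity unit) and Gaussian read noise are
applied, in that order, with all randomness drawn from `seed` (identical
parameters give bit-identical volumes).  `expected_trace` provides the
analytic noiseless oracle: for Gaussian tubes of radius a and PSF s, a
fascicle displacement d gives a normalized overlap of
exp(−d² / (4(a² + s²))), so the expected trace is that function of the
dispersion envelope — maximal at nodes, minimal at `min_offset`.

Presets encode the three published conditions.  The printed values fix
period and minimum offset (wild type 28 μm and 9 μm; the two mutant
classes 33 μm); nothing quantitative is printed about dispersion
amplitudes or noise, so those were calibrated once so that the full
pipeline reproduces the printed trace metrics, and are not revisited:

| preset | period | min_offset | asymmetry | amp | enrichment | noise sd | dropout |
|---|---|---|---|---|---|---|---|
| `wildtype`  | 28 | 9    | 1.0 | 3.4 | 1.5 | 0.02 | 0   |
| `puc_like`  | 33 | 9    | 0.5 | 3.2 | 1.3 | 0.05 | 0.5 |
| `zfh1_like` | 33 | 16.5 | 0.0 | 2.6 | 1.3 | 0.05 | 0   |

`puc_like` raises dispersion and drops the lateral fascicle per internode
with probability 0.5 (incompletely formed lateral connectives);
`zfh1_like` flattens the internodal profile by making the dispersion
symmetric with raised noise.  What the phantoms deliberately omit: cell
bodies, glia, commissures, photobleaching, embryo-to-embryo geometric
variability beyond the seed.  Passing tests therefore demonstrate that the
pipeline recovers a known periodic fascicular architecture under blur and
noise — not that it handles every nuisance structure of real embryos.

## ROI and mask quantification

"Average Integrated Density" follows the Fiji IntDen convention: per ROI,
sum of pixel intensities × pixel area; group statistics per ROI kind.
ROI pixel footprints are fixed by the ROI size alone and then centred to
the nearest pixel, so ROIs of one analysis are always the same size in
pixels.  No background subtraction by default (a `background` argument is
provided).  Mask-based quantification thresholds a reporter channel (Otsu
by default, fixed value optional) into a binary mask; inside + outside
integrated densities sum to the image total exactly.

## Problem sizes and numerical choices

The headline analyses (acceptance script and end-to-end tests) use
6-segment phantoms generated at 0.6 μm isotropic pitch and binned at the
nominal 1.65 μm (realized 1.8 μm), giving ~93–110 bins and ≈4300–6000
registrations per matrix, about 70–90 s each on one CPU.  The unit-test
phantoms are smaller (3–4 segments, 1 μm pitch).  Tolerances: recovered
distances and offsets are asserted within one realized bin; matrix mirror
asymmetry within 1e-3; transform inverse composition within 1e-6 μm /
1e-8 rad.  Peak ties in parabolic refinement fall back to the grid
position; degenerate (constant) sections or empty overlaps propagate NaN
sentinels through the matrix rather than raising.

## Known limitations

- Registration is 2D rigid per section pair; no deformable or 3D
  volumetric registration, no multi-resolution pyramid.
- Node detection assumes an approximately periodic profile; strongly
  aperiodic or single-node matrices require manual node indices.
- The r limb fits use landmarks from the mean trace; profiles whose
  minima move by more than a limb under resampling are summarized only
  approximately.
- The analytic `expected_trace` ignores registration compensation of
  common-mode fascicle displacement, so measured traces sit slightly
  above it between nodes; its extrema locations are exact.
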