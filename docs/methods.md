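# Methods

## System and measured quantities

The pipeline quantifies fluorescence time lapses of phase-separated model
membranes (coexisting liquid-ordered Lo and liquid-disordered Ld phases)
coupled to a reconstituted actin cortex.  Channel 0 carries a membrane dye
that partitions into the Ld phase (bright Ld on dark Lo, or the inverse for
monolayer mixtures); channel 1 carries labeled actin, which enriches over
the Lo phase and condenses into bright actomyosin foci under myosin
activity.  The measured quantities are the total Lo/Ld boundary contour
length and its change against a pre-addition baseline, per-phase domain
counts and areas, the normalized actin-binding curve, and the distribution
of distances between neighboring actomyosin clusters.

## Models

**Contour growth.**  After actin filaments adhere, the boundary length
grows as

    L(t) = L_final * (1 - exp(-(t - t0) / tau)),    t >= t0,

with the lag `t0` fixed at 1 min (the time at which the first domain
deformations become visible), leaving `(L_final, tau)` free.  The fit is
nonlinear least squares with a deterministic closed-form initialization
(`L_final0` from the series maximum, `tau0` from a log-linear regression of
`log(1 - L/L_final0)` on the early points) multi-started over ×{0.5, 1, 2}
perturbations of both parameters; the best converged optimum is kept, which
makes the fit reproducible and robust to shallow local minima.  Parameter
uncertainties are the square roots of the covariance diagonal at the
optimum.

**Line-tension temperature law.**  Line tension between Lo and Ld falls
approximately linearly with temperature, `gamma ≈ gamma0 (TC - T)/TC`,
vanishing at the critical temperature `TC`.  If the adhering filaments
deposit a temperature-independent boundary energy `E = gamma L`, the final
contour-length change obeys

    L(T) = A * TC / (TC - T),    A = E / gamma0.

The model is linear in the single amplitude `A`, so the unweighted
least-squares solution is closed form, `A = Σ L_i f_i / Σ f_i²` with
`f_i = TC/(TC - T_i)`; an inverse-variance weighted mode is available.  Two
deliberate choices: the temperature scale is **Celsius** — the law is
anchored at `T = 0 °C` (where `L = A`) with `TC = 37 °C`, the miscibility
temperature of the 1:2:1 DOPC:DPPC:cholesterol mixture; and the default fit
is **unweighted** — the three measured lengths have very unequal standard
errors, and inverse-variance weighting lets the tightest point dominate the
amplitude, which is not what a boundary-energy summary of all three
temperatures should do.  The fit is intended for the few-point
final-length-versus-temperature summary, not for raw per-frame series.

**Energy ratio.**  `energy_ratio` compares the free energy for one
saturated lipid to transfer between phases (default 1.5 k_BT) with the
boundary-elongation energy `gamma * dl` (default 1 pN × 1 nm = 1e-21 J),
both expressed in k_BT at the experiment's room temperature (24 °C =
297.15 K, exposed as a parameter).  With the defaults the ratio is ≈ 6.2.

## Segmentation chain

Each membrane frame passes through, in order: background correction →
local adaptive threshold → Canny boundary map → XOR combination →
morphological closing → small-hole removal → Laplacian-of-Gaussian (LoG)
small-object merge → speckle removal → contrast screening →
connected-component labeling.  The stages that required concrete design
decisions:

- **Background correction** (`correct_background`): the illumination field
  is estimated as a low-order (default quadratic) polynomial surface fitted
  to the *majority intensity class* (pixels split at the global Otsu
  threshold), with one 3-MAD outlier-rejection pass.  Both phases are
  modulated by the same multiplicative field, so either class alone
  determines it, and restricting the fit to one class removes the strong
  bias a whole-frame fit picks up from the foreground.  Division by the
  unit-mean surface (or subtraction, per `background_mode`) preserves the
  frame mean.  A rolling-ball mode is available.
- **Adaptive threshold**: a pixel is compared with its Gaussian-weighted
  local mean (window `adaptive_block_size`, ≈ 4× the expected domain
  diameter).  Where the pixel differs from that mean by less than three
  times the estimated noise the local comparison carries no information
  (deep inside one phase it degenerates into coin-flipping on noise), and
  the pixel is classified by the global Otsu threshold instead.  A small
  epsilon keeps this band non-empty on noiseless images.
- **XOR combination**: the boundary map refines the threshold mask where
  the two classifiers disagree: `mask XOR (edges ∩ (mask XOR bright))`,
  with `bright` the global-Otsu intensity class.  Along detected edges,
  pixels the local threshold classified against their own intensity class
  are flipped — boundary pixels lost to edge exclusion are restored,
  spurious ones removed.  On a clean mask the disagreement band is empty
  and the stage is a no-op (idempotence), which is what fixes the operand
  order among the several readings of "combine with XOR": the alternatives
  measurably bias the boundary (plain union ≈ +0.5 px dilation, carving
  out in-mask edges ≈ −0.7 px erosion), enough to violate the accuracy
  target below at 10–15 px domain radii.
- **LoG merge**: multiscale LoG detections whose footprint does not
  intersect the existing mask are added as recovered small objects; the
  merge can only add objects, never alter existing ones, so disabling it
  never increases the object count.
- **Contrast screening**: labeled objects whose mean intensity differs
  from the background mean by less than `min_contrast_snr` (default 3)
  times the estimated per-pixel noise are discarded; this is what makes a
  featureless noise-only frame segment to zero labels instead of
  morphology-amplified speckle.

Operator parameters are not dictated by the underlying recipe, so the
defaults (`adaptive_block_size = 101 px`, `canny_sigma = 1 px`,
`closing_radius = 1 px`, min hole/object areas 9 px²) were calibrated once
against the synthetic fixtures: Canny at σ = 2 px traces a smoothed
boundary whose XOR combination erases genuine fine boundary structure
(measured −17 % of contour-length change on deformation fixtures, vs −5 %
at σ = 1), and the same applies to a 2-px closing disk.  Measured fidelity
at the defaults: Jaccard ≈ 1.00 against truth masks on noiseless fixtures
and ≈ 0.99 at the default noise level, for domain radii ≥ 10 px.

## Contour length

The default estimator extracts the 0.5 iso-contour of the lightly smoothed
binary mask (Gaussian σ = 0.75 px, then marching squares) and sums polyline
lengths.  The smoothing scale balances two biases: unsmoothed marching
squares overestimates smooth boundaries by ~5 % (staircase effect), while
heavier smoothing erases genuine boundary structure (σ = 1 px loses ~6 % of
the added length on strongly deformed fixtures).  At σ = 0.75 both errors
stay within ~±2–3 %.  Contours are left open at the image border, so
border-touching structure contributes no artificial closing edges.  The
literal edge-pixel-count reading (`canny_pixel_count`) is retained as a
mode for fidelity comparisons; it is anisotropic and overestimates
diagonal boundaries by up to ~20 %.

## Cluster analysis

Clusters are scale-space LoG maxima on the min-max-normalized actin frame
(σ range 2–6 px, relative threshold 0.1, overlapping detections merged
keeping the stronger response), refined to the intensity-weighted centroid
of a ±σ window (measured mean localization error ≈ 0.2 px on spot grids).
Neighbor distances are the edge lengths of the Delaunay triangulation of
the centroid set — per frame, all edge lengths are reported (the
distance-distribution reading), plus mean ± sd.  Cocircular ties are broken
by the triangulation backend's deterministic convention.  Frames with fewer
than three non-collinear clusters cannot be triangulated; they fall back to
nearest-neighbor chain distances, are flagged `degenerate`, and are
excluded from the pooled edge tables.

## Synthetic data generator

The generator emulates the statistical and geometric structure the
measurement stages assume, with exhaustive ground truth:

- **Domains** are Fourier-perturbed circles (2 random harmonics of order
  2–5, relative amplitude ≤ `domain_irregularity`, default 0.05; 0 gives
  exact circles).  Areas and perimeters are polygon-exact (512 vertices,
  convergent well below 0.1 %), so analytic truth exists for every frame.
- **Rendering**: 4× supersampled rasterization gives anti-aliased ~1 px
  edges comparable to diffraction-limited data at 0.16 µm/px; a fixed
  low-order polynomial illumination surface multiplies the frame
  (`background_amplitude`, default 0.2) and Gaussian noise is added
  (default σ = 2 % of dynamic range — an EMCCD readout approximation;
  Poisson-like regimes are reachable by raising it).  The actin channel is
  the complement-phase texture plus isotropic Gaussian cluster spots.
- **Events** are scripted, not emergent: `translate` and `deform` act per
  frame; `split` replaces a domain by two equal-area children and `fuse`
  replaces two domains by one of summed area, both *instantaneously at the
  scripted frame*, so count steps align exactly with the script.  After
  every modification each domain is rescaled to its conserved target area,
  so total domain-phase (and hence Lo) area is constant to < 0.5 % by
  construction.
- **Kinetic sequences**: when `kinetic_params` is set, a shared amplitude
  of one extra harmonic (`kinetic_mode`, default 3) is solved per frame by
  bisection so the *union perimeter* equals baseline + the mono-exponential
  target, at exactly conserved areas.  The harmonic is deliberately low:
  the added boundary structure must live above the optical/morphological
  scale for any measurement pipeline to resolve it.  Unreachable targets
  raise an error instead of silently saturating.
- **Determinism**: one seeded generator per sequence drives placement,
  shape phases, cluster positions and noise; equal configs are
  bit-identical.

What the generator does **not** emulate: photon (Poisson) noise statistics,
diffraction side lobes and PSF anisotropy, channel misregistration and
chromatic offsets, focus drift and photobleaching, domain Brownian motion,
and any physical dynamics of contraction (event kinematics are chosen for
testability — magnitudes of domain speeds and deformation rates are not
constrained by data).  Passing tests therefore demonstrate correctness of
the measurement chain on well-posed inputs, not robustness to every real
microscopy artifact.

## Numerical choices and degenerate inputs

- 0-based pixel indexing, (row, col) order internally; all reported
  centroids are (x, y) in µm, conversion applied at reporting time.
- Time axis from `frame_interval` metadata, minutes throughout fitting;
  frame 0 is acquisition start; the ΔL baseline frame defaults to 0 (the
  last pre-addition frame is the intended choice and is user-specified).
- All-background frames segment to zero labels without error; empty masks
  have contour length 0; flat binding signals raise (normalization
  undefined); `tau ≤ 0`, times before `t0`, and `T ≥ TC` raise.
- The mono-exponential `tau` is bounded positive; a fit pinned at the
  bound is flagged (`tau_at_bound`).
- Pipeline runs write a manifest with SHA-256 hashes of every product;
  identical config + seed reproduce byte-identical CSV/JSON outputs.

## Problem sizes

The validation suite runs on 200²–480² px scenes with 1–16 domains and
1–10 frames, 200 replicate fits for the kinetic-recovery statistics, and
exhaustive Delaunay oracles up to n = 10 points; these sizes make every
ground-truth comparison polygon-exact while keeping the whole suite fast.

## Known limitations

- Segmentation accuracy is quoted for domain radii ≥ 10× pixel size;
  smaller domains lose proportionally more boundary to half-pixel effects.
- The contour estimator's ±2–3 % envelope is scale-dependent: boundary
  structure below ~10 px wavelength is attenuated by the σ = 0.75 px
  smoothing and by the 1-px morphological closing.
- Per-domain identity is not tracked across frames (aggregate counts and
  areas only), and clusters are not tracked or mass-estimated.
- Absolute contour lengths depend on the field of view; only changes,
  rates and fitted amplitudes are comparable across acquisitions.
- The line-tension amplitude's standard error is the covariance-based
  value from the unweighted fit; with three points it is dominated by the
  scatter of the points around the one-parameter law.
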