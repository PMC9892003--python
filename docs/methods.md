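# Methods

`polyneigh` analyses the spatial organization of ribosomes in
cryo-electron-tomography particle fields: given per-particle positions,
orientations and class labels from subtomogram averaging, it (i) maps the
probability of finding a neighboring ribosome at each position in the frame
of a reference ribosome, (ii) identifies polysome links from reciprocal
trailing/leading neighbor geometry, and (iii) quantifies which ribosome
states and translocon populations are enriched in polysomes with a
multinomial mixed-effects logistic regression. A synthetic vesicle-scene
generator provides ground-truthed data for every stage.

## Coordinate conventions

Positions are stored in Angstroms in the tomogram frame (right-handed,
origin at the tomogram corner); coordinates in voxel units are converted at
import as `(coordinate - origin_shift_voxels) * pixel_size`. Orientations
are intrinsic ZYZ Euler triples `(rot, tilt, psi)` in degrees, canonicalized
to `rot, psi in [-180, 180)`, `tilt in [0, 180]`. The matrix
`M = Rz(psi) @ Ry(tilt) @ Rz(rot)` maps tomogram-frame vectors into the
particle reference frame; this matches the convention of the common
subtomogram-alignment software family, and any consistent convention yields
identical statistics because the analysis depends only on relative
geometry (a property-based test asserts invariance under global rigid
motion to 1e-8 A). For membrane-bound ribosomes the particle-frame xy plane
is the ER membrane, z the outward normal.

## Neighbor histograms

For each ribosome, the vectors to its `n_neighbors = 4` closest neighbors
in the same tomogram, excluding neighbors beyond `max_distance = 100 A`,
are rotated into its particle frame and binned on a cubic grid of
`15 A` voxels. Ties at exactly 100 A are kept (`<=`); ties for the fourth
nearest are broken by ascending particle id, for determinism. The grid is
center-registered — voxel edges at odd multiples of 7.5 A, so the focal
particle occupies the exact center of the central voxel and the
trailing/leading hemispheres are treated symmetrically; with
`half_extent_voxels = 7` the grid spans +/-112.5 A (15 voxels per axis),
the smallest center-registered grid covering the cutoff. Counts are
divided by the total number of analysed neighbor vectors of the subgroup,
pooled across tomograms, so each histogram sums to 1. Subgrouping
(ribosome state, translocon population, or the membrane/soluble dichotomy)
applies to the focal particle only; neighbors are whoever is nearby. The
neighbor relation is not symmetric and the implementation never assumes it
is; each retained neighbor record also carries the inverse vector (focal
particle in the neighbor's frame) so the reciprocal test below never
requires the partner to have retained the focal particle.

## Trailing/leading masks and polysome links

Supra-threshold voxels of the membrane-bound histogram (probability
> 0.0005) and of the soluble histogram (> 0.0003) are split into
26-connected components. Each component is assigned to the trailing or
leading direction whose unit reference vector is closest in angle to the
component's probability-weighted centroid; a gap below 5 degrees is
ambiguous and is an error. Reference directions are explicit configuration
(the mRNA entrance/exit sides cannot be derived from the histogram alone);
synthetic runs use the planted offsets. Directional masks are dilated by 2
voxels (discrete ball) and unioned across the membrane and soluble
populations into one trailing and one leading mask for the dataset.

Two finite-size guards, both inactive at realistic dataset sizes, make the
procedure robust on small scenes: components supported by fewer than
`min_component_counts = 5` neighbor vectors are discarded as shot noise
(at realistic totals any supra-threshold component is supported by far
more), and the pipeline's `adaptive_direction_masks` raises both thresholds
by 1.5x and retries when cluster assignment is ambiguous — the thresholds
are per-dataset choices of the method, and on small scenes the defaults can
sit below the single-count level.

A trailing–leading connection between ribosomes i and j is confirmed
reciprocally: j must fall in the trailing mask in i's frame AND i must fall
in the leading mask in j's frame (the inverse calculation). Vector-in-mask
tests bin the vector with the histogram registration and look up the voxel;
no interpolation. Confirmed candidates are resolved to at most one upstream
and one downstream partner per ribosome — an mRNA threads a linear chain —
by global greedy matching in ascending distance (ties by particle ids).
Greedy matching rather than independent per-focal nearest choice because
the latter can give one particle two outgoing links when two focals select
it; the greedy solution is nearest-first, deterministic, and independent of
iteration order. A permissive mode is not needed for any shipped analysis;
the candidate set before resolution is available from the internals for
sensitivity work. Chains are maximal directed paths; cycles (possible on
closed vesicle geodesics) are opened at their longest edge and logged. A
particle is "in a polysome" if it participates in at least one confirmed
link.

## Association model

For ribosome r with state `s(r)` in tomogram `t(r)` and categorical outcome
`k` (reference category K):

    log P(y_r = k) / P(y_r = K) = beta_{k,s(r)} + u_{k,t(r)},
    u_{k,t} ~ N(0, sigma_k^2), independent over tomograms and categories.

The tomogram random intercept absorbs sample and imaging variability.
Estimation maximizes the Laplace-approximated marginal likelihood: the
per-tomogram integral over u is approximated at its mode, found by a
damped, batched Newton iteration on the per-tomogram sufficient statistics
(counts per state and outcome). For binary outcomes, adaptive Gauss–Hermite
quadrature (21 nodes centered and scaled at the Laplace mode) is available
as `estimation_method="agq"`; the two agree within reported standard errors
on simulated data (tested), and a one-dimensional numeric-integration
oracle reproduces the intercept-only fit. Penalized quasi-likelihood was
deliberately not implemented: it is known to be biased for binary and
multinomial responses, and Laplace/AGQ is fast enough here. Fixing
`random_effect_variance = 0` switches to the closed-form pooled multinomial
logit (predictions are per-state frequencies), used as a degenerate-limit
test.

Numerical choices: coefficients bounded at +/-30 on the log-odds scale;
log sigma bounded in [log 1e-4, log 50]; outer optimization L-BFGS-B with
finite-difference gradients, warm-started inner modes; observed information
by central finite differences of the negative log marginal likelihood
(step 1e-4 relative). Complete separation (a state observed in a single
outcome category) is detected up front, warned about, and the boundary
solution is returned with the state flagged — standard errors for flagged
states are not trustworthy. Degenerate tomograms with one observation are
retained; their intercepts shrink to the prior.

Predictions are conditional on a typical tomogram (u = 0), not
population-averaged; with a nonzero random effect the two differ (Jensen's
inequality), and the conditional quantity is the one the per-state
log-odds parameterize directly. Confidence intervals use the delta method:
probability-scale variance from the softmax Jacobian and the coefficient
covariance, interval built on the logit scale and back-transformed so it
respects [0, 1]. Contrasts between states are two-sided Wald tests on
coefficient differences using the fitted covariance; by default all state
pairs per non-reference outcome, with step-up Hochberg adjustment
(implemented directly from the step-up recursion; cross-checked against
statsmodels in tests). Fold increases divide the modelled mean and CI
bounds by the outcome's fractional abundance in the dataset (the
random-association probability); they are intended for log-axis display.

## Synthetic scenes

Each tomogram holds one spherical vesicle (radius 1000 A) with
membrane-bound ribosomes on the surface (frame z along the outward normal,
random azimuth) and soluble ribosomes in the interior. Polysome chains
grow by stepping from the current particle by the trailing offset expressed
in its frame, reprojecting onto the sphere, and setting the new particle's
azimuth so its leading direction points back along the chain; soluble
chains do the same in free 3D with a random spin about the leading axis.
Defaults: trailing offset (45, 30, 0) A, leading offset (-45, -30, 0) A —
voxel-center aligned, magnitude 54 A, antiparallel in-plane so that chains
run straight and second-order chain neighbors (~108 A) fall outside the
100 A cutoff; chance co-localization then cannot masquerade as a secondary
hotspot. The offsets and all densities are synthetic stand-ins chosen for
geometric plausibility, not measured values. Membrane density 1200 um^-2
gives ~150 membrane particles per vesicle, matching the particles-per-
tomogram scale of real ER-vesicle datasets while keeping chance in-plane
co-localization below the polysome signal at the default thresholds;
soluble particles are ~20% of the total. A 50 A hard-core separation
approximates ribosome excluded volume (rejection sampling; exceeding 1e4
consecutive rejections is an error advising lower density). Chain length
is 1 + Geometric(1 - c) where the continuation probability c is the seed
state's in-polysome propensity shifted by the tomogram's logit-scale random
effect (sd 0.5); states inside chains are abundance-reweighted by polysome
propensity and monosome states by its complement, so elongating states
dominate polysomes and hibernating states are essentially absent, with
marginal state abundances near the configured catalog (rough proportions
of ER-vesicle data; elongating propensity 0.70, hibernating 0.03).
Positional (5 A) and angular (3 degrees) Gaussian jitter is applied after
ground truth is recorded. Per-tomogram random substreams make the scene
reproducible and prefix-stable in the number of tomograms.

`generate_association_dataset` bypasses geometry and draws observations
from the association model exactly (tomogram effects on the log-odds
scale, softmax outcomes), for calibration tests: CI coverage, null
uniformity of Wald p-values, and fold-increase nulls.

What the generator does not emulate: missing-wedge particle loss and
orientation-dependent detection, non-spherical vesicle geometry, mRNA
curvature (planted chains are geodesic-straight), crowding by other
macromolecules, and classification error in state labels. Passing
recovery tests therefore demonstrate correctness of the geometry,
masking, reciprocal-link and inference machinery under the stated noise,
not robustness to those real-data effects.

## Problem sizes in shipped checks

The default test scene uses 20 tomograms (~3,700 particles, ~2,300 planted
links); the rigid-motion check uses a ~550-particle scene; model
calibration uses 100 replicates of 200 tomograms x 50 ribosomes (coverage)
and 200 reseeds of 60 x 40 (null uniformity); the fold-increase null uses
10,000 observations. These sizes give stable statistics at interactive
runtimes; all are configuration, not limits of the implementation.

## Known limitations

- Direction assignment needs user-supplied reference directions on real
  data; the package does not infer mRNA entrance/exit sides from maps.
- The greedy one-in/one-out link resolution cannot represent genuinely
  branched arrangements; branching candidates are resolved to the nearest.
- Conditional (u = 0) rather than population-averaged predictions; with
  large random-effect variance the two can differ noticeably.
- The Laplace approximation can bias variance estimates at very small
  cluster sizes (few ribosomes per tomogram); AGQ mitigates this for
  binary outcomes only.
- STAR import handles one particle loop per file; optics-group blocks are
  ignored, not interpreted.
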