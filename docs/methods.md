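# Methods

This note documents the models, conventions and numerical choices behind
`eyemapper`, and what the synthetic data do and do not establish.

## Coordinate and angle conventions

All lattices use doubled coordinates (h, v) with h + v even; the six
neighbours of a site are (h, v±2) (top v1 / bottom v4) and (h±1, v±1) (the
right pair v2, v6 and left pair v3, v5).  The eye frame is right-eye
canonical: x along the frontal midline, y ipsilateral, z dorsal; azimuth is
0 at the front and positive ipsilateral, elevation 0 in the lens-equator
plane and positive dorsal.  Because of the optic chiasm, the medulla's +h
axis corresponds to −h (anterior) on the eye; medulla grids carry a
`mirrored_h` flag and the eye map applies the mirroring.  Angles are
degrees at every interface and radians internally.  Hexagon metrics use the
small-angle chord convention: an "angle" is the Euclidean chord between
unit vectors times 180/π, so a 5° geodesic spacing reads 4.9984°.

## Dendrite morphometrics

Strahler numbers follow the classic rule (leaves 1; equal merge increments,
unequal merge takes the maximum).  Polytomies — which the rule does not
cover — use the standard generalization: SN = max over children, plus one
when the maximum is attained by two or more children.  The PD is the vector
sum of SN {2, 3} branch vectors; SN 1 twigs are short, nearly isotropic
within-column wiring and are excluded by default (the `sn_set` argument
exposes this for sensitivity analysis).  Amplitude and width are 1st–99th
percentile spans of the resampled node cloud (resampling spacing default
0.1 µm; percentiles by linear interpolation between order statistics).  The
width axis is the axis orthogonal to the PD *within the arbor's PCA plane*,
not an arbitrary 3D orthogonal, because dendrites are nearly planar sheets
and the meaningful width lives in that plane.

## Automated lattice indexing

The reference data assign lattice coordinates to medulla columns by
inspection; this package automates it.  Two local generator vectors are
estimated robustly (displacement vectors from the ~18 points around a seed
to their 8 nearest neighbours, refined by mean-shift in angle/length), the
seed's hexagon is labelled, and a breadth-first wavefront assigns the rest:
each front point refits a local affine lattice model from its assigned
2-ring neighbourhood, predicts its six neighbour positions, and matches
each prediction to the nearest free point within 0.45 of the predicted step
length.  Points that never match are reported unassigned, never guessed.
The recovered indexing is unique up to the 12-element lattice point group,
and tests compare against ground truth modulo that group.  The method is
exact on planar (medulla-style) grids with positional jitter up to 20 % of
the pitch; on spherical lens clouds it is exact in the bulk but can
mis-index the extreme dorsal cap (elevation ≳ 55°), where the synthetic
construction compresses row spacing — the analysis driver reports both
numbers, and the pipeline uses the generator's coordinates for the eye.

## Kernel regression

All mappings use a local-linear estimator with a Gaussian kernel: at each
query the weighted least-squares affine fit is evaluated at the query
point.  Local-linear fits reproduce affine functions exactly and avoid the
boundary bias of local-constant smoothing.  Fixed bandwidths serve
interpolation (dense PD fields); the adaptive k-nearest-neighbour
bandwidth serves mapping between different spaces (medulla → reference
grid, medulla → direction sphere), defaulting to k = 9 (≈ one lattice
ring) when not cross-validated.  Bandwidth/k selection minimizes
leave-one-out squared prediction error over a 25-step log-spaced ladder
(half the median nearest-neighbour spacing to four times the data
diameter); ties resolve to the larger bandwidth.  Singular local designs
(e.g. regression over points confined to a sphere's tangent plane) fall
back to a slope-only ridge (λ = 1e−8 × trace of the normal matrix) with a
warning; the intercept is never penalized, preserving affine reproduction.
The reference grid for PD comparison is the regular hexagonal grid with
unit pitch, centred on each cell's home column; a 45°-tilted square grid is
available as a display option.  Hexagon units are D_h = √3 and D_v = 2 at
unit pitch, so D_v/D_h = 2/√3.

Mapping to the eye regresses head, tail and centre componentwise to 3D and
renormalizes onto the unit sphere (radial projection); the tangent PD
vector at the home ommatidium has norm equal to the head–tail great-circle
span in degrees.  Boundary regressions are stabilized with one ring of
auxiliary support points extrapolated beyond the matched boundary by local
affine fits in lattice coordinates.

## Optic flow and axis search

Flow fields are the *perceived* motion: F_rot(d) = d × ω and
F_trans(d) = (t·d)d − t under the equal-distance assumption.  The sign
convention is anchored physically: backward self-translation along −x̂
makes a lateral direction ŷ see flow +x̂ (the scene streams frontward).
Candidate axes are a Fibonacci sphere lattice (deterministic,
quasi-uniform); 10,356 axes give ≈1.9° mean nearest-neighbour resolution.
The optimized statistic is the mean angular difference (median is
available and reported alongside); zero-length vectors are excluded.
Angular differences between tangent fields use
atan2(|a×b|·d, a·b), folded to [0°, 180°].

## The synthetic eye and what it emulates

`SyntheticConfig` defaults define the study conditions: 750 ommatidia at
5° mean spacing over a field of view spanning azimuth −10°…155° and
elevation −70°…90° (a posterior wedge and a ventral cap are unseen);
planted shear up to 15° away from α = 90°; a medulla compressed along the
anterior–posterior axis to 0.7 of the regular-hexagon horizontal pitch
(1/√3 ≈ 0.58 would be the exactly square-tilted limit); positional jitter
10 % of the local pitch; 180 T4-like dendrites with branch-orientation
concentration κ = 20; half-wave-rectified cosine spike tuning (baseline
10 Hz, gain 80 Hz) with Poisson noise over 3 repetitions.

The eye lattice places rows at constant base elevation and columns at
constant azimuth.  The shear field is planted as a row-tilt
β(az, el) = −A·tanh((az−az_c)/45°)·tanh(el/35°), realized by integrating
de/da = −tan β · cos e along each row (midpoint rule, 0.05° azimuth
steps): dorsal rows bow dorsally away from the central meridian and
ventral rows ventrally, producing α = 90° − β with α < 90° in the
fronto-dorsal and posterior-ventral quadrants and α > 90° in the other
two, while columns stay exactly meridional (the +v axis is never tilted).
Because of that construction, the planted α is recorded analytically per
ommatidium and two independent measurements agree with it: the hexagon
shear metric (within 0.06° at zero jitter) and the tilt of +h-aligned PDs
mapped through the eye map (median error ≈ 1° at default jitter).

T4-like dendrites are depth-3 binary backbones (one SN-4 stem, two SN-3,
four SN-2 branches, eight SN-1 twigs, ~31 nodes): the SN-2/3 pairs fan out
at fixed ±25–30° lateral angles whose contributions cancel in the vector
sum, each direction drawn from a von Mises around the planted PD; SN-1
twigs are uniform in angle.  Segment lengths are one third of the column
pitch, so a dendrite spans roughly one unit hexagon, and all nodes are
kept within 1.2× the hexagon circumradius.

What the generator does **not** emulate: optical blur and neural
superposition; the real eye's smooth ΔΦ gradients (here ΔΦ_h shrinks with
cos(elevation) as a by-product of the constant-azimuth columns, which is
why the extreme dorsal cap is degenerate); biological dendrite tortuosity
and reconstruction errors beyond Gaussian node noise; unequal ommatidia
vs column counts (the default sets are equal, so the eye map is a perfect
bijection — boundary-mismatch behaviour is exercised in tests by
construction).  Passing tests therefore establish the correctness of the
geometry and regression machinery under controlled conditions, not the
biological values of any measured quantity.

## Numerical choices and degenerate inputs

Mollweide's auxiliary angle solves 2θ + sin 2θ = π sin φ by Newton
iteration to 1e−10 with the closed form at the poles; Mercator raises at
|elevation| = 90°.  Directions parallel to a pole get azimuth 0 by
convention.  Tuning curves with all-zero or perfectly uniform rates return
PD = NaN (vector length ~0) — the explicit "undefined PD" signal.  Trees
with cycles, multiple roots or non-finite positions are rejected on
construction.  Resampling preserves branch points and leaves exactly and
redistributes nodes by arc length per unbranched chain.  Seeds: every
generator takes its randomness from `SyntheticConfig.seed` (per-cell
streams are derived from the seed plus the home coordinate and cell id),
so identical configs are bit-identical.

## Problem sizes

The test suite and the acceptance script run the study at its native
scale — 750 ommatidia, 100–180 dendrites, 10,356 candidate axes, 20
replicate seeds for recovery experiments — which completes in about two
minutes for the full suite and under half a minute for the acceptance
script on one CPU.

## Known limitations

- The wavefront indexer's failure mode on degenerate spherical caps is
  reported, not repaired; real lens grids (physically uniform spacing)
  should not exhibit it, but the synthetic dorsal cap does.
- The eye map assumes both point sets come with consistent landmarks;
  cross-animal registration beyond equator/meridian alignment is out of
  scope.
- Adaptive-bandwidth cross-validation on 19-point neighbourhoods is noisy;
  the k = 9 default is used for bulk mapping and CV is reserved for field
  interpolation.
- No uncertainty quantification beyond residual reporting.
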