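# Methods

`ciliarray` reconstructs the 3D organization of basal bodies (BBs) in
*Tetrahymena*-like multi-ciliated cells from calibrated fluorescence
z-stacks, and ships a ground-truthed synthetic-cell generator so that every
stage of the reconstruction can be validated without micrographs. This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic validation does and does not establish.

## The reconstruction pipeline

The pipeline runs in a fixed order; each stage consumes the previous one's
output and each filter only removes candidates.

**1. Cell extraction.** The BB-channel maximum-intensity projection (MIP) is
mean-subtracted, blurred with a 1 µm Gaussian, sharpened with a 0.12 µm
Laplacian-of-Gaussian (image minus scale-normalized LoG response — this
deepens the valleys separating touching objects while keeping the cell blob
above background), blurred again, and thresholded with the Triangle method
on a 256-bin histogram. All image arithmetic clips negatives to zero, the
behaviour of unsigned integer image processing; without the clip the
Triangle background peak drifts below zero and the threshold lands in the
blur halo. Connected components are gated by shape: area in
[200, 2000] µm², max Feret diameter ≤ 60 µm, circularity
(4π·area/perimeter², Crofton perimeter) ≥ 0.85. The largest survivor is the
cell; its mask, dilated by a 5 µm disc, crops the stack. The Crofton
perimeter matters: the naive contour perimeter of a digitized 2:1 ellipse is
~5% too long, which alone pushes a genuine cell below the 0.85 gate. The
lower area bound exists because the three published gates only bound objects
from above — without it a blank noise field yields a small round speckle as
"the cell".

**2. BB detection.** The cropped BB channel is smoothed with a 0.12 µm
Gaussian and every local maximum within an anisotropic ellipsoidal
neighbourhood (0.25 µm in xy, 0.6 µm in z — one BB's footprint) is
collected; plateau ties keep the lexicographically smallest coordinate.
Maxima are then split from noise by a depth-adaptive threshold: for each z
plane, the mean, s.d. and coefficient of variation (cv) of all maxima
intensities within a rolling ±0.75 µm z window give the threshold
`((s − cv·s)·sd) + avg` with sensitivity `s = 6`; the multiplier clamps at
zero when cv > 1 so the threshold never drops below the window mean. Because
the statistics roll with depth, BBs on the far side of a thick cell pass the
cut despite severe attenuation. The threshold is invariant to global
intensity scaling. Two further filters follow: maxima deeper than 2.25 µm
under the convex hull of all accepted maxima are internal BBs and are
deleted (for a point inside a convex polytope the distance to the surface is
the minimum plane distance over facets — exact, no distance-map
discretization); and maxima whose 1 µm² intensity histogram on the raw,
plane-mean-subtracted z-plane has skewness + excess kurtosis < 1 sit on the
homogeneous bright oral-apparatus (OA) plateau and are reclassified as OA
(cortical BBs are isolated peaks: positive skew and kurtosis; moments use
the bias-uncorrected definitions; zero-variance boxes are degenerate and are
excluded and flagged).

**3. Polarity.** Each BB's maximum distance to any other BB is ranked; the
20 greatest identify the two ends of the cell, split by the sign of their
projection on their principal axis, and each pole is its cluster's centroid.
If the two pole centroids are separated by less than 0.8× the cloud's
maximum pairwise distance the cloud has no elongation and polarity fails
loudly. The anterior pole is the one whose surrounding sphere (radius 8 µm;
chosen to cover the dense anterior BB cap and the nearby OA, no radius is
prescribed) integrates more BB-channel intensity; when the OA centroid falls
in the posterior half instead, the OA cue wins and the cell is flagged. The
OA centroid is the centroid of the largest single-linkage cluster (2 µm
radius) of OA-classified maxima — stray misclassified cortical maxima
elsewhere would otherwise drag a plain centroid microns off.

**4. Row linking.** Candidate anterior partners of a BB are all BBs with
strictly greater projection on the posterior→anterior axis. Candidate `c` is
scored for BB `b` as `‖b − c‖ + w·dist(c, plane(b, pole_ant, pole_post))`
with unit weight `w`; the reverse search scores each BB's best *posterior*
partner with the plane through the candidate. Links are accepted only where
forward and reverse agree on the same pair; all agreements of a round are
accepted simultaneously (order-independence), consuming the posterior BB's
out-slot and the anterior partner's in-slot, and rounds repeat until no new
agreement. Remaining BBs link to the closest candidate with a free in-slot
iff closer than 5 µm (reciprocal links carry no distance cap; only this
fallback does). In- and out-degree are both ≤ 1, links never point
posterior, so chains never branch or cycle. BBs exactly on the pole axis
have an undefined plane and can only be linked by the fallback pass. The
linker fails in a known way at the anterior tip, where inter-row spacing
approaches within-row spacing — this mirrors the behaviour of the original
routine and is left as is.

**5. Metrics.** Spacing is the 3D Euclidean link length (curvature
preserved), histogrammed at 0.1 µm; large gaps are links > 3 µm and close
pairs links < 1 µm. Angular deviation of a link is
`arcsin(dist(partner, plane(bb, poles)) / length)` in [0°, 90°]; 0° for a
perfect row. Cells are divided into 16 spatial domains: longitudinal
quadrants IV (anterior) … I (posterior) from the Euclidean distance to the
anterior pole normalized by the pole-to-pole distance, and rotational bins
0°/45°/90°/135° from the azimuth about the axis relative to the OA meridian,
folded to [0°, 180°] by mirror symmetry. Surface area and volume come from
the convex hull of the cortical BB cloud. Daughter (newly assembled) BBs are
called where the posterior partner's age-graded marker intensity (Poc1-like)
is ≥ 2-fold the anterior BB's; the boundary is inclusive. Consecutive dim
BBs in a linear cluster yield only one daughter call per cluster head — an
acknowledged undercount, reproduced by design. Per-BB marker intensities are
background-subtracted integrals in a 0.5 µm-radius sphere with the local
background taken as the median of a 1–1.8× radius shell (no measurement
aperture is prescribed).

**6. Kinetics.** Stage durations multiply each stage's population frequency
by the doubling time of an exponentially growing culture. Rates divide the
parameter change across a stage by that duration; the 0-minute baseline is
the mean of the Stage I quartile with fewest cortical BBs. Predicted counts
halve the Stage IV mean (division) and add each stage's observed daughters.
All of this is pure arithmetic, exact to double precision; rates are also
reported at 1 decimal, the convention used for presenting them.

**7. Averaging.** Around each selected BB (default: medial quadrants II and
III) a cube (default 4 µm, odd sample count, 0.125 µm sampling) is resampled
by trilinear interpolation in an oriented frame: cube x along the
posterior→anterior axis, cube z along the local outward surface normal
(the BB's radial direction from the axis — configurable; no azimuthal
convention is prescribed). Cubes clipped by the stack border are dropped and
counted. Averages are voxelwise means; the central nine points of the
anteroposterior linescan through the maximum projection are fit to a
Gaussian (amplitude, centre, width, offset) with R² reported on those
points; flanking neighbour peaks are detected with parabolic sub-sample
refinement (minimum inter-peak distance 0.5 µm, ~the diffraction limit).
Two datasets sharing a fiducial channel are merged by phase-correlation
translation (no rotation: both datasets are already in the canonical cell
frame) of the fiducial averages, with the same shift applied to the other
channel.

## The synthetic-cell generator

The generator is the package's test bed; its defaults are one fixed set of
"wild-type-like" conditions:

| parameter | default | rationale |
|---|---|---|
| semi-axes | 20 × 10.5 × 10.5 µm | 40 µm cell, aspect < 2 so the projected silhouette clears the 0.85 circularity gate as real cells do |
| rows | 20 | middle of the 18–21 range |
| within-row spacing | 1.2 + 0.9·t µm (t: anterior 0 → posterior 1) | anterior-tight/posterior-loose gradient; ~550 cortical BBs |
| row span | t ∈ [0.02, 0.99] | rows converge near the posterior tip; the anterior cap is occupied by the densest rings |
| OA | 150 spots at 0.3 µm spacing, azimuth −90° (ventral, toward the coverslip), t = 0.15, on a super-Gaussian plateau | a homogeneous bright patch for the skew/kurtosis filter to reject; ventral mounting is the usual imaging orientation |
| PSF σ | 0.1, 0.1, 0.35 µm (x, y, z) | diffraction-limited confocal spot |
| voxels | 0.125 × 0.125 µm xy, 0.3 µm z | 300 nm z-steps; xy at Nyquist-ish sampling (no pixel size is prescribed; this is the implementer's choice) |
| attenuation | 4.3%/µm of depth | far surface ~35% as bright as the near surface across the cell diameter |
| noise | Poisson (gain 2 ADU/photon) + Gaussian read noise sd 10 | camera model |
| background | 100 ADU offset + 150 ADU depth-attenuated cytoplasmic body | real centrin staining shows a filled cell body; without it no histogram method can segment the MIP silhouette |

Rows are ellipsoid meridians at equal azimuths; within-row positions step
the meridian arc length by the spacing profile (midpoint rule with one
refinement — a constant profile reproduces its spacing to well under 1%).
Cortical BBs under the OA footprint are removed (the OA displaces rows).
All randomness flows from one seeded generator; identical spec and seed give
bit-identical ground truth and stacks.

Perturbations model mutant phenotypes: *gaps* delete contiguous runs until
the surviving flanking pair is > 3 µm apart, with `gap_rate` the fraction of
BBs deleted; *disorientation* displaces each BB off its meridian plane by
`local_spacing · tan(ε)`, `ε ~ N(0, σ)` — because both link endpoints
jitter, measured deviations are half-normal with scale √2·σ, and σ is
recovered from the median deviation (robust to mis-linked outliers) after
removing the detection-jitter baseline in quadrature, to about ±15% at
σ = 5–8°; *daughters* dim the anterior member of selected pairs to 25–45% of
its posterior neighbour's second-marker intensity, walking each row
posterior→anterior so every ratio is against final values.

### What the synthetic validation shows — and does not

Passing the synthetic suite establishes that the implementation detects
diffraction-limited spots through a 3:1 depth attenuation (recall and
precision ≥ 0.9 at a 0.5 µm match radius), localizes poles to ≤ 2 µm, links
≥ 95% of row successors correctly, and recovers injected gap frequencies,
daughter rates and disorientation widths. It does not establish performance
on real micrographs: the generator has no optical aberrations beyond a
Gaussian PSF, no cytoplasmic texture, no debris touching the cell, no
sample-to-sample staining variability, and its rows are geometrically ideal
meridians. Headline biological numbers (mean cortical BB count, spacing,
surface area of real populations) require real images and are out of scope.

## Numerical choices and degenerate inputs

- Voxel↔µm conversion happens once, at stack IO; every algorithm works in
  µm. Voxel centres sit at integer multiples of the voxel size.
- "Radius" of the published ImageJ kernels is read as the Gaussian sigma;
  the mapping is a config value (`blur_large_um`, `log_radius_um`) so it can
  be changed.
- The adaptive-threshold window statistics are computed over maxima (not
  voxels), symmetric ±0.75 µm about each plane.
- Interior depth uses exact facet-plane distances (equals the exact
  point-to-facet distance for interior points; verified against a
  brute-force point-to-triangle oracle to 1e-9).
- Box statistics are computed on the raw plane (not the smoothed one),
  switchable in principle via the audit table; clipped boxes use the
  available pixels and are flagged.
- Degenerate inputs fail loudly or are flagged: missing calibration is an
  error (never a silent default), coplanar point sets skip the interior
  filter with a log message, a round cloud raises on pole finding,
  near-equal pole intensities without an OA raise "polarity ambiguous",
  zero-variance boxes are excluded and flagged, flat linescans return a
  non-converged fit.
- Daughter calling with a non-positive anterior intensity treats the ratio
  as infinite: the daughter is called and flagged.

## Known limitations

- No sub-voxel localization refinement (spots are reported at voxel
  centres); localization error is bounded by half a voxel per axis.
- No global row index per BB — links form chains, but chains are not
  labelled as numbered rows.
- The anterior tip can mis-link where inter-row spacing approaches
  within-row spacing; accepted behaviour.
- Rotational domains need an OA; without OA maxima only longitudinal
  quadrants are assigned.
- The adaptive threshold degrades in z-windows whose maxima population has
  cv > 1 (e.g. a bright OA plateau dominating a small cell's window): the
  clamp holds the threshold at the window mean, which can admit noise maxima
  in those planes.
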