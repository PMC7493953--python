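# Methods

This note documents the models, parameters, and numerical choices behind
`speconn`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate and unit conventions

Voxel data are indexed `(channel, z, y, x)`; pitch is `(z, y, x)` in
**pre-expansion nanometers**.  A voxel's physical position is its center
(`position = index × pitch`, 0-based).  Point data (SWC nodes, synapse
records, marker peaks) are `(x, y, z)` nm, matching SWC column order.
Expansion is pure metadata: physical gel pitch = stored pitch × expansion
factor, and the conversion is exactly invertible.  Default pitch is
75 × 75 × 200 nm³ (x,y,z) at 4× expansion — the effective confocal
resolution regime this kind of experiment operates in — with
~150 × 150 × 350 nm³ as the 2× alternative.

## Synthetic scene model

The generator emulates the features of multiplexed expansion volumes that
the analysis depends on; it is the package's ground-truth instrument, not a
physical simulator.

**Geometry.** Somata are spheres (radius drawn from 5–6 µm by default; the
low end of the plausible interneuron range so that eight somata fit a
46 × 46 × 18 µm³ working volume — a deliberate desk-scale choice).  In SWC
terms a soma is a type-1 root plus a shell of type-1 surface nodes at ~1 µm
spacing, so somatic synapses link to a soma-type node under the
nearest-node rule.  Dendrites are persistent random walks (2 µm growth
step, branch probability 0.06 /µm, ~350 µm total per neuron) resampled to
37.5 nm node spacing (half the smallest pitch).  Each neuron carries one
thin axon; additional external axons enter and leave through volume faces.
Axons are routed through *waypoints* planted at controlled distances from
postsynaptic surfaces: contact waypoints at membrane-contact distance
(axon radius + 20 nm cleft) and deliberate ~700 nm near misses that later
become unlabeled-partner distractor sites.  Waypoints are discovered back
from the finished geometry (surface-distance bands), so planting never
relies on hidden generator state.

**Colors.** Each structure gets a color on the unit simplex: cluster
centers with pairwise separation ≥ 0.15 (rejection sampling, falling back
to a triangular lattice for dense packings), per-structure Gaussian jitter
0.02, re-projected to the simplex.  Fragments of one source share a color.

**Rendering.** Membrane-targeted labels are rendered by sampling each
tube/sphere *surface* at ~37.5 nm spacing and splatting to nearest voxels,
weighted per FP channel by the structure's color × `fp_amplitude`
(12 counts/sample by default), then blurring with an anisotropic Gaussian
PSF whose FWHM equals the effective resolution.  Tubes are therefore
hollow: a line profile across a dendrite shows two membrane walls.
Synaptic puncta and fiducial blobs are sub-resolution objects and are
rendered analytically with the PSF folded in (`puncta_amplitude` = 180
counts at peak; PSD blob size derived from the planted PSD volume,
0.015–0.05 µm³; Bassoon σ 90 nm).  Fiducial blobs default to σ 250 nm —
at least the z pitch — because under-sampled fiducials alias under
interpolation and bias affine scale recovery.

**Synapse planting.** PSD puncta (Gephyrin for inhibitory, Homer1 for
excitatory) sit on the post membrane surface; Bassoon is displaced along
the local contact normal by a truncated-normal separation (mean 150 nm,
sd 25 nm, clipped to 100–200 nm).  The planting mixture is 77% excitatory
pair / 21% inhibitory pair / 2% orphan Bassoon — the composition reported
for cortical tissue, used here as a generator default, not a truth claim.
Spacing: sites are rejection-sampled to keep ≥ 310 nm apart, except a
2.5% "close sibling" fraction planted 180–290 nm along the same bouton
(each such planting leaves *two* synapses under 300 nm, so ~95% of planted
synapses end up >300 nm from their nearest neighbor, matching the observed
">90%" property).  Two distractor classes are planted alongside: contacts
with no machinery, and pairs whose Bassoon lies 475–780 nm from every
labeled axon centerline (inside the pre-side search radius but outside any
membrane envelope) — the unlabeled-partner case.

**Noise and rounds.** Photon counting: Poisson(signal + background 3
counts) plus Gaussian read noise (σ 1.5), rounded to integers (hence
losslessly stored as uint16).  Round k ≥ 2 is the scene resampled through
a planted affine (rotation ≤ 2.5°, per-axis scale 0.98–1.04, translation
≤ 8 voxels) composed with a sinusoidal displacement (amplitude 1 voxel),
stain channels multiplied by `decay^(k−1)` with decay = 0.83 (chosen so
that six elution steps leave one third of the original signal, the
reported round-7 behavior), fiducial re-stained (no decay), fresh noise
per round.

**What the generator does not model:** spectral bleed-through, chromatic
aberration, depth-dependent attenuation (the z-histogram matching module
is exercised on constructed stacks instead), axon caliber diversity, spines,
tissue autofluorescence, and tracing errors — the SWC input is exact.
Passing tests therefore demonstrate correctness of the *quantification*
given faithful reconstructions, not robustness to tracing mistakes.

## Detection

**Segmentation.** Global Otsu fails on whole volumes where puncta occupy
<0.1% of voxels (the background mode dominates the histogram), so the
threshold is an *iterated* Otsu: while the foreground fraction exceeds 1%,
Otsu is re-applied to the voxels above the current threshold (monotone,
fixed-point stopping).  Foreground components are split by watershed on the
inverted Euclidean distance transform; seeds are local EDT maxima with a
physical (nm) minimum separation of 300 nm — voxel footprints alone either
over-suppress along z or leak EDT-plateau duplicates.  Because a noisy mask
can still split one blob, fragments whose centroids violate the seed
separation are merged afterwards (under the spacing prior, two puncta
closer than 300 nm are not distinct synapses).  Fragments under 4 voxels
are dropped.  Centroids are intensity-weighted (≈5 nm accuracy at default
noise) and volumes are voxel counts × voxel volume, reported pre-expansion.

**Pairing.** Candidate Bassoon↔PSD edges within 300 nm (generous cover of
the 100–200 nm window while respecting >300 nm inter-synapse spacing) are
matched greedily by ascending separation with mutual exclusion across both
PSD channels, so Gephyrin and Homer1 never share a Bassoon.  Ties break on
the lower PSD id.  Greedy equals optimal here except in pathological
geometries; a Hungarian variant was considered and rejected as
unauditable overkill at these densities.

**Trio classification.** The profile is sampled at 25 nm steps along the
PSD→Bassoon axis extended 400 nm both ways, each channel normalized to
[0, 1].  Peaks are local maxima (prominence 0.2 of the normalized range
after σ = 1-sample smoothing); peak *positions* are refined by
baseline-subtracted center of mass in a ±150 nm window around the punctum
centroid projections, because the discrete argmax of a flat-topped blob
wanders under noise.  The separation window test uses the 3-D peak
separation (the intensity-weighted blob centroids), which is an order of
magnitude more precise than along-profile positions on z-tilted lines
(≈5 nm vs ≈20 nm sd); the profile positions serve the order and membrane
checks and the reported metrology.  The membrane peak may lie up to 300 nm
on the PSD side of the PSD peak: the apposed axon wall sits
(axon radius − separation) *inside* the PSD position, and the cleft is
unresolvable, so the post and axon membranes blend into one peak on that
side.  Membrane peaks are detected in the summed-FP profile and in each FP
channel (a post membrane is prominent in its own dominant channel even
under a brighter neighbor).  Post identity: the measured membrane color is
unmixed as a convex blend of each candidate's color and the nearby axon's
color; a candidate qualifies if the blend residual is ≤ 0.30 *and* there is
positive evidence of ownership — a post color share ≥ 0.15 or the PSD
sitting within 200 nm of the candidate's traced surface.  Pre identity:
the labeled axon whose membrane envelope (radius + membrane thickness +
one lateral voxel = 415 nm) contains the Bassoon centroid; a labeled axon
inside the 800 nm search radius that does *not* contain it triggers the
unlabeled-partner rejection.

**Linking.** Accepted synapses link to the nearest soma/dendrite node of
the matched post skeleton (exact ties → lower node id); compartment is
somatic iff the node is soma-type.  Unlinkable synapses are quarantined,
never silently dropped.

## Registration

Rounds chain pairwise to round 1 on the fiducial channel.  Translation
from phase correlation seeds a deterministic coarse-to-fine Powell
refinement (3 levels) of rotation / per-axis log-scale / translation
maximizing normalized cross-correlation (robust to multiplicative decay).
Parameter walls are enforced inside the objective rather than through the
optimizer's bounds interface, and each level keeps the better of its start
and result.  Interpolation is trilinear in 3-D (per-slice bilinear is
lossy at anisotropic z-pitch; a slicewise variant would reproduce the
per-slice behavior of common 2-D tools but is deliberately not the
default).  The nonrigid stage is a coarse-grid free-form deformation
(control spacing 1500 nm) estimated by per-block phase correlation with
10× subvoxel upsampling, weighted Gaussian smoothing across control points
(the bending-energy regularizer), iterated twice.  The reported residual
is the energy-weighted mean local displacement (nm) from block matching
after alignment; if refinement fails to reduce it, the affine transform is
returned unchanged, so residuals are monotone across stages.

Expansion factors are measured by fitting an affine from the pre-expansion
state onto the post-expansion state (coarse isotropic-scale scan, then the
same Powell refinement) and averaging the per-axis scale factors (column
norms of the linear part — the polar-decomposition stretches for small
rotations).  The correlation is evaluated on a fixed central box that
stays in-bounds for any scale up to 1.15× the scanned optimum, with
out-of-bounds samples scored as mismatch: otherwise growing the scale
shrinks the valid sample set and biases large factors high (~+2.5% at 4×).

## Connectivity analytics

**Convergence bounds.** Upper = count of spatially distinct labeled axon
fragments with ≥ 1 accepted synapse onto the target (fragments, not merged
same-color fragments — "spatially distinct" is the operative property).
Lower = number of unique colors among those fragments, from k-means on
simplex coordinates (10 restarts, fixed seed) with a conservative elbow:
the smallest k at which the relative within-cluster improvement drops
below τ = 0.10 *or* the per-point within-cluster RMS falls below 0.04
simplex units.  The second stopping rule is essential: relative
improvement alone is scale-free and keeps subdividing jitter-sized
clusters when fragments per source are few, inflating the lower bound
past the true source count.  0.04 is twice the default color jitter —
colors closer than measurement noise cannot indicate distinct sources.
Fragments with undefined color (no FP signal) count toward the upper
bound only.

**Input maps.** Path distance from a synapse's node to the nearest
soma-type node along the tree (unique on a tree; verified exactly against
an independent shortest-path oracle), histogrammed at 10 µm bins with
somatic synapses tallied separately.  **Morphology**: total path length,
stems (neurite roots on the soma), bifurcations (nodes with ≥ 2 children),
branches (maximal unbranched segments), and Sholl crossings of concentric
spheres about the soma centroid (10 µm steps), each dual-checked against
brute-force census oracles.  **SnR**: per-ROI mean over the mean of
background-ROI means, with disjointness validation; cross-round reports
expose the signal and background tracks separately, since a background
that decays with the signal cancels in the ratio.

## Benchmark problem sizes

The default benchmark scene is 8 neurons + 30 external axons with 150
planted synapses and 15 + 15 distractors in 46 × 46 × 18 µm³
(614 × 614 × 91 voxels, ~34 M voxels × 7 channels); it builds in about a
minute and detection takes seconds.  Registration benchmarks use
48 × 160 × 160 fiducial fields (250 blobs); expansion benchmarks
64 × 160 × 160 with 4000 blobs; pair-composition uses 500 Bassoon puncta
in 30 × 30 × 12 µm³; convergence coverage uses 100 color-space targets
with 5–40 sources.  These sizes are the package's validation scale —
large enough for stable statistics, small enough to rebuild from scratch
in any run.

## Known limitations

* Sub-resolution close pairs (<300 nm) merge by design; each close sibling
  pair costs one recall count.  Separations planted at the exact window
  edges (100 or 200 nm) can measure just outside it and are honestly
  rejected.
* The post-identity color test assumes the blend model (post + one nearby
  axon); three-way overlaps of differently colored structures at one
  contact are not unmixed.
* Convergence lower bounds assume color jitter ≤ the 0.04 resolution
  floor; heavier jitter would require re-deriving that constant.
* The registration similarity is intensity-based; it needs overlapping
  fiducial content and does not handle content appearing in only one
  round.
* SWC input is trusted; no tracing-error model exists, so reported
  precision/recall describe the quantification pipeline, not end-to-end
  reconstruction fidelity.
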