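# Methods

## Model

The method treats segmentation as a question about path strength in a
fuzzy graph over the voxel grid. A voxel belongs to the vessel to the
degree that *some* 6-connected path joins it to the seed whose weakest
link is strong, where a link's strength (affinity) is a Gaussian of the
pair-mean intensity around the vessel-class mean m with width s. The
per-voxel strongest-path value is the connectivity scene CS in [0, 1];
the segmentation is a threshold on CS.

Assumptions inherited from the problem domain:

- vessels are brighter than liver parenchyma (contrast-enhanced CT);
- vessel intensities are approximately homogeneous around a single mean
  (one Gaussian term; the general affinity form carries two weighted
  feature terms but the second is unused, weights fixed to 1 and 0);
- intensities live on an 8-bit scale. CT volumes in HU must be windowed
  explicitly (`window_to_byte`); nothing rescales silently. A window of
  [-100, 400] HU is a reasonable default for contrast hepatic CT.

## Algorithms and numerical choices

**Propagation.** Max-min Dijkstra with a max-heap and lazy re-insertion
(improved voxels are pushed again; stale entries are skipped on pop).
Max-min path strength makes the result provably independent of
tie-breaking among equal-priority entries; the `tie_break` switch exists
only so tests can demonstrate that invariance. Connectivity values are
doubles; unreached voxels stay exactly 0. A test-only oracle
(`connectivity_oracle`) computes the same fixpoint by iterated
Bellman-Ford-style max-min relaxation and must agree bitwise.

**One canonical exponential.** numpy's vectorized `exp` can differ from
its scalar path by one ulp. All affinity evaluation therefore funnels
through a single scalar expression (`_pair_gauss`); the 256x256 lookup
table is filled from the 511 distinct pair sums evaluated that way.
This is what makes "with LUT" and "without LUT" runs bit-identical
rather than merely close.

**Seed cube.** The 20-voxel cube cannot be centered exactly (even edge);
each axis spans [i - 10, i + 10), truncated at scene borders. Otsu's
threshold maximizes between-class variance over all 256 candidate
splits, ties resolved to the smallest threshold; a constant cube is an
error (badly placed seed), as is a seed whose own intensity falls in the
darker class. The vessel class uses the population (divisor N) standard
deviation — immaterial at cube sizes of thousands of voxels, but fixed
for reproducibility — floored at 0.5 intensity units so noiseless
synthetic data cannot produce a singular Gaussian. The seed voxel's
value is replaced by round(m) before propagation.

**Histogram and threshold.** CS is histogrammed over (0, 1] in 1000 bins
by default; CS == 0 voxels (never reached) are excluded, otherwise the
untouched-background mass dominates. `volume_above(h)` is the voxel
volume times the count of CS >= h, evaluated at bin-edge resolution and
non-increasing in h. The endpoint EP is the largest *positive* bin edge
whose volume still reaches the cap (default 50 ml — manual portal-vein
volumetry averages 11.578 ml across ten datasets, and hepatic vein plus
artery justify the headroom); if even the lowest positive edge holds
less than the cap (small scenes such as phantoms), EP falls back to the
lowest positive edge. Counts are smoothed with a moving average (window
9 bins by default, edges averaged over the in-range part). A bin is a
local maximum if strictly above its left neighbor (plateaus resolve to
their left edge) and at least its right neighbor, one-sided at the
boundaries.

A local maximum only qualifies as the vessel peak if it is
*significant*: walking up from EP, its smoothed count must exceed the
lowest count passed since EP by at least a factor of 3 in 1 + count
space. CS histograms are log-scale objects — genuine vessel peaks stand
orders of magnitude above the valley separating them from the
low-connectivity background mass, while at desk scale (10^2–10^3 vessel
voxels spread over 10^3 bins) near-empty bins produce abundant Poisson
local maxima that a pure first-local-maximum rule would mistake for the
peak immediately above EP. The factor 3 is deliberately coarse: count
fluctuations of factor 2 are routine on bins holding 1–3 voxels, while
real valley-to-peak rises are far larger. If the bin starting at EP is
itself a significant peak (judged by topographic prominence), T = EP; if
no significant peak lies above EP, T falls back to EP with a warning
(the original procedure has no else-branch for this case). The mask is
CS >= T, seed always included.

**RRG comparator.** The grown region at threshold theta equals the
26-connected component of {f >= theta} containing the seed, so each
descent step is one connected-component labeling; the trace N(theta) is
identical to explicit frontier growth. theta_opt maximizes the relative
jump N(theta - 1)/N(theta), ties to the larger theta. Two guards keep
the comparator honest rather than a strawman: steps taken while the
region holds fewer than 50 voxels are ignored (tripling a 5-voxel region
is growth through the vessel, not a flood), and if no remaining step
reaches a factor-3 jump the trace has no considerable change and
theta_opt falls back to theta_end with a warning. theta_end is a user
parameter (how the original comparator chose it automatically is not
restated in our source material); an optional volume cap aborts runaway
floods.

## The phantom generator

Phantoms emulate the features of contrast hepatic CT that the method is
sensitive to, with known ground truth:

- analytic tube trees (cylinders with spherical caps, optional linear
  taper) rasterized by voxel-center distance; voxel centers sit at
  index * spacing;
- the deterministic bifurcating `branching_tree` (default: 3 levels,
  3 mm trunk radius, decay 0.7, 40 degree spread in a 64^3 mm volume)
  mimics portal-vein morphology;
- intensity model: two-level image (background 80, vessel 160 on the
  8-bit scale, i.e. inside the 100–230 vessel band), Gaussian-blurred
  with sigma 0.5 mm to model partial volume (vessel values decay from
  center to edge), then zero-mean Gaussian noise with per-tissue sd
  (10/10 by default) plus an optional global scanner-noise term
  (`noise_sd`, default 0 — the per-class terms already provide
  realistic texture); clamped to [0, 255];
- ground truth is the *pre-blur* analytic tube set, so edge-recovery
  comparisons between methods are meaningful;
- all randomness flows from one integer `rng_seed`.

The two-system phantom places two coaxial tubes whose near ends are
joined by a one-voxel strand at an intermediate intensity (140 by
default — a partial-volume-dimmed vessel end). The second tree is larger
than the seeded one so that its joining produces a marked jump in an
RRG trace: that is precisely the configuration in which region growing's
own threshold selection rejects the second system while fuzzy
connectedness reaches it through the weak link.

What the phantoms do **not** model: anatomically realistic co-simulated
portal/hepatic/arterial trees, pathology, beam hardening, reconstruction
kernels, anisotropic noise. Passing the phantom suite shows the
machinery is correct and behaves as designed under low contrast, blur
and noise; it does not certify clinical accuracy on patient data.

## Problem sizes and defaults

End-to-end checks run on 64^3 phantoms (~1.4 ml trees) with the volume
cap scaled to 1.5x the true tree volume, since a phantom is much smaller
than a liver; the 50 ml default applies to real scenes. The propagation
is pure Python over flat arrays (a 64^3 scene takes on the order of a
second with the LUT); the lookup table's speed advantage over direct
exponential evaluation is hardware-dependent and is reported nowhere as
a result.

## Known limitations

- Single seed, single object: no relative or iterative multi-object
  fuzzy connectedness.
- The affinity uses intensity only (no gradient/scale terms).
- The adaptive threshold assumes the vessel mass forms a peak above EP;
  on histograms without one it falls back to T = EP and says so.
- `theta_end` for the RRG comparator must be supplied by the user.
- DICOM series assembly and liver masking are out of scope; seeds are
  assumed to lie inside the liver.
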