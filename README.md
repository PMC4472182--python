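# fcvessel

Seeded segmentation of hepatic vessels in contrast-enhanced CT with an
adaptive-threshold **fuzzy connectedness** method, plus the classical
refined region-growing (RRG) comparator and a synthetic vascular phantom
generator so the whole pipeline is testable without patient data.

## The problem

For liver surgery planning (resections, living-donor transplants) the
patient's portal/hepatic vessel tree must be extracted from CT. Contrast
between vessels and liver parenchyma is low, vessel edges are blurred by
the partial volume effect, and the tree's morphology is complex — simple
intensity thresholds and region growing lose edge voxels or flood into
parenchyma. Fuzzy connectedness handles exactly this regime, but two
practical obstacles remain: its computational cost, and the need to pick
a final threshold by hand. This package implements the accelerated,
automatically thresholded variant of the method.

## The method

A CT volume is a *scene* C with intensity f(x) (windowed to 8 bits). Two
voxels c, d have **fuzzy affinity**

    mu_k(c, d) = mu_alpha(c, d) * exp( -1/2 * [ ((f(c)+f(d))/2 - m) / s ]^2 )

where mu_alpha is the hard 6-adjacency indicator and m, s are the mean
and standard deviation of the vessel intensity class. The **fuzzy
connectedness** of d to a seed S is the max-min path strength

    mu_K(S, d) = max over paths p from S to d of ( min over links (c_i, c_{i+1}) in p of mu_k )

computed for every voxel by Dijkstra-style propagation with a
max-priority queue, giving the *connectivity scene* CS. The pieces around
this core:

- **Seed parameterization** — a 20x20x20 voxel cube around the user's
  seed is split by Otsu's method; the brighter class is the vessel, its
  mean/sd give (m, s), and the seed's own intensity is replaced by m.
  This makes the result insensitive to whether the seed was clicked at a
  vessel center or near its edge.
- **Lookup table** — intensities are 8-bit, so all 256x256 pair
  affinities are tabulated once and propagation never re-evaluates the
  exponential. The table stores full doubles: results with and without
  it are bit-identical.
- **Adaptive threshold** — the histogram H(x) of CS is scanned from the
  high end: the endpoint EP is the largest threshold h whose segmented
  volume `voxelsize * integral_h^1 H(x) dx` still reaches the anatomical
  cap on total hepatic vessel volume (50 ml by default), and the final
  threshold T is EP itself if the histogram peaks there, else the first
  significant peak between EP and 1.0. The mask is CS >= T.
- **RRG baseline** — 26-connected region growing from the seed while the
  intensity threshold theta descends from f(seed); theta_opt is the
  threshold just above the largest relative jump of the region size
  N(theta) (the flood into parenchyma).
- **Phantoms** — analytic tube trees rasterized over darker parenchyma,
  Gaussian-blurred (partial volume) with per-tissue noise, vessels at
  160 +/- 10 over background 80 +/- 10 on the 8-bit scale, with exact
  pre-blur ground truth.

## Worked example

Generate the default branching phantom, segment it from one trunk seed,
and compare with the ground truth (the volume cap is scaled to the
phantom; a real liver uses the 50 ml default):

```sh
$ fcvessel phantom --rng-seed 1 --outdir demo
{ "phantom": "demo/phantom.nii.gz", "truth_voxels": 1431, "truth_volume_ml": 1.431 }

$ fcvessel segment-fc demo/phantom.nii.gz --seed 32 32 16 --max-volume-ml 2.15 --outdir demo/fc
{
  "method": "fuzzy_connectedness",
  "m": 151.98, "s": 12.91,          # vessel class estimated from the seed cube
  "EP": 0.018,                      # endpoint where the volume cap is reached
  "T": 0.118,                       # first significant histogram peak above EP
  "voxel_count": 1675, "volume_ml": 1.675
}

$ fcvessel evaluate demo/fc/mask.nii.gz demo/truth.nii.gz
{ "dice": 0.921, "volume_a_ml": 1.675, "volume_b_ml": 1.431, "difference_voxels": 244 }
```

(Values abridged from the actual output; `m` sits below the nominal 160
and `s` above the nominal 10 because the Otsu vessel class includes
partial-volume edge voxels — which is what lets the propagation follow
blurred edges.) `segment-rrg` runs the comparator, `histogram` exports
the CS histogram as CSV for inspection.

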