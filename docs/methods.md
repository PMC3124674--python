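# Methods

## Model

ICS treats an RGB histology image as a weighted, directed 8-connected
pixel graph and distributes cell markers by incremental multi-seed
shortest-path expansion. The design assumptions are:

* cells/nuclei of interest are roughly round and share a common average
  diameter *d* (in pixels), supplied by the user;
* stained material is separable from background by Euclidean distance in
  raw 0–255 RGB space against a user-chosen base color, with a strict
  (`<`) tolerance threshold;
* one marker should appear per cell-sized patch of stained tissue, even
  when intercellular boundaries are invisible (saturated fluorescence).

Stepping onto pixel *t* from neighbor *s* costs the Euclidean step length
(1 axially, √2 diagonally) times a per-pixel factor: 0.10 when *t* is
outside the color range, and `1 + g(t)·σ_d·EWF` when inside, where
`g(t) ∈ [0,1]` is the diffuse edge buffer, `EWF` the edge weight factor
and `σ_d` an optional resolution-scaling multiplier `(d + 8)/18`
(see *Cost laws* below). Expansions run Dijkstra over a cost field shared
by all expansions with relax-if-lower semantics; a seed resets its own
cost to 0. Finalization stops at accumulated cost *d*; pixels popped above
the threshold join a FIFO of seed candidates in ascending (cost, y, x)
order. Candidates are re-validated on retrieval (stored cost must still
exceed *d*), become markers if they pass the color filter, and expand
either way so the sweep always covers the whole image. Marker pixels are
wherever the frontier crossed the threshold — they are not cell centroids.

Two exact invariants follow from positive step costs and are verified
against an independent sparse-graph Dijkstra (scipy) in the tests:

* the final cost field equals the min-over-seeds single-source
  shortest-path field of the actual seed set (tolerance 1e−9);
* on zero-gradient uniform in-range regions, pairwise shortest-path
  separation of markers strictly exceeds *d* (Poisson-disk property,
  radius *d*/2 in Euclidean terms since the chamfer metric dominates the
  Euclidean one).

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `cell_diameter` | px | — | doubles as the expansion cost threshold; precision degrades below 4 px (warning) |
| `color_range.base_color` | RGB | — | e.g. (0,0,255) for DAPI, dark brown for DAB |
| `color_range.tolerance` | RGB distance | — | 120–135 worked for DAPI fluorescence material |
| `edge_weight_factor` | — | 0.5 | recommended 0.5–1; raise toward 1 for sharp, high-contrast edges |
| `resolution_scaling` | bool | False | enables the `(d+8)/18` gradient multiplier |
| `diagonal_cost` | — | √2 | settable to 2.0 to reproduce integer-diagonal implementations |
| `initial_seed` | (x, y) | image center | never recorded as a marker (`count_initial_seed` overrides) |

## Diffuse edge buffer

1. **Edge detection** — Sobel gradient magnitude of the Rec.-601 luminance
   computed on the 8-bit intensity scale and saturated at the white level
   (255) before rescaling to [0, 1]. The saturation reproduces the
   behavior of classic 8-bit edge filters: any strong stain/background
   boundary reads as a full-intensity band, so the buffer is insensitive
   to how dark the stain happens to be.
2. **Diffusion** — Gaussian blur with sigma = 0.25 × `cell_diameter`
   (window truncated at ±3σ, reflect padding). The band width therefore
   scales with the expected cell size, letting edge cost be felt before a
   traversal reaches a boundary.
3. **Contrast stretch** — linear histogram stretch saturating 0.5% of the
   pixels, split equally between the tails (quantile clip at 0.25% each
   side). Constant buffers pass through unchanged; a degenerate histogram
   falls back to a pure min–max stretch. The stretch restores a peak of 1
   on the edges after the blur has diluted them.

## Cost laws

Two in-range cost laws are implemented. The plain law multiplies the
gradient term by `EWF` only; the resolution-scaled law additionally
multiplies by `(d + 8)/18` (equal to 1 at d = 10). The scaled law
compensates pipelines whose edge-buffer amplitude shrinks as the blur
kernel widens with the diameter. The buffer built here is
contrast-stretched back to a peak of 1 at every diameter, which already
makes the gradient term resolution-consistent; measured on resized
synthetic fixtures, the plain law yields a coefficient of variation of
counts across 0.5×/1×/2× resolutions of 2–8%, while stacking the scaled
law on top of the normalized buffer yields 35–60%. The plain law is
therefore the default, and the scaled law remains available for
experimentation with unnormalized buffers.

## Synthetic fixtures

The generator emulates the two image families the method targets:

* **DAB preset** — dark-brown disks (101, 67, 33) on near-white
  (245, 240, 235); defaults of 27 cells at d = 23 px mirror the sparse
  proliferating-cell density of brightfield validation material.
* **DAPI preset** — bright-blue disks (40, 40, 255) on near-dark
  (10, 10, 20); denser, smaller nuclei with a fraction fused into blobs.

Disk centers are rejection-sampled with a minimum center-to-center
separation (cap of 10⁴ retries per disk; an infeasible layout raises
rather than truncating). A `cluster_fraction` of cells is instead placed
0.55–0.75 diameters from an existing cluster member, fusing into a single
uniform blob that emulates saturated fluorescence. Per-pixel Gaussian
color jitter (default sd 8 per channel) models sensor/stain noise.
Everything is reproducible from `rng_seed`.

What the generator does **not** model: optical point-spread blur,
illumination gradients across the field, partial-volume "flecks" from
adjacent sections, and natural variation in cell size and shape. Disk
boundaries are razor-sharp at every diameter, which real optics never
produce; passing counts on these fixtures therefore demonstrates the
traversal mechanics and the cost calibration on ideal-contrast material,
not robustness to degraded real-world imagery. Because the synthetic
edges are maximally sharp and relevant, counting runs on synthetic
fixtures set EWF = 1.0 (top of the recommended range), while the API
default remains 0.5.

"Well separated" fixtures use a minimum separation of 3 diameters
center-to-center, matching the observed density of sparse
proliferating-cell material (~27 cells in a 500×400 field at d = 23).

## Numerical choices

* Tie-breaking in the priority queue and in borderline insertion is
  ascending (cost, y, x); runs are byte-for-byte deterministic.
* Threshold comparisons are strict: cost > *d* makes a frontier/seed
  candidate; distance < tolerance makes a pixel in-range (tolerance 0
  admits nothing).
* The 16-bit image loader rescales linearly by the maximum value present.
* Greedy count matching pairs detections and ground truth in ascending
  distance within one match radius, one-to-one.
* The coefficient of variation uses the sample (n−1) standard deviation.
* Test problem sizes: oracle-equivalence fixtures ≤ 30×30 (50 runs),
  coverage fixtures ≤ 30×30 (100 runs), count-recovery fixtures of
  20–200 disks at d = 12–30 on canvases up to ~700×560, and a 50-disk
  fixture rescaled 0.5×/1×/2× for the consistency check.

## Known limitations

* Counting accuracy depends on the diameter assumption; mixtures of cell
  sizes are out of scope.
* Background seeds can suppress markers in cells they can reach cheaply
  (arrival cost + interior crossing below the threshold); with default
  parameters this keeps absolute counts within roughly ±15% on
  well-separated material and biases sparse, small-diameter images
  low.
* The color filter presumes consistent illumination; very dim stained
  regions fall outside the tolerance and are undercounted.
* Marker positions are not centroids and should not be used for precise
  localization without refinement.
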