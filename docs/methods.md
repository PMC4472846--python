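# Methods

## The assay

`macroquant` quantifies fluid-phase endocytosis from multi-channel
fluorescence z-stacks of adherent cells pulsed with a fluorescent dextran.
Macropinosomes — dextran-positive vacuoles of 0.5–5 µm equivalent diameter —
are detected in the dextran channel, counted, sized, and normalized to the
number of cells in the field (counted as DAPI-stained nuclei). The headline
readout is *macropinosomes per 100 cells*, with the SEM taken across
technical replicates.

The per-field processing chain is fixed and identical for every image of an
experiment:

1. split channels; maximum-intensity projection over z;
2. linear conversion to 8-bit (one `(min, max)` for the whole batch);
3. rolling-ball background subtraction;
4. intensity threshold → binary mask (one resolved level per channel role
   per batch);
5. distance-transform watershed to separate touching structures;
6. optional restriction to a GFP-positive cell-footprint mask;
7. 8-connected particle analysis with a calibrated area filter of
   0.2–20.0 µm² (closed range), equivalent to disks of ≈ 0.505–5.046 µm
   diameter — excluding sub-resolution endocytic vesicles (clathrin-coated
   vesicles measure 0.1–0.2 µm) below and debris/aggregates above;
8. DAPI branch: steps 2–5 plus hole filling, then nucleus counting with a
   minimum-area floor; counts divide the particle statistics per cell.

Batch discipline is enforced structurally: the configuration schema has no
per-image overrides, automatic parameters (conversion range, threshold
levels) are resolved once per batch from pooled data, and the manifest
records exactly one parameter block. Per-image adaptation would shrink the
very differences between conditions the assay exists to measure.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `size_filter` | 0.2–20.0 µm², inclusive | calibrated particle-area window |
| `rolling_ball_radius_px` | `auto` = ⌈3 × 5 µm / pixel size⌉ | ball radius; must exceed the largest object of interest |
| threshold method | `li` | minimum-cross-entropy auto level (see below); `otsu` and `fixed` available |
| `watershed.min_peak_separation_px` | ⌈0.5 µm / pixel size⌉ | distance-map peaks closer than the smallest real object are one object |
| `min_nucleus_area_um2` | 30 | floor excluding DAPI-positive organelle speckle; set per cell line |
| `min_cell_area_um2` | 50 | smallest accepted GFP cell footprint |
| `mask_mode` | `pixel_and` | clip structures at the cell-mask boundary; `whole_particle` keeps/drops components by overlap fraction (default 0.5) |
| `conversion_mode` | `batch_global` | 8-bit map from the global min/max of the batch; `source_depth` and `fixed_range` available |

### Why Li and not Otsu as the default auto-threshold

A background-subtracted dextran image is a sparse-punctae image: a large,
near-zero background class and a small, bright foreground class. Otsu's
between-class-variance criterion is known to drift toward the middle of the
intensity range on such imbalanced histograms; on synthetic fields the Otsu
level sits at ~0.6 of the structure peak, which erodes the thresholded
footprint of structures near the 0.5 µm lower size limit until they fall
under the 0.2 µm² area floor and are discarded. Li's minimum-cross-entropy
level sits near the noise shoulder instead, preserving small-structure
footprints; on the synthetic benchmark this raises pooled recall from
≈ 0.83 to ≈ 0.93 at no material precision cost. Otsu remains available and
is verified against an exhaustive between-class-variance search in the
tests; the fixed manual threshold retains parity with the published-style
workflow. Within a batch, any auto method is resolved *once* per channel
role from the pooled histogram of all corrected images.

### Rolling ball

The background is the grayscale opening of the image with a ball-shaped
structuring element (height profile `h(dx,dy) = sqrt(r² − dx² − dy²)`),
computed exactly via non-flat grey erosion/dilation — not the
shrink-and-interpolate approximation found in interactive tools, with which
bit-exact agreement is not promised. The image is reflect-padded by twice
the radius before the opening, making the result independent of the
filters' own boundary handling and preventing dark rims that would bias
peripheral macropinosome detection. The background is anti-extensive
(everywhere ≤ the image), corrected pixels never decrease with increasing
radius, and the operation is translation-equivariant away from borders —
all property-tested against a direct min/max sweep oracle.

### Watershed

Touching structures are separated by flooding the negated Euclidean
distance transform from its local maxima (plateau maxima merged; maxima
closer than the minimum peak separation suppressed), restricted to the
foreground. Divide lines are carved by removing the lower-labelled side of
every inter-region contact — including diagonal contacts, which a
conventional single-pixel zero line leaves 8-connected, silently undoing
the split when particles are relabelled. Foreground only ever shrinks;
components are never merged. Nucleus segmentation uses a larger peak
separation (2 µm) and lightly smooths the distance map (σ = 2 px): nuclei
are an order of magnitude larger than macropinosomes, and discrete
distance-ridge quantization would otherwise oversplit elongated nuclei.

## The synthetic-data generator

The generator emulates the assay's intended imaging conditions — an
HEK293-like adherent monolayer, 3-channel confocal z-stacks (dextran / GFP
/ DAPI), 0.3 µm pixels, eleven z-slices at 0.5 µm spacing — and records
every rendered structure in a ground-truth file so detections can be scored
by greedy nearest-first one-to-one matching (radius 1 µm).

* **Cells** are non-overlapping ellipses (full axes 10–20 µm), seeded at
  minimum size on a jittered hexagonal grid and grown axis-by-axis until
  they reach their sampled size or jam against a neighbour, the way a
  monolayer spreads; growth stops when the requested confluency (default
  0.6, the 50–75 % regime) is reached. Footprints may overhang the field
  edge as in real fields of view; each cell carries one elliptical nucleus
  (axes 4–7 µm) fully inside the field.
* **Macropinosomes**: per-cell counts are Poisson with a mean proportional
  to cell footprint area (uptake scales with membrane), normalized so the
  across-cell mean equals `mean_mp_per_cell` (default 5). Diameters are
  log-uniform on [0.5, 5.0] µm, exercising both decades of the size filter
  evenly; placement is in an annulus over the outer 30 % of the cell radius
  (macropinosomes form at the periphery), relaxing toward the whole cell
  when the annulus is crowded. Structures are discrete organelles and never
  overlap: placement keeps ≥ 1.2 µm between structure edges, draws that do
  not fit are re-homed to cells with room, and a draw that fits nowhere is
  dropped (a cell cannot pack more vacuole cross-section than it has area).
  With `n_mp_total` set the total is exact or generation fails loudly.
* **Confounders** are 0.1–0.2 µm vesicles placed uniformly in cells.
* **Rendering**: structures are drawn as disks into every z-slice their
  z-extent overlaps (at least the nearest slice) and blurred with a
  Gaussian PSF proxy (σ = 0.15 µm). A disk of radius r keeps a fraction
  `1 − exp(−r²/2σ²)` of its peak under that blur; disks are pre-compensated
  so each resolvable structure's rendered peak over the local background
  equals `snr · sqrt(background + read_noise²)`. The compensation is capped
  at the smallest resolvable radius (0.25 µm): sub-resolution vesicles keep
  their physical attenuation and render dim, as they do under a real
  objective where peak brightness falls with dye volume. A low-order 2-D
  polynomial gradient models uneven illumination; noise is Poisson photon
  noise plus Gaussian read noise. One global seed feeds hierarchical
  per-field substreams.

### What the generator does *not* emulate

No photobleaching, stage drift, z-dependent PSF widening, chromatic
offsets, intensity variation between structures of the same size, cell
debris, or autofluorescent texture. Real dextran pulses also produce
partially overlapping vacuoles that no 2-D-projection protocol can separate
— the generator deliberately excludes such unresolvable cases from its
truth, so passing benchmarks bound the *algorithmic* error of the pipeline,
not the biological ambiguity of real images. The dextran–TMR intensity
statistics of real HEK293 data are not reproduced; SNR is a free simulation
parameter.

## Benchmarks and problem sizes

* **Detection fidelity**: 20 independently seeded fields at the default
  scene conditions (256 px desk-scale fields, SNR 10, ≈ 5
  macropinosomes/cell), pooled one-to-one scoring. The tolerance asks
  f1 ≥ 0.90 and a count error ≤ 13 % — the discrepancy band separating
  semi-automated from expert manual counting. Typical pooled values are
  f1 ≈ 0.96, count error ≈ 0.07. Residual losses sit at the 0.5 µm
  detection limit, where the thresholded footprint of the smallest
  structures straddles the 0.2 µm² floor.
* **Fold-change recovery**: two conditions whose ground-truth per-cell
  densities differ 4.5-fold (the effect size of Na⁺/H⁺-exchange inhibition
  by amiloride/EIPA), 3 replicates × 3 fields of 512 px per condition
  (≈ 1200 cells per condition, comfortably above the 200-cell floor),
  processed as a single batch. Per-field truth densities are pinned exactly
  by two-pass generation (the first pass supplies the cell count for the
  exact structure total). The detected fold is accepted within ±10 %;
  typical recovery is 4.4–4.5. The rolling-ball radius for these synthetic
  experiments is 25 px (the largest object is 16.7 px) and the nucleus
  floor 10 µm² (the generator's nuclei, per the 4–7 µm axes, have
  cross-sections of 12–38 µm²) — per-experiment optimization of exactly the
  two knobs the protocol designates as experiment-specific.
* **Confounder rejection**: noiseless fields with vesicles at five times
  the macropinosome density; a detection within 0.5 µm of a vesicle and
  > 1 µm from every macropinosome counts as a surviving confounder, and
  zero must survive.

## Numerical choices and degenerate inputs

* 8-bit conversion rounds half-up; the same `(min, max)` applies to every
  image of a batch (default: the global min/max found in a first pass).
* Thresholding is `pixels ≥ level`; auto methods return `level + 1` so that
  foreground is strictly above the criterion level on integer images.
* A constant channel across a batch has no automatic threshold: standalone
  thresholding raises a degenerate-input error directing the user to a
  fixed level, while the batch pipeline logs a warning and sets the level
  just above the constant so an empty channel yields a valid zero count.
* A field with zero nuclei cannot be normalized; it is flagged invalid,
  logged, and excluded from condition means rather than raising.
* SEM uses the n−1 sample standard deviation over replicate values pooled
  within replicate (`100 · Σcounts / Σnuclei`); it is unavailable for a
  single replicate. Replicates under 200 cells raise an under-sampling
  flag.
* Size-filter bounds are inclusive at both ends; border-touching particles
  are kept (macropinosomes form at the periphery, which may abut the field
  edge) but flagged, with exclusion available by configuration.
* Hole filling is applied to cell and nucleus masks but not to the
  macropinosome mask, where filling would inflate ring-like artefacts.

## Known limitations

* 2-D quantitation on the projection, as in the published workflow; no 3-D
  particle analysis or time-lapse tracking.
* The rolling ball is exact but O(image × ball area); radii much beyond
  ~50 px on large fields are slow. The GFP channel skips background
  subtraction by default: no radius both exceeds a whole-cell footprint and
  preserves it, and the cell mask needs only a threshold — a per-channel
  radius override exists for genuinely uneven GFP backgrounds.
* Shape descriptors beyond area/equivalent diameter (circularity, Feret)
  are not computed; the diameter bounds are defined as equivalents of the
  area bounds.
* Proprietary microscope formats (LSM/ND2/CZI) must be converted to
  TIFF/OME-TIFF upstream.
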