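# Methods

## Scope and model of the data

All quantification operates on single 2D confocal-like planes. The
quantities of interest — the share of lamin signal lying deeper than a
rim band, the penetration depth of a fold, compartment mean intensities,
track/mask intersection — are defined on 2D signal, so the package does
not model 3D stacks, point-spread functions or instrument optics.
Pixel coordinates are 0-based `(row, col)`; objects use 8-connectivity.
Every µm-valued parameter is converted to pixels once at ingest via
`pixel_size_um`; internal computation is in pixels.

## Invagination scoring

For a nucleus mask `N`, let `EDT(p)` be the Euclidean distance (µm) of an
interior pixel `p` to the nuclear boundary. Lamin-positive pixels are
selected by a per-nucleus threshold computed over `N` dilated by the rim
width (so the threshold sees both rim signal and local background).
Positive pixels with `EDT ≤ w` (rim width `w`, default 0.5 µm) form the
boundary set; positive pixels with `EDT > w` the invaginated set. The
invaginated fraction is the intensity-weighted share of the invaginated
set (pixel-count weighting is available as `fraction_mode="area"` for
sensitivity analysis). A nucleus is positive under the fraction rule iff
the fraction strictly exceeds 0.3, and under the depth rule iff the
maximum `EDT` over invaginated pixels is at least 3 µm. Both constants
are configuration defaults, echoed into the run manifest.

Choices behind the defaults:

- **Rim width 0.5 µm** — comparable to the apparent thickness of the
  nuclear-envelope ring at confocal resolution; wide enough to absorb
  segmentation jitter of the outline, narrow relative to the 3 µm depth
  criterion. Exposed in `ScoringConfig` and reported in output metadata.
- **Intensity-weighted fraction as default** — "fraction of total signal"
  reads naturally as intensity; with folds rendered at rim intensity the
  two modes agree closely on synthetic data.
- **Depth = max EDT at lamin pixels** — penetration depth into the
  interior, not geodesic fold length; "extends into the interior for at
  least 3 µm" is interpreted as how deep the fold reaches.
- **Strict `> 0.3`, inclusive `≥ 3 µm`** — matching the wording of the
  two criteria ("exceeded" vs "at least").
- **Per-nucleus Otsu with one isodata refinement** — the lamin histogram
  in a nucleus neighbourhood is strongly bimodal with an empty gap
  between the background and rim modes. Otsu's between-class variance is
  flat across such a gap, and an argmax tie resolves to the gap's *lower*
  edge, where single noisy background pixels can cross the cut and fake
  deep "invaginated" signal. One isodata step — resetting the threshold
  to the midpoint of the two class means — centres the cut in the gap
  and makes the partition stable. A fixed-value threshold override is
  available.
- **Exact conservation** — boundary and interior intensity sums are
  accumulated in float64; float32 pixel values are exactly representable
  and the partial sums stay far below 2^52, so
  `sum(boundary) + sum(interior) = sum(all thresholded lamin)` holds
  exactly, not approximately.

Nuclei with no lamin-positive pixels raise a typed error and are excluded
and counted, never silently scored 0.

## Segmentation

Nuclei: Gaussian smoothing (0.2 µm), Otsu or fixed threshold, hole
filling, removal of objects under 20 µm² (debris), distance-transform
watershed to split touching nuclei (markers = EDT maxima at least 6 µm
apart), and removal of border-touching objects — fraction and depth are
undefined on truncated nuclei. Cell bodies: the cytoplasmic channel is
thresholded, foreground is assigned to the nearest nucleus by a
nucleus-seeded watershed on the distance-to-nucleus map, and each cell is
forced to be a superset of its nucleus with the same label. Nuclei with
no surrounding cytoplasmic foreground are flagged (`no_cytoplasm`) rather
than dropped. Otsu thresholding makes segmentation invariant to constant
intensity offsets.

## Transport assay

`N/C = (mean_nuc − bg) / (mean_cyto − bg)` per reporter, with `bg` the
median intensity outside all cell masks by default. Mean-intensity ratios
are the area-independent analogue of equal-area integrated-density ROIs:
automated compartment masks have unequal areas, and the mean ratio is
invariant to both compartment size and channel rescaling. Cells whose
cytoplasmic mean does not exceed background are excluded and counted.
Only directionality and monotonicity in the mixing parameter are asserted
on synthetic data; absolute ratios of real reporters depend on expression
level and imaging settings.

## Trajectory analysis

Comet detection and linking are out of scope by design — published
trackers solve that problem; the input contract is the per-frame
coordinate table. Nuclear entry tests every segment between consecutive
track points at 0.25 px steps, so a comet crossing the nucleus between
frames is counted. No minimum dwell or track length is imposed: any
intersection counts, and the per-cell flag is order-reversal invariant.
Speeds honour frame gaps (`displacement / (Δframe × interval)`).

## Statistics

`scipy.stats` backs the t test (Student's by default, Welch optional),
one-way ANOVA, Tukey HSD and Dunnett comparisons. The module's tests
verify the classical contracts (F = t² on two groups, type-I error ≈ α
under the null, familywise control of the adjusted comparisons) rather
than re-deriving the distributions.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not photorealism:

- **Nuclei** — ellipses (semi-axes ≈ 6 × 5 µm, jittered) with mild
  low-order radial harmonics (~0.15 µm amplitude) for boundary
  irregularity, laid out on a jittered grid (16 µm spacing) so nuclei
  and somata never overlap. Default pixel size 0.1 µm (oversampled
  confocal).
- **Lamin** — a 0.22 µm rim line at 200 photons/px over a 5 photons/px
  interior, plus invagination folds rendered as constant-width curved
  arcs (quadratic Bezier, curvature-controlled) anchored on the rim at
  rim intensity. The fold centerline stops `width/2` short of the target
  depth so the stamped fold *tip* penetrates to the requested `depth_um`
  (verified against the EDT of the rendered mask to ±0.2 µm).
- **Planted-positive nuclei** — 3–5 folds of width 0.8–1.2 µm and depth
  3.3–4.3 µm (clamped below the minor semi-axis). With these geometries a
  planted nucleus carries an invaginated fraction comfortably above 0.3
  and a depth above 3 µm, so planted positivity and measured positivity
  coincide and prevalence recovery is a clean binomial check.
- **Reporters** — the depleted compartment of each reporter renders at
  `delta + (1 − delta) × 0.08` of the enriched compartment's 150
  photons/px (linear mixing). The 0.08 floor models residual
  steady-state leakage, keeps ratios finite and strictly positive at
  `delta = 0` (N/C ≈ 12.5 for NLS), and preserves the two asserted
  limits: monotonicity in delta and ratio → 1 as delta → 1.
- **Noise** — `Poisson(g·I)/g + N(0, σ) + offset` per channel with
  g = 1 photon/unit, σ = 2, offset = 10; `poisson_gain = inf` gives the
  noiseless limit. Channel sub-seeds derive from the field seed, so an
  identical `FieldSpec` renders bit-identically.
- **Tracks** — persistent random walks at 0.2 µm/s, 1 frame/s, step
  jitter ±5%. Entering tracks steer toward an interior nucleus pixel
  until they cross the boundary; non-entering tracks are rejected out of
  a nucleus keep-out zone wider than one step, so no inter-frame segment
  can cross unrecorded. Per-track entry is an independent Bernoulli draw.

What the generator does **not** emulate: PSF blur and chromatic shifts,
intensity heterogeneity within compartments, neurites and overlapping
cells, 3D fold topology, photobleaching, and tracker errors (broken or
merged tracks). Passing tests therefore demonstrate correctness of the
measurement chain on well-posed 2D inputs — not robustness to every
artifact of real microscopy, where segmentation and thresholding quality
dominate.

## Problem sizes and determinism

Validation uses fields of 300 nuclei (≈ 2900 × 3000 px at 0.1 µm/px) for
population-level checks — control false-positive rate, prevalence
recovery at 0.1/0.25/0.4, the flattened-folds (nocodazole-like) control —
and 50-cell fields per mixing level for transport monotonicity; these
sizes give binomial confidence bands of a few percent while keeping a
full run in tens of seconds. All randomness flows through explicit seeds
(`numpy` `SeedSequence` spawning per channel/cell), so every pipeline
run, test and the acceptance script are deterministic given their seed.

## Known limitations

- Watershed marker selection can over-split very elongated nuclei if
  `split_min_distance_um` is reduced well below the nucleus minor axis.
- The depth score reports the deepest lamin pixel only; it does not count
  folds per nucleus or measure fold length.
- Cohort-style manual scoring (multiple observers, DAB chromogen) is
  represented only by the depth criterion itself, not by an observer
  model.
- The transport background estimate assumes some extracellular area is
  visible in the field.
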