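# Methods notes

This note documents the models, conventions and design decisions behind
`projquant`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, what the synthetic generators do and do not
emulate, and where the design was genuinely open.

## Coordinate conventions

All volumes use one canonical axis order, **(AP, DV, ML)**: axis 0
anteroposterior with indices growing posteriorly, axis 1 dorsoventral
growing ventrally, axis 2 mediolateral growing rightward. File readers
reorder any declared permutation on load, so axis bugs cannot propagate
past I/O. Physical positions are bregma-referenced millimetres with
anterior, ventral and right positive. Bregma and the midline are
configuration (`CoordinateFrame`), never constants, because toy and real
atlases place them differently.

Voxels within 0.5 voxel of the sagittal midplane form a separate
**midline** bucket rather than being forced into a hemisphere; ipsi +
contra + midline + unassigned therefore always partitions any total. This
is our choice — assignment of exactly-midline voxels is otherwise
underdetermined — and it is recorded in table metadata.

## Weighted skeletonization

The multi-threshold skeleton binarizes the probability volume at
thresholds 0.2–0.9 in steps of 0.1, thins each mask, scales each skeleton
by its threshold and sums. Choices a user should know:

* **Thinning algorithm**: 3D medial-axis thinning
  (`skimage.morphology.skeletonize`), 26-connectivity. The procedure that
  the weighted skeleton generalizes does not mandate an algorithm; medial
  axis is the standard for neurite tracing, and the test oracle uses the
  same primitive so equivalence is well defined.
* **Anisotropy** (native voxels 5.3 × 5.3 × 5 µm) is ignored during
  thinning — it operates on the voxel lattice — and carried in metadata
  for physical-unit conversions downstream.
* **Nesting**: the per-threshold masks are nested by construction
  (`P ≥ 0.9 ⊆ P ≥ 0.8 ⊆ …`); the implementation asserts this before
  thinning as a cheap sanity check against non-monotone preprocessing.
* **Weights are metadata.** Downstream counting treats every skeleton voxel
  as one axon-containing voxel. The weight exists to rescue dim axons
  during construction and to support curation; no analysis in this package
  consumes it numerically.
* **Component filter**: components with *strictly fewer* than 10,000
  voxels are removed (26-connectivity; both are config fields since the
  cutoff interacts with connectivity). Filtering relabels survivors by
  descending size with ties broken by previous label, making it
  deterministic and idempotent. Curation is a keep/drop file per component
  with free-text reasons, persisted in provenance — scripted review
  replaces interactive inspection.

## Atlas mapping and normalization

Native skeleton coordinates are scaled to µm, passed through the
registration chain (4×4 affines and/or trilinear displacement grids;
points outside a grid's support take the nearest-edge displacement and are
tallied), divided by the 25 µm atlas voxel size, and **rounded half-up**
(`floor(x + 0.5)`) per axis to a single atlas voxel. Each native axon voxel
contributes exactly one count to exactly one voxel — no trilinear
splatting — so the counts volume retains the native axon-voxel count
exactly; out-of-atlas coordinates are tallied, never dropped silently. The
rounding rule is a documented convention: conservation holds under any
rule, reproducibility demands one.

Dividing by the labeled-neuron count gives density per cell. The
end-to-end invariant `skeleton voxels = density total × n_cells +
out_of_bounds` is asserted on every pipeline run (to float-sum precision,
≈1e-9 relative).

Injection masks are inputs (the upstream study segmented them with a
trained pixel classifier, which is out of scope here; the synthetic module
provides masks). QC: a sample is included iff ≥ 80% of mask voxels carry a
target structure's ID *or any descendant's* (layers count toward their
area); the boundary is inclusive ("at least 80%"). Excluded samples keep
their per-sample outputs, flagged `included=false`, and drop out of group
averages and regressions — auditability over silent removal.

## Region tables, rollup, ranking

Tables carry one row per (leaf structure × {ipsi, contra, midline}) plus
`unassigned` rows for annotation ID 0, so empty regions are explicit
zeros. Rollup replaces each structure by its ancestor *k* steps up (capped
at the root — we use the immediate parent per level, not any fixed
taxonomy depth) and re-sums; totals are conserved exactly at every level.
Ranking takes, per region, the mean of totals over all (group × both
hemispheres) cells with missing entries as 0, sorts descending, breaks
ties lexicographically by acronym, and truncates (default top 75). Midline
and unassigned buckets are reported but never ranked. Log scaling for
display (`log10(x + ε)`, ε = smallest positive value / 10) is
presentation-only; stored zeros stay zeros.

## Similarity matrices

Categorical vectors concatenate ipsi and contra per-leaf-region totals
(hemispheres separate, since the region tables keep them separate; pooling
is the other defensible reading). Spatial correlation filters each map
with an isotropic 3D Gaussian, σ = 4 voxels, **reflect** boundary — the
common scientific default, avoiding edge attenuation; the choice is
recorded in matrix metadata. σ = 0 reduces to raw-voxel correlation. A
constant sample vector has no defined correlation: its entries are NaN and
the sample is listed in the matrix metadata, never silently zeroed. No
injection-site exclusion is applied by default.

## Hotspot topography

The horizontal motor-cortex map selects layers 2/3 and 5 of MOp and MOs
(both hemispheres), sum-projects along DV, filters at σ = 4 px (25 µm
pixels) and thresholds at 75%/95% of max. Decisions where the procedure
was ambiguous, each behind the stated default:

* the 95% centroid is the **unweighted** centroid of all supra-level
  pixels, even if disconnected (an intensity-weighted variant would also
  be defensible; unweighted is the simplest faithful reading);
* peak ROI density is the mean of the **filtered** map over a 9 × 9 pixel
  (225 µm) square centered on the peak pixel, clipped at borders, reported
  per mm² per neuron — the peak is defined on the filtered map, so the ROI
  is measured there too;
* ties at the maximum resolve first-in-scan-order (row-major); relevant
  only for degenerate synthetic inputs;
* an all-zero map yields a defined "no hotspot" result (all metrics NaN)
  and the sample drops out of the regression, mirroring injections without
  motor-cortex axons.

With anterior positive, the mirror map has **positive** slope: more
lateral injections, more anterior hotspots. The regression is ordinary
least squares of centroid AP on injection-center |ML| with Pearson r and a
two-sided t-test on n−2 degrees of freedom; it requires ≥ 3 finite points
and nonzero |ML| variance.

Caudoputamen profiles mask to CP (+descendants), filter at σ = 4 voxels,
and sum: AP and DV curves from the ipsilateral hemisphere only, ML curve
bilateral; curves are cropped to the CP bounding box and reported in
bregma mm. At σ = 0 the curve integrals equal the masked totals exactly.

## Wide-field functional analysis

Frame timing is irregular by design (100 Hz peri-stimulus, 50 Hz
interleaved during stimulation), so every window — the 300 ms baseline,
the 10–260 ms evoked window — selects frames **by timestamp, never by
index**. ΔF/F₀ uses the per-trial mean baseline image; pixels with
non-positive F₀ become NaN and are tallied. Evoked maps average frames
then trials; population maps weight mice by trial count. The response
center is the **value-weighted** center of mass of pixels at or above 80%
of the **within-mask** maximum of the evoked map, inside a 40 × 25 pixel
frontal rectangle; both italicized readings are ambiguous in the
underlying procedure and are fixed here as documented defaults (flags
could expose the alternatives; negative ΔF/F pixels are kept in averages
but can never enter the supra-threshold set when the maximum is
positive). Mice contribute to the population regression even when they
have too few distinct stimulation sites for a per-mouse line.

## Synthetic data: what it emulates, what it does not

The generators produce every input the pipeline consumes, with ground
truth recorded and all randomness drawn from a single seed:

* **Toy atlas** — 241 × 101 × 401 voxels at 25 µm (6 × 2.5 × 10 mm),
  bregma at voxel (120, 0, 200), exact left–right mirror symmetry. Regions
  are hemisphere-symmetric cuboids: MOs (|ML| 0.15–1.0 mm, AP +0.5…+2.75),
  MOp (1.0–2.3 mm, AP 0…+2.75), SSp-bfd (2.4–3.6 mm, AP −2.5…−0.5), SSs
  (3.6–4.6 mm), each with layers 1, 2/3, 5, 6 stacked over the first
  millimetre of depth, plus CP (|ML| 1.3–2.8 mm, DV 1.2–2.2 mm). Extents
  are round-number approximations of the corresponding mouse structures —
  sufficient for exact partition/rollup arithmetic, not anatomy.
* **Tube phantoms** — self-avoiding random-walk centerlines (step 1 voxel,
  angular diffusion 0.2, non-adjacent segments kept ≥ 4 tube radii apart
  so profiles never fuse; walls reflect), Gaussian cross-section of radius
  1 voxel, max-combined, plus bright spherical blobs pinned to volume
  faces emulating surface artifacts, plus additive Gaussian noise clipped
  to [0, 1] — the simplest model that exercises multi-threshold behavior.
  No photorealism, no anisotropic PSF, no intensity falloff.
* **Injection cohorts** — seven injections at |ML| 2.6–4.3 mm spanning
  SSp-bfd into SSs, 80–150 labeled cells each, 50 axon voxels per cell,
  20% of the budget in CP. Hotspot centers follow AP = 0.25 + 0.5·|ML| + ε
  (slope mid-range of reported per-class values; ε of sd 0.1 mm), with
  Gaussian in-plane spread of 6 px. Points are rejection-sampled inside
  the target layer structures, so the deposited counts equal the drawn
  budget exactly (the generator's bookkeeping invariant). `native` mode
  instead renders tube phantoms in a native-resolution window over the
  hotspot with the exact translation affine into atlas space, so
  skeletonization and mapping run for real; registration *error* is not
  simulated (fitting registrations is out of scope).
* **Wide-field sessions** — post-binned geometry (160 × 128 px at
  62.5 µm), stimulation grid at 0.5 mm spacing, response amplitude 0.05
  ΔF/F with σ = 4 px spread and a 0–500 ms boxcar, per-frame noise sd 0.01
  ΔF/F, 10 trials per point. Response centers are snapped to the pixel
  lattice so the noise-free evoked-map peak equals the amplitude exactly.
  `coarse` timing subsamples the clock for cheap simulations while
  preserving timestamp-selection semantics. No hemodynamic contamination,
  no photostimulation artifact, no motion.

Passing tests on these phantoms therefore demonstrates *algorithmic*
correctness — conservation, oracle equivalence, parameter recovery under
the stated noise — not robustness to real-tissue segmentation errors,
registration misfit or imaging artifacts.

## Problem sizes in tests and the acceptance script

Recovery tests use the full 25 µm toy atlas and the full seven-injection
design. Oracle-equivalence phantoms are 50³; native-mode end-to-end runs
use 64³–120³ windows and 3–4 samples, which keeps whole-pipeline
determinism checks to seconds while exercising every stage. Wide-field
recovery uses 6 mice × 4 stimulation sites with frames cropped to the
frontal field (36 × 112 px at the standard pixel size), 5 trials per
point, coarse timing, and per-mouse grid jitter of ≤ 0.15 mm (as in
per-animal grid calibration; it also decorrelates pixel-snapping across
mice so OLS interval calibration is honest). Confidence-interval coverage
is measured over 200 seeded replicates for both the anatomical and the
functional regression.

## Known limitations

* The skeletonization algorithm and its connectivity are package choices;
  a different thinning primitive would move voxel-level results.
* Weighted-skeleton weights are retained but unused downstream; any
  analysis that should consume them needs new code.
* The toy atlas has no curvature, no intermediate hierarchy nodes between
  area and layer, and IDs shared across hemispheres (hemispheres are
  resolved geometrically, as in the CCF).
* Real region rankings depend on the real parcellation and data; the
  package reproduces the *procedure*, not any published top-75 list.
* Displacement-field transforms are supported and tested, but synthetic
  cohorts use pure affines; warp-induced distortion of counts is untested
  against ground truth.
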