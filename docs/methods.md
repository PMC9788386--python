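# Methods

## The scoring problem

The cytokinesis-block micronucleus (CBMN) assay blocks cytokinesis with
cytochalasin B so that cells which completed exactly one nuclear division
appear bi-nucleated. Genotoxic damage is read out as micronuclei (MN) —
small chromatin bodies separate from the main nuclei — counted **only** in
bi-nucleated cells (BNCs), the population known to have divided under
treatment. Automated scoring therefore needs four things in sequence:
reliable single-nucleus segmentation, a cell territory that groups the right
nuclei together, a classifier on nucleus count, and an MN detector confined
to BNCs. Each stage is described below together with the choices that were
genuinely open and how they were settled.

## Synthetic plates and what they do (and do not) emulate

No public image corpus exists for this assay layout, so the package carries a
simulator whose defaults define the study conditions used by the test suite.

**Geometry.** Each field (default 512×512 px) holds a fixed number of cells
(default 25, ≈20 % area coverage — a sub-confluent monolayer). A cell is a
disc-shaped cytoplasm containing 1, 2 or ≥3 near-circular elliptical nuclei
(mean radius 10 ± 1.5 px, eccentricity ≤ 0.08), drawn from a mixture
(default p_mono = 0.45, p_bi = 0.50, p_multi = 0.05 — the cytochalasin-B
working point at which about half the population is bi-nucleated, with a
small multinucleated tail). Sister nuclei keep a 3-px rim gap; the cytoplasm
radius is the nuclear extent plus 6 px.

**Spatial regimes.** One `clustering` knob switches between the two growth
phenotypes that matter for segmentation: `0` places cells by hard-core
random sequential adsorption (cytoplasms disjoint with a 6-px gap —
enzymatically separated cells), larger values use a Neyman–Scott cluster
process (mean cluster size 1 + clustering, offspring scatter ∝ cell radius)
in which cells overlap freely — aggregated colony growth that provably
degrades nucleus counting (tested as a paired property over seeds).

**Micronuclei.** Each BNC draws Poisson(`mn_rate`) MN (default 0.02, a
vehicle-level background; dose presets simply raise the rate). An MN is a
disc of diameter `mn_diameter_ratio` (default 0.2, inside the 1/3 OECD
ceiling) times the cell's mean nucleus diameter, floor radius 1.5 px, placed
uniformly in the cytoplasm with a ≥4-px rim clearance to every main nucleus
and to other MN — MN are *distinct* chromatin bodies, so the rendered image
always agrees with the truth count. MN that find no clear spot in 200 draws
are dropped from both image and truth.

**Intensities and noise.** Nuclei and MN share the DNA-channel chromatin
amplitude (100 units over a 20-unit pedestal, ±8 % per cell); the actin
channel is a smoothed filled cytoplasm indicator (amplitude 60). An additive
planar illumination gradient with peak-to-trough span `background_gradient`
× channel amplitude (default 0.2), then Poisson shot noise and Gaussian read
noise (sd 2) are applied. Optional reporter (baseline 10, ×`reporter_fold`
inside cells) and low-contrast phase-like channels support the ROS readout.

**Determinism.** Every stochastic step derives from
`SeedSequence([seed, field_index, stream])`; identical parameters give
bit-identical images and truth. Per-well seeds on a plate are a fixed
integer mix of the group seed and well position (kept below 2³¹).

**Not emulated** (and therefore not demonstrated by passing tests):
real chromatin texture, focus drift, spectral crosstalk, apoptotic/necrotic
morphologies, nucleoplasmic bridges and buds, irregular cell shapes, and
density-dependent intensity effects. The simulator shows that the *geometry
and counting logic* of the pipeline is correct under realistic noise, not
that the default thresholds transfer unchanged to any particular microscope.

## Illumination correction

The background surface is the blockwise low percentile of the image
(default 32-px blocks, 10th percentile), lightly smoothed and bilinearly
upsampled; only the *trend* (surface minus its minimum) is subtracted and
the result clipped at zero. Flat images pass through unchanged, and the
pedestal is preserved so Otsu thresholds stay meaningful. For channels whose
foreground structures are cell-sized rather than nucleus-sized (actin,
phase, reporter) the surface is estimated on 64-px blocks at the 5th
percentile, because a cell body can cover an entire 32-px block and would
otherwise inflate the local background. Residual trend on default synthetic
fields is below 5 % of the nuclear amplitude.

## Nucleus segmentation

Gaussian smoothing (σ = 2 px) then Otsu. An **empty-field guard** rejects
the threshold when the foreground–background separation is small (below
max(8 intensity units, 3 robust σ from the median)): without it, Otsu on a
noise- or residual-gradient-only field would hallucinate objects. Touching
nuclei are split by a watershed on the negated, smoothed distance transform,
seeded at distance-transform maxima at least `split_min_distance` (8 px)
apart. Area gates (100–5000 px²) drop debris and — deliberately — MN-sized
specks, which belong to the MN detector, not the nucleus map. Objects
touching the field border are excluded by default (whole-cell scoring).
Labels are renumbered by topmost-leftmost pixel so runs are reproducible.

## Cytoplasm territories and cell assembly

Each connected component of the thresholded, hole-filled actin mask is one
cell territory. This implements the merge rule directly: two nuclei inside
one unbroken actin blob form one bi-nucleated territory, so no seeded
watershed is needed (splitting a blob between nuclei would *undo* exactly the
BNC geometry the assay depends on). A nucleus is assigned to the territory
covering > 60 % of its area; a nucleus straddling territories with no
majority owner is *cross-contaminating* and removed from every cell — the
same cleanup step used by high-content scoring protocols for this assay.
The 0.6 fraction is strict enough to catch straddlers yet robust to 1-px
boundary jitter. Cells are classed mono (1), bi (2), multi (≥3); zero
surviving nuclei or a border-touching territory means `excluded` and the
cell leaves the scored totals.

## Micronucleus detection

Only for BNCs. Within the cell's territory the DNA channel is smoothed at
σ = 1 px (MN are a few pixels across; the σ = 2 nuclear smoothing would
flatten them) and thresholded 30 % of the way from the local background
(median of non-nuclear territory pixels) to the cell's main-nucleus mean —
about 5 robust σ above background at default noise. Candidates are kept iff

1. equivalent diameter between 1/16 and 1/3 of the mean main-nucleus
   diameter (the upper bound is the OECD criterion; the lower bound
   suppresses noise specks),
2. after 1-px dilation they still do not touch the (1-px dilated) main
   nuclei — a clear cytoplasmic rim,
3. mean raw DNA intensity within 0.5–2× the main-nucleus mean (chromatin,
   not debris),
4. area ≥ 4 px² and centroid inside the territory.

Calls are ordered by centroid (row, col). On default-noise synthetic plates
with ≥500 true MN both precision and recall exceed 0.90 (the suite measures
them by greedy centroid matching at 5-px tolerance).

## Endpoints

CBPI = (N₁ + 2N₂ + 3N₃₊)/N; %BNC = 100·N₂/N; MN frequency is reported as
**total MN per 1000 BNCs** (matching the conventional axis label), not as
percent micronucleated BNCs. A well with no scored cells or no BNCs is
returned with zeroed endpoints and an explicit QC flag rather than an
exception, so plate-level tables never silently drop wells.

## ROS readout

MFI per cell area = (summed reporter intensity)/(total cell-mask area) over
all fields of a well, the mask thresholded from the phase-like channel
(actin as fallback) after illumination correction; this is the
total-over-total convention rather than a mean of per-cell ratios. Folds are
versus the mean vehicle MFI, so vehicle wells average exactly 1.

## Statistics

Dunnett's many-to-one procedure is computed through the exact equicorrelated
multivariate-t distribution (scipy's implementation, fixed integration
stream, so results are deterministic); each comparison also records its
marginal pooled-model t-test p (pooled SD, df = N − k), which is the
quantity the adjusted p provably dominates. A 2000-replicate null simulation
in the test suite confirms family-wise type-I calibration at α = 0.05
within [0.03, 0.07]. The 4PL dose–response
y = bottom + (top − bottom)/(1 + 10^(hill·(log₁₀c − log₁₀IC50))) is fitted by
Levenberg–Marquardt with multi-start over hill sign and IC50 quantile
anchors; zero doses map to one decade below the lowest nonzero dose; IC50 is
the curve midpoint. Initialisation uses only quantiles of log-concentration,
which makes the fitted IC50 exactly equivariant under unit rescaling.
Degenerate data (constant response) lower the convergence flag instead of
raising. SEM = sd/√n over replicate wells; n = 1 rows are flagged, not
guessed.

## Problem sizes used by the test suite

The suite runs entirely on simulated data at desk scale: 512-px fields, 25
cells per field; the exact-recovery plate is 4 wells × 10 fields; detection
quality uses 30 all-BNC fields (≈600 true MN) plus 20 mixture fields; the
bi-nucleation calibration scores ≥2000 cells (~80 fields); the clustering
comparison pairs 20 seeds. These sizes keep every run reproducible on a
single CPU while leaving the binomial/Poisson tolerances meaningful.

## Known limitations

* Thresholds are calibrated for the simulator's contrast regime; real DAPI /
  phalloidin images will need `SegmentationParams`/`MnParams` adjustment.
* Clustered (overlapping) growth is *measured* to degrade counting — the
  package offers no declumping rescue beyond the watershed, mirroring the
  assay's own answer (separate the cells before fixation).
* One territory per connected actin blob means truly confluent sheets
  collapse into one excluded mega-cell rather than being partitioned.
* The full cytome assay (nucleoplasmic bridges, buds, apoptosis/necrosis) is
  out of scope.
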