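# Methods

This note documents the models, parameters and numerical choices behind
`trisyn`, and what the synthetic-data validation does and does not show.

## Image model and geometry

Scenes are registered 2D intensity planes, one per marker role, at a
default pixel size of 0.04 µm and a default field of 1950 × 1950 px
(78 × 78 µm), matching super-resolution confocal fields of the lateral
ventral horn. Inputs are assumed to be reconstructed single-z planes;
3D stacks, drift correction and detector simulation are out of scope.

## Segmentation chain

Each channel is processed as a punctate-immunofluorescence particle
analysis:

1. **Background subtraction** — grey-scale morphological opening with a
   disc footprint (default radius 20 px ≈ 0.8 µm), subtracted from the
   image and clipped at zero. This is the opening-based equivalent of
   rolling-ball background removal; the footprint must exceed the largest
   object of interest, so channels with large objects (C-boutons, somata)
   use a larger radius or skip the step.
2. **Gaussian smoothing** — σ = 1 px by default (sub-punctum smoothing at
   0.04 µm/px), reflective borders, so total intensity is conserved to
   better than 1 %.
3. **Thresholding** — Otsu's between-class variance criterion per channel
   by default, with a manual override in the config. A constant plane
   binarizes to *empty*: with no contrast there is no evidence of objects.
   No per-image intensity normalisation is applied before thresholding.
4. **Watershed splitting** — Euclidean distance-transform watershed seeded
   by local maxima with a minimum seed separation (default 3 px,
   8-connectivity). The seed separation should scale with expected object
   size: for puncta of Gaussian σ ≈ 3 px a separation of 5 px avoids
   spurious splits from discretised distance-transform plateaus, and the
   validation studies use object-size-matched separations (5 px for small
   puncta, 12 px for C-bouton-sized objects, 15–25 px for nuclei/somata).
   Components too thin to contain a detected maximum receive a fallback
   seed so no foreground pixel is ever lost.
5. **Size filter** — particles of fewer than 8 px are removed ("less than
   eight" read literally: area ≥ 8 px survives); labels are relabelled
   contiguously.
6. **Measurement** — area, centroid and mean intensity per particle, with
   intensity *redirected* to the raw plane; the processed image only
   selects which pixels are measured.

## Colocalization and synapse typing

All colocalization is object-based with a single rule: two particles
colocalize when their masks share at least one pixel. Derived definitions:

- *Bona fide synapse*: presynaptic particle overlapping ≥ 1 PSD95
  particle. The recorded PSD partner is the largest overlapping PSD
  particle; area ties break to the lowest label (deterministic).
- *Tripartite synapse*: a bona fide synapse whose bouton overlaps any PAP
  particle; the tripartite fraction is reported over bona fide synapses,
  so tripartite + non-tripartite always partitions them.
- *C-bouton apposition*: "apposed to" soma labelling implies membrane
  contact rather than containment, so the soma mask is dilated by a small
  tolerance (default 2 px = 0.08 µm, config-overridable) before the
  overlap test. The apposed set is non-decreasing in the dilation radius.
- *pTDP-43 content*: a cluster overlapping k boutons increments each
  bouton's count — the reported metric is per-bouton content, not an
  exclusive assignment.

Single-marker presynaptic metrics (density, total area, size) are computed
over all presynaptic particles, not only those with a PSD partner; the
synapse-restricted sizes are reported as separate columns.

## Nuclear/cytoplasmic pTDP-43 partition

The stain set for mislocalisation (pTDP-43 + DAPI) contains no soma
marker, so the "surrounding cell body" is approximated by a fixed-width
annulus around each nucleus (default 1 µm), minus every nucleus. Nuclei
touching the image border are flagged and excluded by default. Signals are
summed background-subtracted intensities; both the nuclear/cytoplasmic
ratio (reported as infinite when the cytoplasmic sum is zero) and the
bounded nuclear fraction nuclear/(nuclear+cytoplasmic) ∈ [0, 1] are
provided, and statistics use the fraction. A cluster-count mode (counting
segmented pTDP-43 particles per compartment by centroid) is available as
an option. In the pipeline the intensity sums are restricted to the
segmented pTDP-43 foreground: without this restriction the residual noise
floor left by opening-based background subtraction accumulates over the
cytoplasmic annulus (which has several times the nuclear area) and biases
the fraction downward.

## Astrocyte morphometry

GFAP coverage is the foreground area fraction; intensity is the raw-plane
mean over the mask (0 with an `intensity_undefined` flag when the mask is
empty); astrocyte density counts DAPI nuclei overlapping the GFAP mask
(≥ 1 px) per 10,000 µm² — GFAP fragments are not cells. Branching analysis
skeletonizes the mask (topology-preserving thinning); a branch point is a
skeleton pixel with ≥ 3 skeleton neighbours, with adjacent junction pixels
merged into one junction; branches are the skeleton segments between
junctions and endpoints; lengths count diagonal steps as √2 px, scaled by
the pixel size; terminal spurs shorter than 3 px are pruned. "Branch
length" means branch-segment length (a point has no length). Branch counts
are invariant under translation and 90° rotation.

## Group statistics

Per-image values are aggregated to one value per animal by the median
across all images (at least two tissue sections per animal; a single image
triggers a warning). Groups are compared with the equal-variance (pooled)
two-sample Student *t*-test with df = n₁ + n₂ − 2 — the convention implied
by reported degrees of freedom of 10 for 6 vs 6 and 9 for 6 vs 5 animals —
and a two-sided p-value from the Student-t survival function. Shapiro–Wilk
(Royston's approximation, via scipy, verified against R's `shapiro.test`)
screens each group; a normality failure emits a warning but never switches
the test. No multiple-testing correction is applied by default;
Benjamini–Hochberg is available behind a flag. Zero pooled variance is
reported as a degenerate comparison rather than a number.

## Synthetic scenes

The generator emulates the statistical structure of the real data, not its
appearance:

- **Puncta** are isotropic 2D Gaussian spots truncated at 3σ; the radius
  parameter is σ, log-normally distributed (median + log-dispersion), with
  truncated-normal peak amplitudes. Counts are Poisson with mean
  density × area / 10,000 µm²; positions are a homogeneous Poisson process
  with an optional hard-core separation and optional exclusion of cell
  regions for presynaptic markers.
- **Appositions**: each bouton receives a PSD95 partner with probability
  `psd_apposition_prob`, and (if bona fide) a PAP partner with probability
  `tripartite_prob`. Partners are offset by one bouton-σ in a random
  direction, which guarantees partial (≥ 1 px), not concentric, overlap of
  the half-maximum object masks for any partner size.
- **pTDP-43**: per bouton, a Poisson number of clusters (σ = 2.5 px by
  default) placed within one bouton-σ of its centre, with a hard-core
  separation of 4 cluster-σ so that clusters of one bouton remain
  resolvable after segmentation. Somatic pTDP-43 is split between the
  nucleus and the annular cytoplasm so the compartment amplitude sums
  match `nuclear_fraction` exactly; spot counts per compartment are chosen
  so per-spot amplitudes are nearly equal across compartments, keeping
  threshold truncation unbiased.
- **Cells**: nuclei and somata are soft-edged discs; cell centres carry a
  hard-core separation so nucleus + annulus regions never overlap.
- **Noise**: Poisson shot noise on (signal + background) at a photon scale
  plus additive Gaussian read noise (defaults: scale 2, background 10,
  read σ 2), the standard fluorescence camera model.

Identical (config, seed) gives bit-identical planes and tables.

Default marker statistics (densities per 10,000 µm², σ medians) were fixed
once as field-realistic values for ventral-horn grey matter: sparse large
cholinergic boutons (15 per 10⁴ µm², σ 10 px), denser small inhibitory and
excitatory puncta (80–150 per 10⁴ µm², σ 4–5 px). The NLS-like phenotype
differs from control only by the stated effects: VAChT size median
reduced 25 %, VGLUT1 density reduced 25 %, pTDP-43 clusters per bouton
3 → 2, nuclear fraction 0.8 → 0.4; contact probabilities (0.8 PSD
apposition, 0.75 tripartite) are common to both groups. Cohorts add a
log-normal animal-level effect (5 % CV) on density and size to both
groups, so per-animal values vary realistically around the group means.

What the generator does *not* emulate: tissue autofluorescence, spatially
structured background, anisotropic or clustered punctum layouts, marker
bleed-through, and section-to-section variability beyond the animal
effect. Passing recovery tests therefore demonstrates the correctness of
the measurement chain under the stated noise model, not robustness to
every real-tissue artefact. One known interaction worth noting: the
per-channel global Otsu threshold couples bright somatic pTDP-43 to the
detectability of dim synaptic clusters in the same channel, so absolute
cluster-content levels in scenes containing cell bodies are
threshold-limited (group comparisons remain valid because both groups
share the limitation; cluster-rate recovery is validated on neuropil-only
scenes).

## Validation problem sizes

Simulation studies use scaled-down fields chosen as the package's default
validation sizes: 512–1280 px fields with densities set to yield ~50–250
objects per scene for recovery checks, and 320-px single-marker fields for
the 20-replicate type-I-error and power studies (6 vs 6 animals, two
images each). The type-I study uses identical group generators and
pools all metric comparisons; the power study injects the 25 % VAChT
size-median reduction and tracks the size metric.

## Pipeline and reproducibility

The pipeline validates the sample sheet (declared genotypes only, files
present), processes every image, and writes per-image, per-animal and
group-comparison CSVs plus a manifest with a config hash. Intermediate
tables carry image/section/animal keys but no genotype string; genotype is
joined only at the statistics stage, mirroring blinded analysis. Reruns
with the same inputs and config are byte-identical. A missing channel
skips the dependent analysis with a logged warning and a nonzero status
flag in the manifest rather than failing the run.
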