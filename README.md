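# trisyn

Quantification of synapse subtypes, tripartite astrocytic contacts and
TDP-43 mislocalisation in multi-channel fluorescence microscopy images of
spinal cord.

## What this package does

In ALS models such as the doxycycline-inducible TDP-43ΔNLS mouse,
phosphorylated TDP-43 (pTDP-43) mislocalises from the nucleus to the
cytoplasm of neurons, and individual synapse populations — cholinergic
C-boutons (VAChT), inhibitory boutons (GLYT2), and excitatory boutons
(VGLUT1/VGLUT2) — change in density and size in subtype-specific ways.
`trisyn` implements the image-analysis and statistics pipeline needed to
measure this from super-resolution confocal images:

- **Punctum segmentation** per channel: background subtraction (grey-scale
  opening), Gaussian smoothing, thresholding (Otsu or manual), watershed
  splitting of merged structures, removal of particles smaller than 8
  pixels, and measurement of particle number, size and intensity with the
  intensity read from the raw image.
- **Object-based colocalization**: two particles colocalize when their
  masks overlap by at least one pixel. On this rule, a *bona fide synapse*
  is a presynaptic bouton partially colocalised with a PSD95 particle; a
  synapse is *tripartite* when the bouton also contacts a perisynaptic
  astrocytic process (PAP; p-Ezrin or GFAP); C-boutons are VAChT puncta
  apposed to motor-neuron somata; per-bouton pTDP-43 content is the number
  and size of overlapping pTDP-43 clusters.
- **Cell morphometry**: the nuclear/cytoplasmic pTDP-43 partition per DAPI
  nucleus (cytoplasm approximated by a 1-µm annulus), cell densities per
  10,000 µm², soma sizes, GFAP coverage/intensity and skeleton-based
  astrocyte branching.
- **Group statistics**: per-image metrics are aggregated to one value per
  animal by the median across images, then compared between genotypes with
  the equal-variance two-sample Student *t*-test,

  *t* = (x̄₁ − x̄₂) / (s_p · √(1/n₁ + 1/n₂)),  df = n₁ + n₂ − 2,

  with per-group Shapiro–Wilk normality screening and mean ± SEM reporting.
- **Synthetic scenes**: a generator of multi-channel fields with known
  ground truth (Poisson point processes of Gaussian puncta, PSD/PAP
  appositions with set probabilities, nuclei/somata as discs, pTDP-43
  split between compartments by a mislocalisation parameter, Poisson +
  Gaussian noise) used to validate every stage by parameter recovery and
  to run power and type-I-error studies.

Analysis stages operate blinded: no genotype label appears in any
intermediate table; genotype is joined only at the statistics stage.

## Worked example

Simulate a 6 vs 6 cohort with two images per animal in which the NLS-like
group has smaller VAChT boutons (size median reduced 25 %) and a nuclear
pTDP-43 fraction of 0.4 instead of 0.8, then run the full pipeline:

```python
import dataclasses
from trisyn.scenes import SceneConfig, MarkerParams, generate_cohort
from trisyn.pipeline import RunConfig, run_pipeline
from trisyn.segmentation import SegmentationParams

base = SceneConfig(
    field_size_px=(320, 320),
    markers={"vacht": MarkerParams(1500.0, 4.0, 0.15, 120.0, 15.0),
             "psd95": MarkerParams(200.0, 3.0, 0.2, 90.0, 12.0)},
    presyn_roles=("vacht",), soma_count=0,
    nucleus_count=1, nucleus_radius_range_px=(18, 24),
    psd_apposition_prob=0.8, ptdp43_clusters_per_bouton_rate=0.5,
    ptdp43_cell_signal=3000.0, nuclear_fraction=0.8, min_separation_px=12,
)
nls = dataclasses.replace(base, nuclear_fraction=0.4)
nls.markers = dict(nls.markers)
nls.markers["vacht"] = dataclasses.replace(base.markers["vacht"], radius_median_px=3.0)
generate_cohort(6, 6, 2, "demo_cohort", base_config_pair=(base, nls), seed=42)

cfg = RunConfig(output_dir="demo_out",
                default_seg=SegmentationParams(background_radius_px=6,
                                               watershed_min_distance_px=5),
                nucleus_min_size_px=250, presyn_roles=("vacht",))
res = run_pipeline("demo_cohort/sample_sheet.csv", cfg)
print(res["group_comparisons"].round(4).to_string(index=False))
```

Selected rows of the printed comparison table (seed 42):

```
                   metric  mean_control  mean_nls       t  df      p
vacht_density_per_10k_um2     1490.2751 1398.7223  0.6275  10 0.5444
      vacht_mean_size_um2        0.1077    0.0902  8.9748  10 0.0000
vacht_tripartite_fraction        0.7710    0.7713 -0.0121  10 0.9906
    ptdp_nuclear_fraction        0.7803    0.4009 30.2364  10 0.0000
```

Reading the output: bouton *density* does not differ between the groups
(p = 0.54, as simulated), the injected 25 % bouton-size reduction is
detected (mean size 0.108 vs 0.090 µm², p < 10⁻⁵), the tripartite fraction
is unchanged (~0.77 in both groups, matching the generator's 0.75 contact
probability up to sampling noise), and the nuclear pTDP-43 fraction
recovers the simulated mislocalisation (0.78 vs 0.40 against true values
0.8 and 0.4). Each row reports the pooled *t*, df = n₁ + n₂ − 2 = 10, and
the two-sided p-value.

A `trisyn` console script exposes the same steps
(`trisyn simulate`, `trisyn run-all`, `trisyn stats`, `trisyn init-config`).

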