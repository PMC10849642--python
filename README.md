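# vesseltau

Vessel-centric 3D quantification of perivascular tau pathology in
cleared-tissue fluorescence microscopy.

In Alzheimer's disease, hyperphosphorylated tau accumulates not only in
neurons (as neurofibrillary tangles, NFTs) but also along the surfaces
of cortical arterioles. Quantifying that accumulation requires a
vessel-centric coordinate system: every voxel near an individually
traced vessel gets an *along-vessel* coordinate (arc length on the
vessel centerline) and an *away-from-vessel* coordinate (Euclidean
distance from the vessel surface). `vesseltau` implements that
quantification end to end for anyone analyzing tubular structures and
their surroundings in 3D fluorescence volumes: neuropathology groups
working with cleared human tissue, and more generally labs measuring
how a diffuse signal or a population of segmented objects distributes
around vessels.

## What it computes

Given multichannel volumes (phospho-tau/AT8, neurons/HuD, vessels/GLUT1),
per-vessel binary masks, and a cortical-layer label volume:

1. **Geometry** — per vessel: an exact anisotropy-aware Euclidean
   distance field *d(x)* (0 inside the mask), a centerline with
   cumulative arc length *s*, and a diameter estimate averaged over
   three equally spaced cross-sections.
2. **Normalization** — each sample's intensities are mapped onto a
   common dataspace by a monotone piecewise-linear transform fixed at
   three measured anchors (background, autofluorescence, positive
   immunolabel; 3 depths × 10 readings each).
3. **Surface-tau deciles** — each 10-μm interval along a vessel is a
   bin; its surface tau is the mean normalized intensity over voxels
   with *d* ≤ 3 μm; bins are percentile-ranked within each donor and
   grouped into deciles 1–10.
4. **Radial profiles** — per decile group, mean intensity in 2-μm
   distance bands out to 100 μm, expressed as
   100·(mean_band − mean_image)/mean_image, so 0 % means "no different
   from average tissue".
5. **Object densities** — segmented NFTs and neurons are matched across
   channels (a neuron is NFT-positive when a tangle overlaps it), placed
   into bins by arc position when within 30 μm of the surface, and
   converted to counts per mm³ of bin neighborhood.
6. **Association statistic** — the fraction of NFT-bearing neurons per
   donor × decile is tested with a one-way repeated-measures ANOVA
   (F = MS_decile/MS_error, R² = SS_decile/(SS_decile+SS_error)), plus
   capillary-immunoassay lane normalization with one-tailed t-tests.

Because the underlying human imaging is not publicly deposited, the
package ships a first-class synthetic phantom generator
(`vesseltau.phantom`) that renders vessels, an exponential perivascular
halo `A·exp(−d/λ)` on chosen arc intervals, neurons whose NFT
probability follows `logistic(β0 + β1·decile)`, layer slabs, and
per-sample affine staining shifts — with complete ground truth, so every
stage is validated by recovery tests.

## Worked example

```python
import numpy as np, pandas as pd
import vesseltau as vt
from vesseltau.phantom import PhantomSpec, VesselSpec, generate_phantom
from vesseltau.io import RunConfig

spec = PhantomSpec(
    shape=(48, 160, 160), tissue_margin_um=0.0, noise_sd=4.0,
    neuron_density_per_mm3=0.0,
    vessels=[VesselSpec(np.array([[24., 80., 8.], [24., 80., 152.]]),
                        radius_um=8, halo_amplitude=20, halo_decay_um=10,
                        tau_intervals=[(20., 80.)])],
)
res = generate_phantom(spec)
cfg = RunConfig()
rec = vt.VesselRecord.from_mask(res.vessel_masks[0], spec.voxel_size)
print(f"diameter {rec.diameter_um:.1f} um, length {rec.total_length_um:.0f} um")
bins = vt.bin_along_vessel(res.channels["AT8"], rec, cfg, donor_id="d1")
bins = vt.rank_deciles(bins, cfg)
print(bins[["bin_index", "mean_surface_intensity", "decile"]].head(4))
```

prints

```
diameter 16.3 um, length 144 um
   bin_index  mean_surface_intensity  decile
0          0               24.991778       2
1          1               26.918219       6
2          2               43.713858      10
3          3               43.694664       9
```

The first bin sits before the tau-positive interval, so its surface tau
is at the autofluorescence level ≈ 25 and it ranks low; bin 1 straddles
the interval boundary at arc 20 μm; bins inside the halo interval
approach 25 + A ≈ 45 and occupy the top deciles.

The same flow, staged and cached on disk, is available from the shell:

```bash
vesseltau run --outdir runs/demo --seed 17 --n-donors 3 --n-vessels 2
```

which emits `bins.csv`, `radial_profile.csv`, `layer_summary.csv`,
`heatmap.csv`, `nft_by_decile.csv`, `stats.json` and a `manifest.json`
of SHA-256 output hashes.

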