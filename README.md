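# rhizoct

Quantifying root-induced soil compaction in 3D X-ray µCT images.

Growing roots interact with soil structure in both directions: where the
pore system offers too few connected macropores, a root must push particles
aside and densify its surroundings — the rhizosphere — while in
well-connected soil it can follow existing pores and leave the fabric
untouched.  `rhizoct` implements the image-analysis chain used to measure
this at ~19 µm resolution:

* **pore segmentation** by hysteresis thresholding (air-, water- and
  root-filled pores alike), with visible porosity, the local-thickness
  (maximum inscribed ball) pore-size distribution, and the volumetric Euler
  characteristic χ as a pore-connectivity measure (strongly negative χ =
  many redundant connections);
* **root/biopore segmentation** by multiscale Hessian tubeness
  (σ²·√(λ₂λ₃)), with diameter classes split at ~250 µm and skeleton-based
  length densities;
* **radial gradient analysis** — the core protocol: a Euclidean distance
  transform from every soil voxel to the nearest root surface, then mean
  gray value and porosity per distance shell, normalized per sample.  Gray
  values act as a sub-resolution density proxy (anti-correlated with
  porosity), so a normalized gray profile rising above 1 toward the root
  marks rhizosphere compaction;
* **compaction-model fitting**: the exponential model
  ε(x) = ε_bulk − Δε·exp(−x/(m·d_root)) (decay length a fixed multiple of
  the root diameter), plus a wall-effect extension
  A_w·exp(−x/(k·d_p)) for the porosity excess from loose particle packing
  directly at the root surface;
* a **seeded phantom generator** (granular matrix at controlled porosity,
  curved tubes, prescribed radial halos, CT-like blur and noise) providing
  exact ground truth, because public µCT benchmarks with known rhizosphere
  structure do not exist.

The target audience is soil scientists and image-analysis practitioners
working with µCT of rooted soil who want a scripted, reproducible, tested
version of this measurement chain.

## Worked example

```python
import rhizoct as rc

# a 3 mm cube of granular soil (10 % porosity) with one 500 µm root and a
# prescribed compaction halo: porosity deficit 0.10 decaying over 300 µm
config = rc.single_tube_config(
    shape=(160, 160, 160), seed=7,
    halo=rc.HaloParams(A_c=0.10, L_c=300.0),
)
gray, truth = rc.generate_phantom(config)

pipeline = rc.PipelineConfig(denoise=False, stride=1, edge_guard=False,
                             split_classes=False)
report = rc.analyze_volume(gray, pipeline).report

print(f"visible porosity : {report['visible_porosity']:.4f}")
print(f"Euler chi density: {report['euler_chi_density_per_mm3']:.1f} per mm^3")
print(f"root diameter    : {report['root_diameter_um']:.0f} um")
print(f"root length dens.: {report['tube_length_density_mm_per_cm3']:.1f} mm/cm^3")
halo = report['profiles']['all']['halo_recovery']
print(f"compaction amplitude A_c: {halo['A_c']:.3f}   (true 0.100)")
print(f"decay length L_c        : {halo['L_c_um']:.0f} um  (true 300 um)")
```

prints

```
visible porosity : 0.1084
Euler chi density: 126.9 per mm^3
root diameter    : 498 um
root length dens.: 107.6 mm/cm^3
compaction amplitude A_c: 0.110   (true 0.100)
decay length L_c        : 275 um  (true 300 um)
```

The measured porosity includes the root (roots segment as pore, as in the
field protocol); the positive χ density says this repacked matrix is
dominated by isolated pores; and the fitted halo parameters recover the
prescribed compaction within their validated tolerances (amplitude ±0.02,
decay length ±20 %).  `docs/methods.md` explains each stage, the phantom
generator, and why the amplitude is read from the porosity profile but the
decay length from the gray-value profile.

The same chain is available as a CLI for TIFF stacks on disk:

```
rhizoct generate --out phantom.tif --shape 160 --halo-ac 0.10
rhizoct preprocess phantom.tif pre.tif --no-denoise
rhizoct pores pre.tif pores.tif
rhizoct tubes pores.tif tubes.tif
rhizoct profile pre.tif pores.tif tubes.tif profile.csv --stride 1
rhizoct fit profile.csv fit.json --root-diameter 500 --x-min 100
rhizoct run --config config.yaml        # everything in one go
```

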