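# trabkit

3D trabecular bone morphometry from CT volumes: automated region-growing
segmentation, structure parameters, synthetic validation phantoms, and
paired method-agreement statistics.

Trabecular bone — the spongy network of rods and plates inside vertebrae
and the peripheral skeleton — carries much of what determines bone
strength beyond mineral density. Its microstructure can be measured ex
vivo by micro-CT and in vivo by HR-pQCT or other clinical CT devices, but
clinical resolutions (60–80 µm voxels) approach the thickness of the
trabeculae themselves, so segmentation and the partial-volume effect
dominate measurement quality. `trabkit` is for researchers comparing bone
microstructure across scanners or software: it provides a
segmentation-to-statistics pipeline whose every stage is testable against
phantoms with analytic ground truth.

## What it computes

Given a grayscale volume with isotropic voxel spacing and a binary VOI
mask delineating the trabecular compartment (cortical bone excluded):

1. **Segmentation** — automated region growing (ARG): bone and background
   are grown from intensity-extreme seeds under a homogeneity threshold
   *t* (a voxel joins a region when its intensity is within *t*·σ_VOI of
   the running region mean); the procedure is repeated over an increasing
   threshold schedule, starting from deliberate under-segmentation, and
   the iteration where both phases are jointly most homogeneous is
   selected. Otsu thresholding is available for high-CNR data, and the two
   agree voxel-for-voxel on cleanly separable volumes.
2. **Morphometry** — nine parameters plus CNR per volume:
   BV/TV (bone volume fraction); Tb.Th, Tb.Sp, Tb.Sc (mean trabecular
   thickness, edge-to-edge separation and midline-to-midline spacing, in
   mm, from maximal-inscribed-sphere local maps) with their intra-volume
   dispersions s(Tb.Th), s(Tb.Sp), s(Tb.Sc); Tb.Nd and Tb.Tm (skeleton
   intersections and free ends per mm³, from a topology-preserving 3D
   thinning that keeps plate mid-surfaces as well as rod mid-curves); and
   CNR = (skeleton mean − background mean)/background SD.
3. **Statistics** — per-parameter paired comparison of two devices:
   Pearson r with Fisher-z 95% CI (`tanh(atanh r ± 1.96/√(n−3))`), R² and
   p; Bland–Altman bias with 95% limits of agreement (bias ± 1.96 SD of
   differences) and proportional-bias regression; paired t-tests with CIs
   of the mean difference.
4. **Phantoms** — plate stacks, rod lattices and three-axis rod grids with
   analytic truth, plus a scanner-degradation chain (Gaussian PSF,
   resampling, additive noise calibrated to a target CNR) and a paired
   in-silico cohort generator.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Measure a noisy plate phantom (plates 0.2 mm thick at 1.0 mm pitch,
0.05 mm voxels, noise calibrated to CNR 10):

```python
import numpy as np
import trabkit as tk

spec = tk.PhantomSpec(kind="plate_stack", pitch_mm=1.0, element_width_mm=0.2,
                      extent_mm=(4.0, 4.0, 4.0), base_spacing_mm=0.05)
volume, truth = tk.make_phantom(spec)
voi = tk.MaskVolume(np.ones(volume.shape, bool), volume.spacing_mm)

sd = tk.noise_sd_for_cnr(volume, voi, target_cnr=10.0, bone=truth.bone)
noisy = tk.degrade(volume, tk.DegradationSpec(noise_sd=sd,
                                              target_spacing_mm=0.05, rng_seed=1))

result = tk.analyze(noisy, voi, method="arg")
for k, v in result.as_row().items():
    print(f"{k:>9s}  {v:.3f}")
```

prints

```
     BVTV  0.200
    Tb.Th  0.200
 s(Tb.Th)  0.000
    Tb.Sc  0.962
 s(Tb.Sc)  0.081
    Tb.Sp  0.787
 s(Tb.Sp)  0.062
    Tb.Nd  0.062
    Tb.Tm  0.000
      CNR  10.005
```

BV/TV and Tb.Th are recovered exactly (truth 0.2 and 0.2 mm); Tb.Sp and
Tb.Sc are within one and two voxels of the 0.8 and 1.0 mm truth; a uniform
plate stack has near-zero thickness dispersion and essentially no skeleton
intersections or free ends; the measured CNR sits at the calibrated 10.

The same pipeline is available from the shell:

```sh
trabkit phantom --kind plate_stack --extent-mm 4 --out-dir ph/
trabkit analyze ph/phantom.mha --mask ph/phantom_truth_mask.mha --method otsu --out-dir out/
trabkit compare reference.csv test.csv --out-dir tables/
```

`analyze` writes one CSV row per volume (columns BVTV, Tb.Th, s(Tb.Th),
Tb.Sc, s(Tb.Sc), Tb.Sp, s(Tb.Sp), Tb.Nd, Tb.Tm, CNR); `compare` joins two
such CSVs by specimen ID and emits correlation, descriptive and t-test
tables plus Bland–Altman and scatter plots. Volumes are read and written
as NIfTI, MetaImage or TIFF stacks (TIFF needs `--spacing-um`).

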