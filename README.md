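# canopylidar

Plot-level canopy trait analysis from field-scale LiDAR point clouds of
cereal trials.

Mobile (e.g. backpack) LiDAR can map a multi-hectare wheat trial in minutes,
producing tens of millions of 3D points — but turning that cloud into
per-plot, per-variety numbers a breeder can rank is the hard part.
`canopylidar` implements that analysis end to end:

1. **Denoise** — statistical outlier removal: a point is discarded when its
   mean distance to its k nearest neighbours exceeds avg + k·std of those
   per-point means over the whole cloud.
2. **Ground filter + normalization** — classify ground vs. above-ground
   returns, flatten the terrain (slopes removed by TIN interpolation of the
   local ground surface), leaving ground at z = 0 and canopy heights in cm.
3. **Canopy height model (CHM)** — rasterize the normalized canopy by
   TIN interpolation at 1 cm/pixel and encode it to 8-bit grayscale
   (0 cm → black, 160 cm → white).
4. **Plot segmentation** — adaptive thresholding, Sobel + Hough detection of
   the inter-plot gap lines, line merging, lattice assembly (optionally
   assisted by a known row × column layout), and entropy-weighted sampling
   windows.
5. **Traits per plot** — height H₁₀ (mean of the highest 10% of points),
   canopy coverage from the overhead projection of the highest 50% (H₅₀),
   3D canopy surface area from an alpha-shape mesh over down-sampled voxels,
   and the voxel biomass indices 3DVI / 3DPI.
6. **Spectral canopy-structure index (3DCI)** — the plot CHM's 2D DFT
   log-magnitude spectrogram is sampled along its diagonal, a Gaussian
   A·exp(−(x−μ)²/2σ²) is fitted, the trapezoidal area under the fitted curve
   on [−100, 100] accumulates canopy spatial variation, and areas are
   min–max normalized over a cohort with the band stretched to
   [0.593·min, 1.294·max] so every index falls strictly inside (0, 1).
   The curve's apex curvature, κ = A/σ² for the fitted Gaussian, indexes
   canopy density.
7. **Nitrogen-response analytics** — classify varieties into four N-response
   patterns from their 3DCI at low/medium/high N, and rank varieties in a
   performance matrix: per-trait percentage deviation from the trimmed mean,
   banded into ranks 1–5 (±7.5% / ±15% boundaries; height penalized
   symmetrically), combined with weights GN 0.25, SN 0.25, 3DCI 0.2,
   surface 0.2, height 0.1.

A synthetic-field generator (`canopylidar.synthfield`) produces labelled
point clouds of drilled plot trials — sloped noisy terrain, drill-row
structure, spike-scale height texture, controllable coverage — with exact
per-plot ground truth, so the whole pipeline is testable without field data.

## Worked example

```python
from canopylidar import cloudio, run_pipeline, RunConfig
from canopylidar.synthfield import FieldLayout, CanopySpec, TerrainSpec, generate_field
from canopylidar.preprocess import DenoiseParams

layout = FieldLayout(n_plot_rows=2, n_plot_cols=2, margin=0.5)
specs = [CanopySpec(mean_height=h, height_sd=3.0) for h in (70, 85, 90, 75)]
cloud, truth = generate_field(layout, specs, TerrainSpec(slope_x=0.01), seed=21)
cloudio.write_cloud(cloud, "field.las")

result = run_pipeline(RunConfig(
    input_path="field.las", output_dir="out",
    denoise=DenoiseParams.for_density(1500),
))
print(result["traits"][["plot_row", "plot_col", "height_h10", "coverage",
                        "curve_auc", "dci_3d"]].round(3).to_string(index=False))
```

prints

```
 plot_row  plot_col  height_h10  coverage  curve_auc  dci_3d
        0         0      73.818     0.471   1576.341   0.574
        0         1      88.766     0.465   1558.786   0.558
        1         0      93.790     0.471   1597.695   0.592
        1         1      78.710     0.462   1543.771   0.545
```

The four plots were generated with mean canopy heights 70/85/90/75 cm.  H₁₀
sits a few cm above each mean because it averages the top decile of a
textured canopy.  Coverage ≈ 0.47 is the overhead footprint of the H₅₀
(spike-layer) points, which concentrate on the drill rows — roughly half of
each plot at the generator's defaults.  The 3DCI column is the
cohort-normalized area under each plot's canopy structural curve; with the
same height texture in every plot the four values are, as they should be,
close together.  The same run writes `out/traits.csv`, `out/plots.csv`, a
processed LAS, and a JSON-lines log of every stage.

The same pipeline is available from the shell:

```bash
canopylidar synth --rows 2 --cols 2 --seed 21 --out field
canopylidar run-all field.las --out out --layout 2 2
```

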