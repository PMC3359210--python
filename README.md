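# entroseg

Automated quantification of stain levels in microscopy images, built
for experiments that compare cell-replication activity across
conditions with fluorescent live-cell imaging, and for nuclear
segmentation in immunohistochemistry (IHC) tissue images.

The number of cells captured in a field changes with the microscope's
sampling location, so summed intensities or positive-pixel counts are
not comparable between images. `entroseg` instead:

1. **separates stains** by colour deconvolution — under the
   Lambert–Beer law the optical density $D = \ln(I_0/I_1)$ of each RGB
   channel is linear in stain amount, so with unit stain OD vectors
   stacked into a matrix $A$, a pixel's concentrations are
   $C = D A^{-1}$;
2. **segments cells (or nuclei)** with unsupervised maximum-entropy
   thresholding — the cut-off $j^*$ maximises the Kapur criterion, the
   sum of Shannon entropies of the two renormalised class histograms;
   for IHC a multistage variant first stratifies the image into eight
   entropy-derived layers, thresholds the layer histogram, and cleans
   the mask with a radius-3 majority filter;
3. **scores each image** as the mean stain magnitude over the
   segmented foreground, $s = \frac{1}{|F|}\sum_{(m,n)\in F}\mu(m,n)$
   — invariant to how many cells the field contains;
4. **compares groups** of per-image scores with one-way ANOVA and
   Tukey HSD / LSD post-hoc tests.

A synthetic-data module generates fluorescence fields and IHC
composites with exact ground-truth masks and scores, so the whole
pipeline is testable end to end. See `docs/methods.md` for the model
details and design choices.

## Worked example

Score three synthetic cohorts (low / mid / high stain level, three
images each with different cell counts) and test the group means:

```python
from entroseg import (FluorFieldSpec, PipelineConfig, make_fluor_field,
                      run_pipeline, multiple_comparisons, format_p)

config = PipelineConfig.for_mode("live-cell")
groups = {}
for label, mean in (("low", 30.0), ("mid", 60.0), ("high", 90.0)):
    fields = [make_fluor_field(FluorFieldSpec(stain_mean=mean,
                                              n_cells=10 + 5 * i, seed=40 + i))
              for i in range(3)]
    table, masks = run_pipeline([f.image for f in fields], config)
    groups[label] = table["score"].tolist()
    print(label, [round(s, 2) for s in table["score"]])

anova, pairs = multiple_comparisons(groups)
print(f"F({anova.df_between},{anova.df_within}) = {anova.f_statistic:.2f}, "
      f"p = {format_p(anova.p_value)}")
for c in pairs:
    print(c.group_i, c.group_j, round(c.mean_diff, 2),
          format_p(c.p_lsd), format_p(c.p_tukey))
```

prints

```
low [137.94, 138.13, 139.24]
mid [149.47, 150.69, 152.34]
high [163.2, 164.37, 166.44]
F(2,6) = 294.66, p = < 0.001
low mid -12.4 < 0.001 < 0.001
low high -26.23 < 0.001 < 0.001
mid high -13.84 < 0.001 < 0.001
```

Scores within each cohort are tight despite 10–20 cells per image
(cell-count invariance), strictly ordered across stain levels, and the
ANOVA plus both post-hoc tests call every pairwise difference
significant — the behaviour the score is designed for.

The same flow from the shell:

```sh
entroseg synth fluor --n 3 --seed 40 -o fields/
entroseg pipeline fields/*.png --mode live-cell -o out/
entroseg compare-groups out/scores.csv -o report.json
```

Other subcommands: `segment` (write a mask for one image, live-cell or
IHC mode), `quantify` (score an image against a mask), `evaluate`
(pixel precision/recall against a ground-truth mask).

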