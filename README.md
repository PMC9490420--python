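# tendonquant

Quantitative histomorphometry for developing tendon sections — built around
the measurements used to follow chick jaw-tendon maturation from embryonic
day 9 to 19, and usable for any calibrated RGB histology where the same
quantities matter:

- **Cell density and nuclear shape** (H&E): colour-deconvolve the
  hematoxylin channel, segment nuclei, report nuclei/mm², aspect ratio
  AR = major/minor axis, and circularity = 4π·area/perimeter².
- **Collagen content and organization** (picrosirius red): percentage area
  fraction of PSR staining in brightfield and of birefringence under
  crossed polarizers, at one frozen threshold per metric for a whole batch.
- **Collagen fiber maturity** (polarized PSR): a per-pixel classifier —
  collagen-rich mask at `I_R + I_G + I_B ≥ 140`, then red/mature if
  `I_R/I_G ≥ 1.8`, green/immature if `≤ 1.1`, yellow/intermediate between —
  with a calibration routine that derives the two limits from ≥ 10 labeled
  pixels per class.
- **DAB immunohistochemistry** (TNC, COL3, LOX, MMP2, MMP9, ...): H-DAB
  separation and DAB-positive percentage area at a frozen per-target
  threshold.
- **Statistics**: technical replicates (three 60 × 60 µm ROIs per section)
  averaged into biological replicates; per metric, one-way ANOVA + Tukey
  after a normality gate, Kruskal–Wallis + Dunn/Holm otherwise, α = 0.05.
- **Synthetic phantoms**: seeded H&E / polarized-PSR / DAB fields with
  exact ground truth (counts, class maps, positive masks) and a d9–d19
  stage series that emulates the reported developmental trends, so every
  measurement is validated by parameter recovery.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Generate a three-stage phantom study (3 biological × 3 technical replicates
per stage and modality) and run the full pipeline:

```sh
tendonquant simulate scratch/demo --stages 9,13,19 --base-seed 42
# wrote 81 images under scratch/demo
```

```python
from tendonquant.pipeline import RunConfig, run_study

res = run_study(RunConfig(manifest="scratch/demo/manifest.csv",
                          out_dir="scratch/demo_run"))
print(res.biological.groupby(["metric", "stage_day"])["value"]
      .mean().unstack().round(2))
```

```text
stage_day                     9        13       19
metric
birefringence_pct          69.73    67.99    65.30
cell_density_per_mm2     2034.51  2543.13  1668.29
dab_DAB_pct                 9.53    38.75    10.32
immature_green_pct         82.33    29.01     7.46
intermediate_yellow_pct    17.67    51.90    22.62
mature_red_pct              0.00    19.09    69.92
nuclear_aspect_ratio        1.28     1.61     2.74
nuclear_circularity         1.09     1.03     0.82
```

The pipeline recovers the generator's developmental story: cell density
peaks at d13 and then falls, nuclei elongate monotonically (AR 1.28 → 2.74,
circularity 1.09 → 0.82), immature green collagen gives way to mature red
(0% at d9 → 69.9% of collagen-rich pixels at d19), and the COL3-like DAB
signal peaks mid-series. The between-stage tests land on the parametric
branch, e.g. for cell density:

```text
cell_density_per_mm2 anova stat=51.81 p=0.000164
  (13 vs 19, p_adj=0.0001, significant)
  (13 vs  9, p_adj=0.0026, significant)
  (19 vs  9, p_adj=0.0128, significant)
```

Single images work too:

```sh
tendonquant measure scratch/demo/images/TmAM_d13_N1_n1_psr_pol.tif --modality psr_pol
```

```json
{
  "birefringence_pct": 35.064697265625,
  "green_pct_mask": 29.8543900950388,
  "yellow_pct_mask": 52.2364635103322,
  "red_pct_mask": 17.909146394629
}
```

(here the default threshold 128 was applied; pipeline runs freeze an
Otsu-derived level per batch instead). Other subcommands: `run` (YAML
config), `calibrate` (maturity limits from labeled pixels), `stats`
(tests on an existing study table CSV).

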