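# Methods

`tendonquant` quantifies developing-tendon histology from calibrated RGB
micrographs: cell density and nuclear shape from H&E sections, collagen
content/organization/maturity from picrosirius-red (PSR) sections, and
protein distribution from DAB immunostains, followed by a replicate-aware
statistical workflow. This note records the models, the defaults and why,
the numerical choices, and what the synthetic phantoms do and do not show.

## Stain separation

Brightfield absorption follows Beer–Lambert: per-pixel optical density
`OD = -log10((I + ε)/255)` with `ε = 1/255` guarding zeros (white → OD ≈ 0,
black → OD ≈ 2.4, finite). A stain pair is a 3×3 matrix of unit-norm OD
direction vectors (rows: stain 1, stain 2, residual completed by rectified
cross product); concentrations are the OD vector times the matrix inverse,
with negative values clipped to zero afterwards because concentrations are
physical. Default vectors are the published Ruifrok–Johnston H&E and H-DAB
values — the same ones the common Fiji presets ship — and can be replaced
from a JSON/YAML config when a slide set was scanned under different
staining.

Numerical note: the inversion is exact on float OD (round trip to machine
precision, `deconvolve_od`), while going through an 8-bit image bounds
agreement at the quantization step (≈1e-2 in concentration for typical OD);
both paths are tested at their own tolerance.

## ROIs

All measurements are made in named, same-size, pairwise non-overlapping
rectangles, by design three 60 × 60 µm squares per section placed along the
tendon mid-portion (technical replicates). Placement is anatomical judgment
and comes from the user (CSV/JSON of centers); the package converts the
physical edge to pixels (round-half-away-from-zero), validates bounds and
overlap exactly on half-open integer rectangles, and crops without
resampling. Phantom datasets emit one ROI-sized field per image, so there
the full frame is the ROI.

## Nuclear morphometry

The hematoxylin concentration channel is smoothed (Gaussian, σ = 1 px),
thresholded (Otsu by default; a fixed OD level is available), connected
components are filtered to 5–500 µm² and optionally split by a
distance-transform watershed. A user-supplied label map bypasses all of
this, mirroring manual outlining. Per nucleus: area = pixel count × (µm/px)²;
major/minor axes from the moment-equivalent ellipse; aspect ratio AR =
major/minor (≥ 1 by construction); circularity = 4π·area/perimeter².
Density is nuclei per mm² with the centroid-in-ROI counting rule, which
makes counts additive over an ROI partition.

Perimeter estimator: plain pixel-boundary counting biases circularity of a
digital circle low by ~15%, and the common weighted chain-code and Crofton
estimators each fail either the circle or the square. We use the
marching-squares 0.5-level contour whose vertex polygon is smoothed with a
circular 5-point moving average before summing segment lengths: a radius-50
circle measures circularity 0.994, a 100-px square 0.800 (ideal π/4 ≈
0.785), an 80:20 ellipse AR 4.03. Objects under 5 px are counted but
excluded from shape metrics. Circularity of very small digitized shapes can
slightly exceed 1; values up to 1.1 are accepted.

## Collagen content and organization

Content (brightfield PSR): OD projected onto a PSR-like stain direction,
scaled to 8 bits against a fixed OD ceiling of 1.5 (not per-image min-max —
per-image scaling would silently break threshold comparability across
stages), thresholded, percent positive area reported with exact integer
counts. Organization (polarized light): luminance of the polarized frame,
same thresholding machinery. One threshold per metric is frozen for an
entire batch (all replicates, all stages) and echoed to the run log; the
default strategy computes Otsu on a designated reference image and freezes
that level, a deterministic surrogate for the study's single manual choice.

## Fiber maturity classification

Per pixel of the polarized PSR image: a net-intensity mask
`I_R + I_G + I_B ≥ 140` (inclusive) selects collagen-rich pixels; within the
mask the red/green ratio classifies red/mature at `I_R/I_G ≥ 1.8`,
green/immature at `≤ 1.1`, yellow/intermediate strictly between. The four
classes (including "excluded") partition every 8-bit triplet exactly and
fractions sum to 100% identically. Edge semantics are inclusive on all
printed inequalities. `I_G = 0` with `I_R > 0` leaves the ratio undefined;
the default treats it as +∞ → red (a pure-red pixel is maximally
red-shifted), configurable to "excluded". `I_G = I_R = 0` with high blue is
classed green (no red shift at all). Both ROI-relative and mask-relative
fractions are reported; the mask-relative numbers are the headline because
the mask is what defines the collagen-rich region. The limits can be
re-calibrated from ≥ 10 labeled pixels per class: each limit is the
midpoint between adjacent class ratio ranges, and overlapping ranges are an
error rather than silently averaged.

## DAB immunohistochemistry

H-DAB separation, DAB channel scaled by the same fixed OD ceiling,
thresholded at one frozen level per protein target. Because separation
isolates the DAB vector, the measured fraction is insensitive to
hematoxylin counterstain strength (verified within 1 percentage point on
phantoms).

## Statistics

Technical replicates are averaged into one value per biological replicate
(missing values dropped with a warning; deviation from the n = 3 design
warns but does not fail). Between-stage comparison per metric and tendon:
D'Agostino–Pearson normality per group, then one-way ANOVA with Tukey HSD
(Tukey–Kramer under unequal sizes) if no group rejects, otherwise
Kruskal–Wallis with Dunn's z-tests and Holm adjustment. α = 0.05. The Dunn
post hoc is an implementation choice and reports flag it as such.

The D'Agostino–Pearson omnibus statistic is only defined for n ≥ 8, while
tendon studies of this design run N = 3–6 embryos per stage. Groups too
small to test are recorded as `too_small` and treated as "cannot reject
normality", keeping the parametric branch reachable at realistic replicate
counts; groups under n = 3 force the non-parametric branch. The branch
taken, per-group outcomes and notes are part of every report, so the
decision path is reproducible from the output alone. Under the null
(3 Gaussian groups, N = 4, 1000 replicates) the empirical type-I error of
the workflow is within 0.05 ± 0.02 (checked in the acceptance suite).
Degenerate inputs: all-constant groups return H = 0 / p = 1; zero
within-group variance in Tukey yields p = 0 for unequal means and p = 1 for
equal means instead of NaN.

## Synthetic phantoms

No raw slide scans accompany the study design, so validation runs on seeded
phantoms that carry exact ground truth:

- **Nuclei fields**: the count is fixed at `round(density × area)` before
  placement, so density ground truth is exact; ellipses (area ~
  N(40, 8²) µm², AR ~ N(ar_mean, 0.2²) truncated at 1, uniform orientation)
  are placed by rejection sampling with non-overlapping bounding circles
  (2 px clearance, budget 100 attempts per nucleus; exceeding it raises
  with the achievable density). Hematoxylin OD 0.8 over eosin background
  OD 0.15, composed through the same H&E matrix the separation inverts.
- **Fiber fields**: class pixel counts are exact by largest-remainder
  rounding; classes are laid out along a smooth oriented noise field for
  fiber-like texture (cosmetic — class is encoded only in net intensity and
  R/G ratio). Each pixel's integer RGB is constructed, then nudged by ±1
  where rounding would cross a class boundary, so the generated class map
  is recovered by the classifier exactly. Background pixels are capped
  strictly below the net-intensity mask.
- **DAB fields**: an exact-count positive mask (top-k of a smoothed noise
  field) at OD 0.8 over hematoxylin 0.3, optional Gaussian OD noise.
- **Stage series**: d9–d19 with N = 3 biological × n = 3 technical fields
  per stage and modality, 128×128 px at 1 µm/px by default (phantom runs in
  tests use 96×96 px fields). Per-stage parameters follow the reported
  qualitative directions — density 1800 → 2600 (peak d13) → 1600 /mm²;
  AR 1.3 → 3.0 monotone; green 55 → 5%, yellow peaking 35% at d13, red
  0 → 47% of fiber pixels; a COL3-like DAB fraction peaking at d13 — with
  magnitudes chosen as plausible for embryonic tendon, since the source
  results exist only graphically. Inter-embryo variability is emulated by a
  per-biological-replicate multiplicative jitter (CV 8%, clipped to
  [0.5, 1.5]) on density, AR and stain fractions — without it every
  replicate of a stage would measure identically (counts are exact by
  construction) and the within-stage variance feeding the ANOVA would be
  zero. Technical replicates of one embryo share the jitter but not the
  placement seed. Per-image and per-embryo seeds derive from the base seed
  by CRC-32 of the ID tuple, so datasets are bit-reproducible image by
  image.

What passing on phantoms does **not** show: robustness to real-slide
variability — uneven staining, folds, debris, out-of-focus regions,
touching/overlapping nuclei at high density, polarization artifacts, and
stain vectors that drift from the published values. The phantoms validate
the measurement arithmetic and the pipeline plumbing, not slide QC.

## Problem sizes

Default validation sizes were chosen to keep recovery statistically crisp:
512×512 px at 1 µm/px (≈ 0.26 mm²) for density recovery (500–3000 /mm²
within 10%), 100×100 px fiber fields for exact fraction recovery, 200×200
px DAB fields, five-seed stage series of 96×96 px fields for trend-sign
checks, 1000-replicate null simulations for test calibration.
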