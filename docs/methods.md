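# Methods

This note records the models, defaults and numerical choices behind
`padcyto`, and what the synthetic-data validation does and does not show
about real microscopy data.

## The conservation model

The core assumption is that a cell in G0/G1 holds a fixed amount *A* of
constitutive pericentric heterochromatin and redistributes it among *n*
chromocenters (PADs) by fusion and splitting.  Consequences used
throughout:

- mean PAD area = *A*/*n*, so count vs mean area is a power law with
  exponent −1 and 1/*n* is linear in √(mean area) (a linear-size proxy);
- individual PAD sizes have a broad, decreasing, exponential-like spectrum
  with no characteristic size;
- centromere count per PAD grows with PAD area (clustering), since each
  PAD carries at least one centromere.

The synthetic generator encodes exactly this structure; the fits in
`padcyto.scaling` measure it.

## Synthetic-data generator

Defaults are chosen to mimic serum-starved G0/G1 populations of an
epithelial cell line:

| parameter | default | rationale |
|---|---|---|
| `total_pad_area` | 16 µm² | conserved per-cell heterochromatin amount; with counts of 6–16 this gives mean PAD areas of 1–2.7 µm², matching the observed range |
| `count_law` | uniform {6..16} | the bulk of per-cell chromocenter counts in starved controls |
| `area_cv` | 0.1 | cell-to-cell spread of the conserved total; no published value exists, 10% is a realistic biological CV (setting 0 gives exact conservation) |
| `dirichlet_alpha` | 1.0 | symmetric stick-breaking concentration; α=1 gives a broad, scale-free-like fragment spectrum, larger α gives more even fragments |
| `centromere_density` | 1.0 /µm² | one centromere per µm² of PAD, ≥1 per PAD; yields clusters of >6 centromeres only in the largest PADs |
| `dna_class_probs` | 0.85 / 0.10 / 0.05 | 2C / S-G2 / preapoptotic mixture typical of a starved, mostly G0/G1 population |
| `px_per_um`, `image_size` | 8 px/µm, 192 px | epifluorescence-like sampling; one nucleus (radius ~5.5 µm) per field |
| `noise_sd` | 2.0 | Gaussian read noise, ~1% of the chromocenter peak amplitude |

DNA classes scale the DAPI base intensity (100 for 2C, 200 for S-G2 since
DNA has doubled, 65 for preapoptotic cells, which also aggregate their
chromocenters into 1–3 large PADs).  The DAPI channel additionally carries
10% of the chromocenter signal as DNA-dense excess.

**Rendering.**  Chromocenters and centromere foci are Gaussian-profile
discs whose half-maximum contour equals the true radius (σ = r/√(2 ln 2)).
Two choices make noise-free recovery *exact* rather than approximate:
profiles are truncated at 1.4 r, and rejection-sampled placement keeps
centres at least 1.25 (r_i + r_j) + 2 px apart (1.5 scale for foci).
Together these guarantee that no blob's tail can lift any pixel outside
another blob above half maximum, so thresholding at half max separates
every object.  Placement is retried up to 500 times per disc with up to 20
whole-set restarts; an infeasible configuration raises `PlacementError`
rather than silently overlapping objects.

**Randomness.**  One root `SeedSequence(seed)` is spawned once per cell
(per plate section for qPCR, with fixed stream tags for the AO,
heterogeneity and plate generators), so output is bit-identical for a
given seed and adding cells never perturbs earlier ones.

**AO populations.**  Per-nucleus R/G is lognormal with mean
`control_rg × shift_factor` and SD `control_rg × noise_sd` (the SD is
specified on the control-normalised scale, as population spreads are
reported).  Fields are uniform ellipses whose red plane is the green plane
times the per-cell R/G, so measured ratios equal the drawn values exactly
at zero pixel noise.

**Heterogeneity textures.**  A requested fraction of in-mask pixels is
displaced ±25% from the mean (balanced up/down so the mean is preserved);
the measured >10%-deviation fraction equals the target to within one
pixel's weight.

**qPCR plates.**  CT = baseline − log2(expression) + N(0, σ²) per well;
reference genes vary across samples with a specified SD of log2
expression.  Fold changes are recovered unbiased on the log2 scale because
ΔΔCT is a linear combination of Gaussian terms.

**What the generator does not emulate:** optics (no PSF, no chromatic
shift, no uneven illumination), 3-D structure (single plane only),
nucleoli and chromosome territories, autofluorescence background, touching
nuclei, or photobleaching.  Passing the recovery tests therefore shows the
*measurement* chain is correct, not that segmentation thresholds are
optimal for any particular microscope; on real data the exposed thresholds
in `QuantConfig` will need tuning per acquisition setting.

## Cytometry choices

- Original measurements of this kind are made on interactively drawn
  contours; here all contours are automatic for reproducibility: Otsu on
  the Gaussian-smoothed (σ = 0.25 µm) DAPI channel for nuclei, and a
  fraction-of-maximum threshold (default 0.5, matching the generator's
  soft-edged foci) or percentile threshold for the red/green channels.
- Connected components use 8-connectivity; coordinates are pixel-centred,
  0-based, row-major; areas convert via `px_per_um²`.
- PAD components below 0.2 µm² are discarded — the finest unit resolvable
  in the confocal size spectra this limit is taken from.
- The 2C gate is modal IFI × [1−w, 1+w] with w = 0.25 (no published window
  exists; ±25% comfortably contains the 2C spread at realistic nuclear
  size variation while excluding doubled S-G2 signal).  The mode is the
  tallest peak of a Gaussian KDE.  Preapoptotic labelling requires both
  sub-window IFI and a top-quartile mean PAD area (chromocenter
  aggregation with DNA loss); low-IFI cells without aggregated PADs stay
  unassigned.  Fewer than 20 cells: no gating, all unassigned.
- The heterogeneity statistic uses a strict inequality ("more than 10%"):
  pixels deviating exactly 10% do not count.  A zero-mean field is defined
  as perfectly homogeneous.  The statistic is invariant under global
  intensity scaling and non-decreasing as the tolerance shrinks.

## Fitting choices

- Power laws are fitted by OLS of log10 y on log10 x over raw points;
  exponential size spectra by OLS of ln(count) on bin centre over
  non-empty equal-width bins on (0, 6 µm²] (20 bins by default, the cap
  reflecting that the spectrum is dominated by PADs below 5–6 µm²).  The
  regression approach (rather than maximum-likelihood tail estimation) is
  deliberate: the claims being reproduced are regression-based, and R² is
  reported on the fitted scale, as regression software reports it for
  linearised fits.
- Non-positive values are excluded before any log transform, with counts
  logged; fewer than 3 surviving points (or non-empty bins) is an error.
- R² is defined as 1 − SSR/SST and set to 0 when SST = 0 (constant
  response); a zero-variance predictor is an error.
- The centromere-clustering comparison fits both a linear and an
  exponential model to PADs with ≥1 centromere and reports both R² values;
  all-equal counts make the exponential fit degenerate (flagged, R² = 0).

## Statistics choices

- Group comparisons use Welch's unequal-variance t-test (two-tailed); with
  only "t-test" specified by convention, Welch is the safer default.  The
  summary-statistics path uses the same formulas (verified to equal the
  raw-data path and an independent numerical integration of the t
  density).  Both SDs zero degenerates to p = 1 (equal means) or p = 0
  with a flag.
- Benjamini–Hochberg adjustment delegates to
  `statsmodels.stats.multitest.multipletests('fdr_bh')` behind a
  validating wrapper; the test suite pins it to a literal step-up
  implementation on fuzzed inputs.  All comparisons within one experiment
  form a single adjustment family.
- geNorm M is the published pairwise-variation definition reimplemented on
  the CT scale (log2(Q_j/Q_k) = CT_k − CT_j); with exactly two candidates
  the two scores are identical by construction.
- qPCR replicates are averaged arithmetically on the CT scale before ΔCT;
  amplification efficiency is fixed at 2 (no efficiency correction).
  Two-gene reference schemes subtract the mean CT of the pair, which is
  identical to normalising relative quantities by their geometric mean.

## Problem sizes

Validation studies run at sizes chosen to make their Monte-Carlo error
small relative to the tested tolerances: 300-cell cohorts for scaling and
gate-fraction recovery, 400-cell AO populations (matching reported
per-time-point cell counts), 1000 simulated plates/families for bias and
type-I-error checks, and 40-cell rendered cohorts for exact-recovery
tests.  The conserved-area acceptance study uses the generator's ground
truth directly (no rendering), since its defining computation is on
fragment areas; the rendered path is validated separately by the recovery
suite.

## Known limitations

- Segmentation assumes well-separated nuclei; touching nuclei are flagged
  as oversized rather than split (no watershed).
- Centromere counting is centroid-containment only; a focus straddling a
  PAD boundary is assigned to at most one PAD, and foci merging closer
  than the resolution limit undercounts, as in real imaging.
- The exponential-spectrum fit treats bin counts as homoscedastic on the
  log scale; sparse tail bins therefore carry disproportionate weight at
  small sample sizes.
- The bimodality detector (KDE peak finding) is a reporting aid, not a
  calibrated test.
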