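# padcyto

Image cytometry of pericentromere-associated domains (PADs) — the
constitutive heterochromatin blocks, visible as H3K9me3-positive
chromocenters, that cluster centromeres in interphase nuclei.  The package
is aimed at quantitative cell biologists who need reproducible, scriptable
versions of the measurements usually done interactively in commercial
imaging software: per-nucleus DNA-content cytometry, chromocenter counting
and sizing, centromere-focus colocalisation, fluorescence-ratio imaging,
and the statistics that sit on top.

## What it computes

**Chromocenter cytometry.** Nuclei are segmented on the DAPI channel
(Otsu on a smoothed image); the integrated DAPI fluorescence intensity
(IFI) gates each cell into 2C, S-G2 or preapoptotic classes around the
modal IFI.  Chromocenters are connected components of the thresholded
H3K9me3 channel inside each nucleus; CENPA foci are counted per
chromocenter by centroid containment.

**Scale-free size–number fits.** When a cell redistributes a conserved
amount A of pericentric heterochromatin over n chromocenters by fusion and
splitting, the mean chromocenter area is A/n.  The package fits the
resulting laws with ordinary least squares on the appropriate scale and
reports R² on that scale:

- 1/n against √(mean area) — linear;
- count against mean area — power law (log–log), exponent −1 under exact
  conservation;
- the individual-size spectrum — exponential (log-linear on histogram
  bins);
- centromere count against PAD area — linear vs exponential model
  comparison.

**Acridine-orange R/G index.** Per nucleus, R/G = IFI_red / IFI_green of
the two AO emission planes; higher values mean a more unfolded DNA
conformation.  Populations are normalised to the control mean and compared
with two-tailed Welch tests, Benjamini–Hochberg adjusted within each
experiment.

**qPCR relative quantification.**  ΔCT = CT(target) − CT(reference),
ΔΔCT = ΔCT − ΔCT(control), RQ = 2^(−ΔΔCT); single-reference or two-gene
geometric-mean normalisation, plus the geNorm pairwise-variation stability
measure M.

**Synthetic data with ground truth.**  A seeded generator produces
three-channel nucleus fields with conserved per-cell chromocenter area
(symmetric Dirichlet stick-breaking), nested centromere foci, AO two-plane
populations with controllable shifts, heterogeneity textures with an exact
deviant-pixel fraction, and qPCR plates with known fold changes — so every
pipeline stage can be validated against known truth.

## Worked example

`examples/03_ao_shift.py` simulates a starving control and two treated
populations whose R/G distributions are shifted by factors 1.16 and 1.49,
then runs the full normalisation and testing pipeline:

```
normalised R/G (control mean = 1; higher = more unfolded DNA):
            ST: 1.00 +/- 0.15 (n = 400)
    HRG 20 min: 1.16 +/- 0.16 (n = 400)
    HRG 60 min: 1.50 +/- 0.17 (n = 400)

Welch tests, BH-adjusted within the experiment:
            ST vs HRG 20 min: t =  -14.76, adj. p = 9.71e-44
            ST vs HRG 60 min: t =  -45.08, adj. p = 2.25e-220
    HRG 20 min vs HRG 60 min: t =  -29.40, adj. p = 3.86e-129
```

The control mean is exactly 1 by construction; both treated groups are
shifted upward (more unfolded DNA) and every pairwise comparison is
significant far below α = 0.001.  `examples/02_scaling_fits.py` prints the
conserved-area scaling fits (power-law exponent −0.996, R² = 0.98 on a
406-cell cohort); the other examples cover segmentation recovery and qPCR.

## Command line

Each analysis is also a CLI verb over a YAML config:

```sh
padcyto simulate --seed 1 --outdir runs/sim      # fields + ground truth
padcyto pads     --seed 1 --outdir runs/pads     # cytometry + fits
padcyto ao       --seed 1 --outdir runs/ao       # R/G shift table
padcyto qpcr     --seed 1 --outdir runs/qpcr     # RQ + geNorm M
padcyto report   --seed 1 --outdir runs/all      # everything + report.json
```

Outputs are CSV/JSON (and TIFF for simulated fields); reruns with the same
config and seed are byte-identical.

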