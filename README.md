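# vertebrome

MicroCT phenomics of the adult zebrafish vertebral column.

Whole-body microCT makes the entire zebrafish spine — 22–28 vertebrae,
each with a centrum, a neural arch, and a haemal arch with pleural ribs —
accessible as a *spatially distributed* phenotype. Instead of measuring
one or two vertebrae deeply, `vertebrome` segments every vertebra
semi-automatically, measures 25 morphological and densitometric traits per
vertebra, and tests whether the *pattern* of a trait along the column
differs between groups. Pattern-level testing buys sensitivity: many
correlated vertebrae each carrying a small effect are jointly detectable
long before any single vertebra is. The package is aimed at skeletal
biologists running reverse-genetic screens or characterizing mutants
related to human bone disease, and at anyone who needs a reproducible,
scriptable replacement for manual spine segmentation.

## What it does

- **Volume I/O** (`vertebrome.volume_io`) — DICOM series in/out, raw
  intensity → tissue mineral density via the scanner calibration
  TMD = (x / 4096) · slope + intercept (mgHA/cm³; defaults
  slope = 281.706, intercept = −195.402), reorientation, projections.
- **Segmentation** (`vertebrome.segmentation`) — IsoData thresholding with
  a 0.73 correction factor; user seed lines between adjacent centra are
  extruded into separation planes and grown until the connected components
  on the two sides have distinct plurality components; each vertebra is
  then split into neural arch / centrum / haemal-arch masks (5-voxel
  centrum buffer by default); Dice coefficients for segmentation QC.
- **Morphometry** (`vertebrome.morphometry`) — per element and per
  vertebra: TMD, model-independent local thickness (largest inscribed
  sphere), volume, surface area, intra-specimen TMD/thickness variation,
  and centrum length — 4 × 6 + 1 = 25 measures per vertebra, written as
  tab-separated phenome tables.
- **Statistics** (`vertebrome.phenostats`) — the global test of vertebral
  patterns: for centered group-indicator residuals e and the fish ×
  vertebrae matrix X, the score statistic Q = eᵀXXᵀe / k is referred to
  its chi-square-mixture null (eigenvalues of the centered Gram matrix,
  Imhof inversion), with exact label-permutation as an option;
  per-vertebra covariate decomposition; skeletal-barcode standard scores;
  pairwise correlation profiling; Royston's multivariate-normality screen.
- **Allometry** (`vertebrome.allometry`) — power-law growth models
  y = a·xᵇ against standard length, normalization y* = y·(x*/x)ᵇ, tissue
  mineral content (TMC = Vol × TMD), and the two-step normalized TMD
  (normalize TMC and Vol independently, then divide).
- **Power simulation** (`vertebrome.powersim`) — Monte-Carlo
  sensitivity/specificity of the global test vs single-vertebra and
  averaged Welch t-tests, under multivariate-normal models estimated from
  control cohorts, with uniform or linearly ramped effect sizes d.
- **Phantoms** (`vertebrome.phantom`) — synthetic spine volumes (hourglass
  centra, dorsal/ventral arches, rib-bearing anterior vertebrae, Gaussian
  noise) with exact ground truth, so the whole pipeline is testable
  without scan data.

## Worked example

Generate a noisy 3-vertebra phantom, run the full pipeline, and estimate
test power:

```sh
$ vertebrome phantom --n 3 --noise 100 --seed 5 --out fish01
wrote 114 slices to fish01

$ vertebrome pipeline fish01 --seeds fish01/seeds.tsv --out fish01.txt --sl 24.0
wrote fish01.txt (3 vertebrae)
```

`fish01.txt` is a tab-separated table, one row per vertebra, with the 25
measures under their long column names (`CentrumTMDs`, `CentrumVolumes`,
…). The first centrum measures, for instance, come out at
Cent.TMD = 492.4 mgHA/cm³, Cent.Vol = 7.075 × 10⁷ µm³ and
Cent.Th = 70.2 µm — the phantom was designed with a centrum intensity
calibrating to 492.4 mgHA/cm³ and a 4-voxel (84 µm) wall, so density and
volume are recovered exactly and thickness to well within one 21 µm voxel.

```sh
$ vertebrome power --feature Tot.TMD --d 4 --n 3 --alpha 0.05 --sims 10000 --seed 1
procedure  n  alpha   d   shape  sensitivity  specificity
   global  3   0.05 4.0 uniform       1.0000       0.9475
 t_single  3   0.05 4.0 uniform       0.8879       0.9663
   t_mean  3   0.05 4.0 uniform       0.9997       0.9658
```

Read: with 3 fish per group and a uniform 4-SD shift in total vertebral
TMD, the pattern-level global test detects the mutant essentially always,
a t-test of a single vertebra only ~89% of the time, and all procedures
keep their false-positive rate near the nominal 5%. (Rates here are under
a synthetic wild-type model; `--control-dir` estimates the model from
your own control tables instead.)

Group comparison and allometric normalization:

```sh
vertebrome stats global-test wt_dir/ mut_dir/ --feature Cent.TMD --vertebrae 1:16
vertebrome allometry fit wt_dir/ --lengths lengths.tsv --out models.tsv
vertebrome allometry normalize wt_dir/ --lengths lengths.tsv --xref 20.2 --out-dir wt_scaled/
```

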