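# skelphen

Quantitative skeletal-phenotyping pipeline: biomechanical curve-feature
extraction, reference-cohort bone-quality SD-scoring, calibrated gray-level
mineralization densitometry with percent-scale Kolmogorov–Smirnov
comparison, ASBMR histomorphometry, and the accompanying statistics
(ΔΔCT expression, group comparisons, CV-based power analysis). Every input
the pipeline consumes can be generated synthetically with known ground
truth, so all stages are testable offline.

## Modules

| Module | What it does |
| --- | --- |
| `skelphen.synthetic` | Ground-truth generators: bilinear fracture curves (0.03 mm/s, 20 Hz), reference cohorts with a linear BMC→biomechanics relationship (BMC CV 2 %, max-load CV 9 %, fracture-load CV 20 %), mutant groups with injected residual-SD deficits, gray-level fields with calibration standards, histomorphometry trace tables. |
| `skelphen.biomech` | Yield / maximum / fracture load and stiffness from load–displacement curves (contact detection, anchored elastic-window search, offset yield rule, largest post-peak step drop). |
| `skelphen.quality` | Per-parameter OLS of biomechanics on BMC over a wild-type reference cohort; group scores in residual-SD units with a ±2 SD outlier band. |
| `skelphen.densitometry` | Affine gray→density calibration from standard-region medians; fixed-range 16-bin BMC and 8-bin qBSE mineralization histograms. |
| `skelphen.distcompare` | Two-sample KS on the percent scale with analytic critical values (6.01 / 7.20 / 8.62 at n₁ = n₂ = 1024 for α = 0.05 / 0.01 / 0.001). |
| `skelphen.histomorph` | Growth-plate zone heights; Oc.N/B.Pm, Oc.S/B.Pm; MS, MAR, BFR = (MS/100)·MAR; OS/B.Pm, O.Th; eroded surface. |
| `skelphen.stats` | ΔΔCT fold changes, ANOVA+Tukey / Kruskal–Wallis+Dunn / t / rank-sum dispatch, noncentral-t power and sample-size. |
| `skelphen.config`, `skelphen.pipeline`, `skelphen.cli` | Strict YAML/JSON config, end-to-end bundle runner with seed/config-hash provenance, `skelphen` CLI. |

## CLI

```bash
skelphen simulate curves --seed 1 --out sim/ -n 5     # synthetic inputs
skelphen biomech sim/curve_*.csv --out report.csv     # curve parameters
skelphen quality fit cohort.csv --out model.json      # reference regression
skelphen quality score hom.csv --model model.json --out scores.csv
skelphen densitometry sim/gray --mode qbse --out hist.csv
skelphen ks a.csv b.csv                               # percent-scale KS
skelphen histomorph section1.csv section2.csv --out histo.json
skelphen stats ddct ct.csv --reference-genes Tubulin,GusB --calibrator s0,s1 --out fold.csv
skelphen stats power --cv 0.1 --diff 0.2
skelphen run --seed 1 --out bundle/                   # full demo pipeline
```

`skelphen run` executes simulate → biomech → densitometry → KS → quality →
histomorphometry on synthetic data and writes a bundle directory whose
`summary.json` / `run.log` carry the seed, config hash and package
versions.

## File conventions

CSV/JSON throughout (UTF-8, explicit headers); curves as
`displacement_mm,load_N`; cohorts as
`specimen_id,genotype,sex,bmc,yield_load,max_load,fracture_load,stiffness`;
gray fields as 16-bit TIFF plus a JSON sidecar with 0-based half-open
region rectangles; histomorphometry sections as
`segment_id,length_um,flag,width_um,interlabel_um`. Lengths in µm,
perimeters in mm, loads in N, displacement in mm.
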