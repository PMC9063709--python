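# inflorascan

Image-based morphometrics and yield analytics for trimmed cannabis
inflorescences ("buds"), aimed at breeders and phenomics groups who screen
large clonal populations and need per-bud measurements at a scale hand
calipers cannot reach.

A plant's harvested inflorescences are spread on a contrasting board and
photographed once; from that single calibrated image the package computes,
per object:

* **IS** — inflorescence size (cm²), the pixel count times p_l², where p_l
  is the physical edge length of one pixel (cm/px);
* **IL, IW** — length and width (cm) of the *best-fit ellipse*, the ellipse
  whose second-order central moments match the object's:

      IL = 2√2 · √( (u₂₀ + u₀₂ + √((u₂₀ − u₀₂)² + 4u₁₁²)) / u₀₀ ) · p_l

  (IW with the inner root subtracted), with u_pq = Σ (xᵢ−x̄)ᵖ(yᵢ−ȳ)𐞥;
* **CH, HP** — convex hull area (cm²) and hull perimeter (cm), via Andrew's
  monotone chain and the shoelace formula;
* **ISH** — shape ratio IW/IL (1 = round, → 0 = elongated).

Segmentation uses the blue channel of the RGB image (plant matter reflects
little blue) with minimum-error (Kittler–Illingworth) thresholding, followed
by an area opening that deletes debris below 1 cm², and connected-component
labeling. Per plant, the package aggregates IN (inflorescence count) and
TIC = Σ IS (total inflorescence coverage, cm²), unifies fresh- and
dry-imaged plants through per-trait linear calibrations (trusted only when
R² > 0.9), and estimates broad-sense heritability from clonal replicates as
H² = V_G/(V_G + V_W) by one-way random-effects method of moments.

The yield layer apportions a plant's measured inflorescence dry biomass
(IDB, g) over its buds proportionally to area (density = IDB/TIC, g/cm²),
reports what fraction of buds carries 50/75/90% of the yield, and predicts
IDB from the mean width of the 20 longest buds via IDB = β₁·IW + β₀. The
published coefficients (β₁ = 59.14 g/cm, β₀ = −134.97 g, valid for mean
IW > 2.5 cm) ship as explicit defaults with a provenance tag — they are
environment-specific, and `refit_prediction` refits them on local data.

No study images are distributed; `inflorascan.synthetic` generates
ground-truthed scenes (superellipse buds with known axes) and clonal
populations (genotype × clone variance components, right-skewed bud sizes,
IDB ∝ TIC) on which every stage is tested end to end.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_yield_distribution_and_prediction.py` prints:

```
plant G001-1: IN = 220, TIC = 936 cm^2, IDB = 108.4 g
density = 0.116 g/cm^2; weights sum to 108.4 g (conserved)
  largest  23.2% of buds hold 50% of the yield
  largest  48.6% of buds hold 75% of the yield
  largest  72.3% of buds hold 90% of the yield

mean width of the 20 longest buds = 2.74 cm
published-coefficient prediction  = 27.3 g (IDB = 59.14*IW -134.97)
locally refitted line: IDB = 97.63*IW -163.04  (R2 = 0.40, n = 160)

caliper-survey stability (10 rounds each):
  measuring  5 of 20: subsample means 2.41-3.03 cm (max deviation 12.1%)
  measuring 10 of 20: subsample means 2.57-3.05 cm (max deviation 11.3%)
  measuring 15 of 20: subsample means 2.65-2.90 cm (max deviation 5.8%)
```

The first block says this plant concentrates half its 108 g yield in under a
quarter of its 220 buds — the practical case for picking large buds first.
The prediction block contrasts the shipped coefficients with a local refit,
and the last block shows how a caliper survey of only m of the 20 longest
buds degrades as m shrinks.

The command-line interface mirrors the library
(`inflorascan segment | measure | summarize | stats | yield | simulate |
montage | run`); `inflorascan run --config run.yaml` executes the whole
chain from photographs to analyses.

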