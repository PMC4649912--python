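# mirconcord

Cross-platform concordance analysis for microRNA qPCR panels, plus a
stochastic simulator of multi-platform qPCR measurement.

## The problem

Circulating microRNAs are attractive disease biomarkers (e.g. a 5-miRNA
panel for diabetic retinopathy), but validating a signature on clinical
samples means running many assays across many samples — which pushes labs
from the standard 5 µl 96-well qPCR plate toward high-throughput
microfluidic (1 µl cards) and nanoliter platforms (33 nl and 15 nl
arrays). Shrinking the reaction volume shrinks the expected number of
template copies per reaction: at low abundance the copy count per reaction
is Poisson, so at a mean of one copy per reaction about 37 % of reactions
receive *no* template at all, 37 % one copy and 18 % two. Replicate
variability and dropout therefore grow as volume falls, and platforms stop
agreeing exactly where biomarker panels live — at low copy number.

`mirconcord` packages the analyses needed to quantify this, for anyone
benchmarking qPCR platforms or validating a miRNA signature across them:

* **Replicate variability** — per-group CV% (100·sd/mean of replicate CTs,
  n−1 denominator), replicate range, expression tiers (ultra-high CT < 10,
  high 10–20, moderate 20–30, low > 30), and **fidelity scoring**: the
  percentage of replicate groups whose CT range stays under 1/2/3-cycle
  cutoffs (a 3-cycle spread ≈ 2³ = 8-fold in abundance).
* **Cross-platform concordance** — CT values are not comparable across
  platforms, so each platform is z-scored; ordinary least squares of a
  comparison platform on a reference ("gold standard") platform gives
  Pearson *r*, *R²* and the **compression slope**, whose deviation from the
  ideal slope of 1 measures dynamic-range compression.
* **Cluster concordance** — per-platform miRNA clustering with Ward
  linkage / Euclidean distance, cluster count by the **Mojena rule**
  (first fusion height above mean + 1.25·sd of all fusion heights),
  k-means refinement seeded at the Ward centroids, and a misassignment
  percentage after optimal one-to-one cluster matching between platforms.
* **Signature profiles** — radar (polygon) profiles of an ordered miRNA
  panel; polygon area ½·sin(2π/n)·Σᵢ rᵢ·rᵢ₊₁ and axis-wise shape
  correlation compare a signature's appearance across platforms.
* **Simulator** — Poisson copy partitioning at platform-specific reaction
  volume and dilution (λ = concentration · volume / dilution), deterministic
  pre-amplification gain, a log-linear CT model with Gaussian cycle noise,
  run-level shifts and a hard detection limit. Ground truth is recorded per
  reaction, so every analysis above can be validated against known answers.

## Worked example

```python
import mirconcord as mc

table, ledger = mc.simulate_study(mc.default_config(seed=42))

stats = mc.replicate_stats(table)
print(stats.dropna(subset=["cv_pct"]).groupby("platform")["cv_pct"].median())
```

```
platform
DA       6.93
OA       1.42
TLDA     5.47
ViiA7    0.58
```

Median replicate CV% rises from the 5 µl plate (ViiA7, 0.58 %) through the
33 nl array (OA, 1.42 %), the 1 µl card (TLDA, 5.47 %) and the 15 nl array
(DA, 6.93 %) — the same rank order real platform comparisons report.
Fidelity at the 1-CT cutoff falls the same way (100 % → 69 % → 5.7 % →
3.9 % here). Concordance against the reference platform:

```python
print(mc.concordance_table(table, "ViiA7"))
```

```
reference platform    n      r     r2  slope  intercept
    ViiA7       DA  168  0.995  0.991  0.995       -0.0
    ViiA7       OA  168  0.998  0.997  0.998       -0.0
    ViiA7     TLDA  168  0.997  0.994  0.997       -0.0
```

All 42 miRNAs × 4 samples match (n = 168 pairs per comparison); slopes just
below 1 indicate mild compression. Clustering each platform's z-scored
miRNA-by-sample matrix selects k = 4 via the Mojena rule and, on this
cleanly separated synthetic truth, assigns every miRNA to the same cluster
as the reference platform (0 % misassignment).

The same pipeline runs from the shell:

```sh
mirconcord simulate --seed 42 --out table.csv --truth truth.csv
mirconcord run --out study_out/          # full bundle + summary.json
mirconcord variability --input table.csv --out var/
mirconcord concordance --input table.csv --reference ViiA7 --out conc.csv
mirconcord cluster --input table.csv --reference ViiA7 --out clusters/
```

Real data enters through the same long CSV layout
(`platform,run,user,sample,mirna,replicate,ct`, with `Undetermined` for
dropouts); `read_ct_table` accepts a column-name mapping for other layouts.

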