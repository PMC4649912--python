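# Methods

## Data model

A study is a long table of reactions keyed by
(platform, run, sample, mirna, replicate) with a CT value or an
undetermined flag (NaN in memory). All analyses are pure functions of this
table; wide matrices are derived views. Determined CTs must be finite and
positive; duplicate keys are rejected at construction.

## Replicate variability

For each (platform, run, sample, mirna) group — runs pooled only on
request, since between-run reproducibility is analyzed separately — we
report the mean, sd, CV% = 100·sd/mean and range (max − min) of the
determined replicate CTs.

* **sd denominator**: n − 1 (the replicates are a sample of the
  measurement process). Groups with fewer than two determined values get
  NaN sd/CV/range and a flag rather than an error.
* **CV on the CT scale**: CV is computed directly on CT values, not on
  linearized abundance; sub-percent to low-double-digit CV ranges are only
  meaningful on the CT scale.
* **Expression tiers**: ultra-high CT < 10, high [10, 20], moderate
  (20, 30], low > 30. Published interval conventions of the form
  "10.01–20.00" leave (10, 10.01] unassigned at CT resolution; closing the
  intervals on the high-abundance side keeps the tiers a total, exclusive
  partition of (0, ∞) while moving no printed boundary by more than 0.01
  cycles.
* **Fidelity**: per platform and cutoff c ∈ {1, 2, 3} cycles, the
  percentage of scorable replicate groups with range *strictly* below c
  ("differed by less than"); deviation from fidelity is the complement. A
  group containing any undetermined replicate counts as exceeding every
  cutoff under the default `fail_all` policy — a dropout is a
  worse-than-8-fold discordance — with an `exclude` policy available that
  scores only the determined values. Scoring is per *group* (range over all
  replicates), not per replicate pair; with duplicate reactions the two
  coincide, and the group convention extends monotonically to n > 2.
* **Inter-run differences**: per (platform, mirna), run means are formed
  per sample, differenced between the two runs over shared samples, and
  summarized as mean absolute and mean signed difference; the signed mean
  exposes systematic run shifts (e.g. a repeat run reading consistently
  lower).

## Cross-platform concordance

Replicates are collapsed to their cell mean, cells missing on either
platform of a compared pair are dropped (pairwise-complete matching per
pair, not listwise across all platforms — a full panel yields 42 miRNAs ×
4 samples = 168 pairs per comparison), and each platform's retained values
are standardized to mean 0, sd 1 (sample sd). Concordance is unweighted
OLS of the comparison platform (y) on the reference platform (x), with
Pearson r, R² = r², slope and intercept. The axis convention benchmarks
against the reference on x; the slope's deviation from 1 measures
compression/expansion.

When both platforms are standardized over exactly the matched cells the
OLS slope equals r identically; reported slopes and correlations therefore
separate only when standardization and matching use different cell sets,
which is why `ConcordanceRegressor` accepts any externally standardized
pairs. An option standardizes within sample-type groups (e.g. cellular vs
serum) instead of per platform overall; the default is per platform.

## Clustering

Rows are miRNAs, columns samples, entries the platform's z-scored collapsed
CTs. miRNAs with a missing fraction above 15 % — judged over the cells of
all platforms pooled (per-platform filtering available) — are excluded;
remaining missing entries are imputed with the row (miRNA) mean. This
missingness filter also subsumes assays unreadable on a single platform;
no assay names are hard-coded.

Agglomeration is Ward's minimum-variance criterion on Euclidean distances
(scipy linkage). The cluster count follows the Mojena stopping rule: with
fusion heights α₁ ≤ … ≤ α_{n−1}, merges with height strictly above
mean(α) + k·sd(α) (sample sd, default constant k = 1.25, the classical
recommendation) are flagged; cutting below the lowest flagged merge leaves
(#flagged + 1) clusters, and no flagged merge means one cluster. The Ward
cut at that k seeds a single k-means run (sklearn, `n_init=1`,
Ward-centroid initialization), making the refinement deterministic; sklearn's
k-means relocates points rather than leaving clusters empty, so all k labels
stay populated. `MojenaWardKMeans` wraps the chain as a sklearn-compatible
clusterer.

Partitions from two platforms are compared on their shared miRNAs via the
contingency table. Default matching is optimal one-to-one maximal overlap
(Hungarian assignment), under which the misassignment percentage is
invariant to relabeling of either partition; a `literal` mode instead maps
each comparison cluster to the reference cluster it shares at least two
members with (many-to-one allowed), a looser published-style convention.

## Signature profiles

A profile is an ordered panel (≥ 3 miRNAs) of replicate-mean values for one
(platform, sample). Axes sit at equal angles 2π/n; the polygon area is
½·sin(2π/n)·Σᵢ rᵢ·r₍ᵢ mod n₎₊₁ — invariant under cyclic rotation and
reversal, quadratic under uniform scaling. Profiles are compared by area
ratio (1 if both areas are zero; an error if only the denominator
vanishes) and Pearson correlation across matched axes (flagged undefined
for constant profiles). Raw CT is the default radial scale, matching
published radar displays; an inverted scale (max − CT) is available since
lower CT means higher abundance. Axis order is the caller's panel order;
there is no canonical sorting.

## Simulator

The generator embodies the limiting-dilution argument quantitatively:

1. **Partitioning.** Each reaction receives a Poisson copy count with mean
   λ = concentration × reaction_volume / dilution_factor. Concentration is
   the ground truth per (miRNA, sample) in copies per liter of the shared
   pre-dilution pre-amplification product; each platform applies its own
   dilution. λ thus scales linearly with volume at fixed dilution, which is
   the volume effect the dropout property tests isolate (the 15 nl
   platform's smaller volume is partly offset by its 1:10 rather than 1:40
   dilution in the four-platform defaults).
2. **Measurement.** c copies are pre-amplified deterministically to
   N = c·(1+E)^P effective copies (efficiency E = 0.95 by default,
   P = 12 or 16 cycles) and cross threshold at
   ct = ct_one_copy − log(N)/log(1+E) + run_shift + ε,
   ε ~ N(0, noise_sd²) per reaction and run_shift ~ N(0, 0.5²) cycles per
   (platform, run). Zero copies, or ct beyond max_cycles = 40, are
   undetermined. With E = 1 each copy doubling lowers CT by exactly one
   cycle. ct_one_copy = 45 places an un-amplified single copy outside the
   detection window and a pre-amplified one in the low-expression tier,
   as real single-copy reactions behave. This CT model is intentionally
   the simplest one reproducing one-cycle-per-doubling, volume-dependent
   dropout and tier-dependent variability; pre-amplification is a
   deterministic gain (stochastic early-cycle amplification would add bias
   amplification, which the model does not attempt).
3. **Platform defaults.** ViiA7 5 µl / 12 PA cycles / 1:40 / noise 0.10;
   TLDA 1 µl / 12 / 1:40 / 1.20; OA 33 nl / 12 / 1:40 / 0.30; DA 15 nl /
   16 / 1:10 / 1.50 cycles. The noise sds were derived from the median
   replicate CVs and CT levels the four real platform classes exhibit, and
   reproduce their rank order (96-well < 33 nl array < 1 µl card < 15 nl
   array) — note the card is noisier than the larger-volume 33 nl array in
   the real data too, so platform noise is not forced monotone in volume;
   the Poisson dropout component is.
4. **Truth profile.** 42 miRNAs × 4 samples (two cellular, two serum
   labels) in four planted clusters occupying log10-concentration bands
   13–14, 11.5–12.5, 10–11 and 9–10 copies/l, each cluster carrying its own
   ±1.5 log2 across-sample pattern plus 0.25 log2 per-cell jitter. The top
   band reaches the ultra-high tier on the 5 µl platform; the bottom band
   yields a mean of a few copies per nanoliter-scale reaction, where
   Poisson dropout and CT spread become visible. Two runs, duplicate-to-
   octuplicate replication supported (default 4).
5. **Determinism.** All randomness flows from one master seed through
   named substreams (partition, noise, run shift), so identical configs
   produce byte-identical tables and modules can be perturbed
   independently.

### What the simulator does and does not emulate

It reproduces the structural features the analyses rest on: Poisson
dropout scaling with reaction volume, noise growing as abundance falls,
platform-level noise differences, run-level shifts, cluster-structured
expression, and realistic CT ranges. It does not model RT/pre-amplification
chemistry, primer-pool incompatibilities (absent assays are simply missing
in configs), amplification-efficiency differences between assays,
lot-to-lot consumable variation, or sequencing-based quantification.
Passing tests on simulated data therefore demonstrate correctness of the
statistical pipeline and the qualitative volume-driven platform ordering —
not quantitative agreement with any particular instrument's error profile.

## Numerical choices and degenerate inputs

* Zero-variance platforms and < 3 matched cells raise typed errors rather
  than emitting NaN statistics.
* A replicate range exactly equal to a fidelity cutoff fails that cutoff
  (strict inequality).
* Mojena with a single merge (n = 2) treats the sd of one height as 0, so
  k is 2 only if that height exceeds itself — i.e. never — giving k = 1.
* Ties in Ward merges follow scipy's ordering; the small-instance oracle
  in the tests uses continuous random data, where ties have measure zero.
* `assign_clusters` with k = n returns the identity partition without
  invoking k-means.
* Report CSVs round to 6 significant digits; the measurement table itself
  is written at 10 significant digits, so round trips are lossless at
  analysis precision.

## Problem sizes

The default synthetic study (4 platforms × 2 runs × 4 samples × 42 miRNAs
× 4 replicates = 5 376 reactions) runs the full pipeline in about a
second; the test suite's Monte-Carlo checks use 10⁵ Poisson draws, the
planted-partition recovery 100 seeded runs of 24 × 4 matrices, and the
brute-force Ward oracle instances of up to 7 rows, sizes at which the
exhaustive oracle is exact and fast.
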