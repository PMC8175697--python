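# Methods

## The problem setting

Plasma (circulating) miRNAs are measured by RT-qPCR panels as quantification
cycles Cq, where lower Cq means earlier amplification and higher abundance.
A diagnostic signature is a small set of miRNAs whose joint ΔCq profile
feeds a classifier separating cancer from healthy plasma. The central
methodological hazard this package addresses is *population confounding*:
baseline plasma miRNA profiles differ between recruitment sites (genetics,
environment, pre-analytics), so a miRNA that separates cases from controls
in one population may owe part of that separation to site, and a signature
built on it degrades when validated on the other population.

## Generative model of the synthetic data

`simdata` draws, for sample *s* and miRNA *m*,

    Cq(s, m) = mu[m] + delta_d[m]·1{s cancer} + delta_s[m]·1{s site B}
               + b_s + eps(s, m)

- `mu[m]` — baseline mean Cq, drawn once per study from U(22, 34) (typical
  plasma panel range) unless supplied;
- `delta_d[m]` — disease shift in Cq; default five miRNAs at −2 Cq (a
  4-fold abundance increase in cancers, a realistic strong biomarker);
- `delta_s[m]` — site shift; default twenty miRNAs at ±2 Cq, two of which
  are also disease miRNAs — the confounding overlap is the mechanism under
  study, so it is on by default;
- `b_s ~ N(0, sigma_sample)` — per-sample offset (loading/extraction
  efficiency), default SD 1 Cq; exactly the nuisance ΔCq normalization
  removes, which lets tests verify the normalization's purpose;
- `eps ~ N(0, sigma_noise)` — measurement noise, default SD 0.5 Cq
  (typical qPCR technical replication);
- values above `lod_cq` (default 37 cycles) are censored to missing — low
  abundance goes undetected; each site measures only its own panel
  (defaults 187 and 175 miRNAs, 165 common).

Cohort sizes default to the two-site study design the package emulates
(143/136 and 82/73 cancer/healthy), with 55 + 55 per site split into
age/subtype/count-matched design cohorts (largest-remainder subtype
allocation, greedy within-stratum age pairing) and REST validation cohorts.
Hemolysis ABS₄₁₄ is drawn Gamma(2, 1.2), putting ~8% of samples past the
\>5 exclusion threshold.

What the generator deliberately does not emulate: amplification-efficiency
and melt-curve artifacts, spike-in chemistry, correlated miRNA co-regulation
(features are independent given class/site/sample), and age- or
subtype-dependent effect sizes. Passing tests therefore demonstrate that the
*pipeline machinery* behaves correctly under a faithful additive-Gaussian
abstraction of two-site qPCR data, not that any specific signature will
transfer to real cohorts.

## Normalization

"Most expressed" is ranked by mean *present* Cq over the whole dataset
(ties broken lexicographically); the per-sample reference is the mean of the
sample's present normalizer Cqs. Missing values are excluded from both
means and never imputed — imputation would fabricate signal. Each dataset
recomputes its own top-50, so the normalizer sets legitimately differ
between cohorts and no validation statistic leaks into design.

## Feature selection and stability

Resampling partitions are stratified bootstraps (class proportions
preserved), the forest-community convention for "random resampling
partitions". Per partition, MDA is permutation importance evaluated on the
partition's out-of-bag samples (3 permutations per feature) and MDG the
impurity-based importance of the fitted forest. The combined rank is the
rank of the mean of the two per-feature ranks — raw MDA and MDG are on
incomparable scales, their ranks are not. Exact rank ties break
lexicographically by miRNA name, making every ordering deterministic under
a fixed seed.

The Kuncheva consistency index uses the closed form
(o − s²/N)/(s − s²/N) averaged over partition pairs and is undefined at
s = N (refused). The Spearman index is the mean pairwise rank correlation
of the full per-partition orderings. When no pool size k is imposed, the
default is the smallest k at which the Kuncheva index changes by < 0.01
("stability plateau") — the criterion is configurable because plateau
detection is a heuristic, not a theorem.

## Signature search

The search is exhaustive by design (2^k − 1 subsets, ordered by size then
name; a guard refuses pools above 25 without an explicit override). Design
scoring uses repeated stratified Monte-Carlo 90/10 splits rather than
10-fold CV: repeated splits are the fully specified scheme (count, fraction,
shared partitions across signatures); stratified k-fold remains available
(`make_kfold_splits`). Stratification prevents single-class test partitions
at ~110-sample design cohorts; should one still occur, that repeat is
skipped with a logged count rather than polluting the AUC mean. mtry is
⌊√p⌋ with a floor of 1.

## Validation

Ensemble scores are the mean over design-repeat forests of the forest's
predicted cancer probability; with fully grown trees this equals the
fraction of trees voting cancer. AUC is the Mann–Whitney statistic (ties
½); the CI is DeLong's variance estimate on the placement components,
clipped to [0, 1], with an all-tied degenerate input returning the
uninformative interval (0, 1) with a warning. ROC points are evaluated at
midpoints between distinct scores plus the ±∞ ends, which makes the
trapezoidal area algebraically equal to the Mann–Whitney AUC (a test
enforces equality to 1e−12). The Youden cutoff scans the same candidate
set; ties in J resolve to the highest cutoff, favoring specificity —
appropriate for a screening-adjunct test where false positives trigger
invasive follow-up. The decision rule at the cutoff is score ≥ cutoff ⇒
cancer.

## Population comparison and confounder exclusion

PCA runs on mean-centered, unscaled ΔCq (all features share Cq units;
scaling is available upstream but not default). The site screens are the
same forest machinery with site as the label, and a per-miRNA
Kruskal–Wallis H (tie-corrected, via scipy) ranked by p then H then name.
The default confounder call is the *triple intersection* — a disease-set
miRNA is flagged only when both site screens agree — with a stricter
union variant available. Excluded miRNAs are dropped column-wise without
re-normalization: exclusion of a handful of miRNAs changes the top-50
normalizer set only if a flagged miRNA were itself a normalizer, and
per-dataset re-normalization upstream covers that case.

## Problem sizes and numerical choices

Full-scale settings (ntree = 3000, 50 design splits, 100 partitions, pools
of 13–17) are the `ForestConfig` defaults and are what the CLI uses. The
test suite and the controlled experiments in `mirsig.experiments` run a
reduced profile — ntree = 100, 10–15 partitions, 10 design splits, pools of
5, 40–60 miRNAs, 50–80 subjects per group — chosen so a complete experiment
is a minutes-scale, single-CPU computation while keeping every effect size
at the generator's realistic defaults. Null-calibration checks use
validation cohorts of ~60 per class so that the Monte-Carlo standard error
of a mean shortlist AUC (~0.05) sits well inside the ±0.07 tolerance the
calibration test asserts.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; per-signature forest seeds derive from a CRC32
of the signature's member names so results are independent of enumeration
order and of Python's hash randomization. Identical seeds and inputs give
byte-identical result tables (enforced by a replay test).

## Known limitations

- Greedy age matching is deterministic and auditable but not optimal
  (Hungarian-style matching could reduce total age discrepancy).
- MDA from 3 OOB permutations is noisier than R's per-tree permutation
  importance; averaging over ≥15 partitions compensates.
- The DeLong interval is asymptotic; at very small validation cohorts
  (< ~10 per class) its coverage degrades and the bootstrap option in the
  roadmap would be preferable.
- Signatures containing miRNAs missing in *some* validation samples drop
  those samples rather than the signature; heavy censoring can therefore
  shrink the effective validation cohort.
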