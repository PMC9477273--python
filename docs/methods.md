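# Methods

This note documents the models behind `cleavekit`, the defaults that
matter, what the synthetic data does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Forward model of the cleavage assay

Each sensor has a ligand-free cleavage fraction `c0` ∈ (0, 1). A cognate
ligand at concentration `x` (µM) acts on the **odds** scale, dividing the
cleavage odds by a saturating fold change

```
FC(x) = 1 + (fc_max − 1) · x / (x + ec50)
```

so `FC(0) = 1` and `FC(∞) = fc_max`. When several cognate ligands are
present simultaneously their fold changes combine multiplicatively
(additively in log-odds); the assay literature does not constrain this
choice, and the multiplicative rule is the natural null of independent
odds-scale effects. The hyperbolic concentration dependence is likewise a
modeling choice: observed dose curves are monotone and saturating, and a
single-site binding isotherm is the simplest form with those properties.

Sequencing is modeled in two stages: total reads per sensor are multinomial
in the library abundances, and cleaved reads are binomial within a sensor
at its model cleavage fraction. A per-condition `bias` multiplier on the
odds emulates run-to-run ratio bias; it is what reference-sequence
normalization must remove. No sequencing-error model is applied (reads are
exact copies of prefix + insert + suffix), so read-counting tests verify
bookkeeping, not error tolerance.

Default parameter distributions for synthetic libraries, used wherever a
study design does not fix them, are: `c0 ~ Beta(5, 2)` (cleavage-biased, as
expected after initial enrichment for cleavers), `fc_max ~ logUniform(2, 17)`
(the observed dynamic range of responses), `ec50 = 0.5 µM` by default for
planted targets (sub-micromolar binders; measured sensitivities span
~25 nM to >5 µM). These are fixtures for testing, not claims about any real
library.

## Fold-change statistics

With raw counts (a, b) = (cleaved, uncleaved) in reference and test
conditions, all four counts receive the Haldane–Anscombe pseudocount ½,
making zero-read sensors well-defined (they yield FC = 1 with maximal
standard error). Then

```
FC = (a′_ref · b′_test) / (b′_ref · a′_test) / k
se(log FC) = sqrt(1/a′_ref + 1/b′_ref + 1/a′_test + 1/b′_test)
```

Confidence intervals are `exp(log FC ± z · se)` and the p-value is the
two-sided normal tail of `log FC / se` (delta method). At 200 reads per
condition the 95 % interval's empirical coverage of a true 4-fold change is
95.0 % (measured over 10⁴ simulated sensors), which is what the acceptance
suite asserts at ±2 %.

The normalization factor `k` is the **median** raw fold change over
designated unresponsive reference sensors with ≥100 reads in both
conditions — the median resists a responsive contaminant among the
references. With fewer than three usable references the factor falls back
to 1 with a warning.

Reads are assigned to sensors by **exact insert identity** after prefix and
suffix removal (prefixes tolerate a configurable Hamming mismatch budget;
condition barcodes are matched exactly and may be 1–10 nt). No
near-duplicate collapsing is performed: the simulator emits error-free
reads, so a collapse step would have nothing to correct here, and on real
data error correction belongs upstream of counting where quality scores
are still available. Unassignable reads are tallied by reason, never
silently dropped.

A sensor is called **significant** when `p < 1/N` (Bonferroni over the `N`
sequences tested), both conditions carry ≥100 reads, and FC ≥ 2 (optionally
also FC ≤ ½ for inverse responders). Under a null screen this yields
family-wise false positives in the Poisson(1) regime.

## Pool design

The library is partitioned `n_partitions` independent times into pools of
exactly `pool_size` compounds. Within a pool, no two compounds may have any
pair of expected singly-charged positive-mode adduct m/z values (M+H
+1.00728, M+Na +21.98192, M+NH4 +18.03383 Da) closer than `mz_window`
(default 0.01 Da) — this keeps every compound individually verifiable by
LC-MS in the mixtures it inhabits. The constraint is applied to all three
adducts by default and is configurable.

The solver is randomized greedy with repair: per partition, shuffle the
compounds, insert each into the least-loaded conflict-free pool, repair
leftovers by single swaps, and restart the partition on failure. At the
reference scale (5,120 compounds, 9 × 20 pools of 256) the problem is loose
and the first attempt essentially always succeeds; an exact CSP solver
would be unwarranted. Infeasible instances (e.g. more mutually conflicting
compounds than pools) raise an error naming a greedy-maximal conflict
clique.

`decodability_report` estimates by Monte Carlo, for target-set sizes
1..k, the fraction of compound sets whose induced responsive-pool union
identifies them uniquely (no other compound's full signature fits inside
it). The report is made monotone non-increasing in set size by a running
minimum; the raw estimates are monotone in expectation already.

## Group-testing decode

Pools are classified three ways from their fold-change records:
**responsive** (significant and FC ≥ 2), **nonresponsive** (upper 95 %
bound below 2), otherwise **indeterminate**; unmeasured pools are listed
separately. A compound is a **candidate** when its responsive support is at
least `support_min` (default 0.8, i.e. ≥8 of 9 measured pools — one pool
may drop to read noise) of its measured pools and it has at most
`violations_max` (default 1) nonresponsive pools. Indeterminate pools count
in the denominator but can never be violations. The minimal explanation is
a minimum set cover of the responsive pools over candidates — exact search
up to 12 candidates (greedy cover can overshoot by one on heavily
overlapping patterns; toy-design tests compare against exhaustive
enumeration), greedy beyond, with deterministic tie-breaks (support,
violations, lexical id).

A sensor is **promiscuous** when it has more than `promiscuity_cap` (10)
candidates or more than half its measured pools respond: with ~10 or more
distinct targets in a 9-partition design the responsive set blankets most
pools and carries no information.

### Reference screen

The packaged screen benchmark (`cleavekit.benchmarks.pool_screen_benchmark`)
measures 180 single-target sensors (fc_max 6, EC50 0.5 µM, compounds at
2 µM per pool) against all 180 pools of a full 5,120-compound design at
200 reads/sensor/pool. The shared no-ligand reference condition is
simulated at 2,000 reads/sensor — one deep reference run against many
shallow pool runs, mirroring how a real campaign re-sequences selected
conditions at depth — and significance is Bonferroni over all sensor×pool
tests. Exact single-target recovery is 98–99 % across seeds; the acceptance
suite requires ≥95 %. The residual failures are sensors with `c0` near 1,
whose cleaved:uncleaved odds are intrinsically poorly estimated.

## Response profiling

The profile distance between sensors i and j is

```
d′(i, j) = max over shared conditions v of |log FC_i,v − log FC_j,v| / sqrt(se_i,v² + se_j,v²)
```

a symmetric premetric (d′(i,i) = 0) measured in combined-standard-error
units. Missing cells are excluded from the max rather than imputed; a pair
with no shared measured condition is an error, not a zero. Clustering is
agglomerative **complete linkage** on d′, so every within-cluster pair sits
below the merge height; the flat cutoff defaults to d′ = 3 (≈3 combined
standard errors) and is a flag, not a claim. Cluster representatives are
the highest-abundance members (ties by sensor id). Dendrograms export to
Newick with d′ heights.

Cross-reactivity at fold threshold `f`: per sensor, the number of compounds
driving ≥ f-fold change; per compound, the minimum over its responding
sensors. Note that the cumulative count of compounds with cross-reactivity
≤ C is guaranteed monotone in C but **not** in f: raising f removes
responders but can make surviving compounds more uniquely sensed, so at
small C the count may rise with f. The suite asserts only the true
monotonicities (in C, and of the number of compounds with any responder
in f).

Dose series are two-fold dilutions; the minimum detectable concentration is
the lowest *measured* concentration with FC ≥ 2 and a 95 % lower bound
above 1 — no interpolation. Sensors responding (≥2-fold at 10 µM in the
single-compound matrix) to a compound co-assayed in the same well are
masked with a reason rather than reported.

## Fragment-based hit prediction

Sensor–compound pairs are labeled **hit** (90 % CI lower bound > 2),
**miss** (upper bound < 2) or **indeterminate** — a pure function of the
interval, no model involved. Compounds are featurized as presence bits over
the union of canonical circular atom environments of radius 0–3 enumerated
from the whole library (the vocabulary size is emergent from the library,
and the sorted key order is persisted to JSON for reproducibility).

Per sensor with ≥3 hits, a random forest (200 trees, unlimited depth, fixed
seed, balanced class weights) is evaluated by leave-one-out
cross-validation; folds whose training set is single-class predict the
majority class and are flagged. Two corrections counter the well-known
leave-one-out prior-shift artifact (holding out a hit depresses the
training class prior, so raw LOO scores are anti-correlated with the
held-out label — a label-permutation null scores ~0.35 AUC instead of
chance): the forest uses balanced class weights, and the ranking score
used for ROC is the predicted probability minus the fold's training hit
fraction. Hard hit/miss predictions for the confusion table still
threshold the raw probability at 0.5. With both corrections the
permutation null sits at ~0.44 pooled AUC; the residual pessimism is the
inherent effect of the held-out example's absence and shrinks with sample
size. Aggregation sums confusions across sensors, reports precision
TP/(TP+FP) (undefined when TP+FP = 0), and pools all centered scores into
a single ROC AUC alongside per-sensor tables.

## Selection dynamics

A round multiplies each sensor's abundance by its survival weight — `c`
under the round's condition for cleaved-selecting rounds, `1 − c` for
uncleaved-selecting rounds — renormalizes (PCR amplification preserves only
relative abundance), and optionally applies a multinomial bottleneck of
`sample_size` molecules. Parasitic amplicons receive a fixed,
sense-independent weight (default 0.95/round), emulating sequences whose
structure evades the reverse-transcription block; note this default makes
amplicons fitter per round-pair (0.95² ≈ 0.90) than even strong switchers
(≈0.9 × 0.44 ≈ 0.40), so in mixed simulations amplicons dominate unless
their fitness is set below the switcher range — the packaged recovery
benchmark therefore runs amplicon-free and amplicon dynamics are exercised
separately.

The default 95-round schedule: rounds 1–7 select cleavers with no ligand;
thereafter rounds alternate, with the selection mixture at 2 µM per
compound in the uncleaved-selecting (positive) rounds; from round 88 the
concentration drops to 1 µM and the *alternate* mixture is added to the
cleaved-selecting rounds to penalize cross-reactive sensors. Per-round
carry-forward defaults to 10⁶ molecules with the first four rounds at 10⁷
(the large-volume rounds that protect pre-enrichment diversity); with a
uniform 10⁵ bottleneck, rare planted switchers are lost to drift in rounds
5–10 before selection can act, which measures the bottleneck rather than
the method. Schedules round-trip through YAML.

The end-to-end benchmark plants 20 identical switchers (c0 = 0.9, fc_max
10, EC50 1 µM, targets inside the selection mixture) in a 10⁴-sensor
library, runs the full 95-round schedule, sequences the final round at 10⁶
reads per condition, and calls responders with the Bonferroni rule at
N = 10⁴. Identical response parameters make selection fitness uniform
across the plants, so the benchmark measures recovery rather than
fitness-spread survivorship. Sensitivity is 1.0 with zero false positives
across seeds; the acceptance suite requires ≥0.8 and ≤2.

## LC-MS pool verification

For each compound, peaks matching an expected adduct m/z within 10 ppm are
collected across its five expected pools and a set of control pools, then
clustered by retention time with a 0.1 min single-linkage tolerance
(clusters split at gaps > 0.1 min, global across runs). The winning
(adduct, RT-cluster) signature maximizes expected-pool presence, then
minimizes control presence, then maximizes mean intensity — a rule
invariant to peak-list order and to positive rescaling of intensities. A
compound is **identified** when the signature appears in ≥4 of 5 expected
pools and ≤0 control pools (both thresholds are flags), and **ambiguous**
when another library compound's expected adducts collide with the winning
m/z within tolerance (a conservative, mass-only collision rule). The
synthetic peak generator assigns each compound a latent retention time,
emits all three adducts with log-normal intensities and small m/z/RT
jitter, and supports per-pool dropout and background noise peaks; it does
not model chromatographic drift between runs, isotope patterns, or
ion-suppression effects, so identification tests exercise the matching
logic, not instrument realism.

## Scales and determinism

All generators and simulations take explicit integer seeds and are
deterministic per seed (byte-identical emitted reads included). The test
and acceptance suites run the statistics at the study scales quoted above —
10⁴ sensors for calibration checks, the full 5,120-compound/180-pool design
for the screen, 95 rounds for the campaign — chosen so the whole suite
completes on a single CPU in minutes while keeping every Monte-Carlo
assertion inside comfortable sampling error.

## Known limitations

- No sequencing-error or PCR-chimera model; insert identity is exact, and
  near-duplicate collapsing is out of scope.
- Synthetic compound structures come from a small template grammar and
  their masses are independent of the structures; fragment-classification
  results on them demonstrate correctness of the machinery, not chemical
  generality.
- The saturating response and multiplicative ligand combination are
  modeling conventions; real sensors may show cooperativity or
  interference.
- Amplicon fitness is a single free parameter standing in for an
  unmodeled structural mechanism.
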