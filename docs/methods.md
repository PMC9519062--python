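# Methods

## The partition model

The analysis treats "seasonality" as a property to be discovered, not
imposed. Samples (depth × date community profiles) are assumed to occupy a
small number of recurring habitat states; a taxon is *seasonal* if its
abundance concentrates in one state, and *aseasonal* if its fluctuations
cannot be told apart from random reallocation of samples. The partition is
chosen to maximise the evidence for seasonality: for every k in a range,
samples are clustered, each taxon's indicator value for its best cluster
is permutation-tested, and the k with the largest sum of significant
indicator values wins. Ties go to the smaller k (parsimony).

Assumptions worth stating:

- Hellinger geometry. Counts are compositional; k-means and PCA operate on
  `sqrt(relative abundance)`, which bounds the entries, down-weights
  dominant taxa, and makes Euclidean distance equal the Hellinger distance
  between raw profiles.
- The cluster statistic is means-based ("group-equalised") specificity
  times presence fidelity, `IndVal = sqrt(A·B)`. Using cluster *means* in
  A makes the statistic insensitive to unequal cluster sizes. The classic
  Dufrêne–Legendre product `A·B` is available via `variant="classic"`.
- Only a taxon's maximum IndVal over clusters is tested (one test per
  taxon, not per taxon × cluster); the remaining multiplicity across taxa
  is handled by Benjamini–Hochberg step-up FDR at 5%.
- The permutation null reallocates whole samples among clusters — one
  shared permutation per iteration for all taxa, preserving taxon–taxon
  correlation. An independent per-taxon reallocation is exposed as an
  explicit non-default (`reallocation="per_taxon"`).
- The full test (permutations + FDR) is rerun independently at every k of
  the scan; p-values are not recycled across k.

## Parameters that matter

| parameter | default | units | why |
| --- | --- | --- | --- |
| `min_reads` | 5 | reads | drop OTU clusters with < 5 reads total, the standard low-abundance artifact filter |
| rarefaction `depth` | min sample total | reads | common depth removes library-size effects; samples below depth are dropped, not kept unrarefied |
| `n_perm` | 999 | – | permutation resolution 1/1000 with the +1 finite-sample correction, `p = (1+#{null ≥ obs})/(1+n_perm)` |
| `fdr_alpha` | 0.05 | – | BH step-up control level across taxa |
| `k_min..k_max` | 2..min(12, n−1) | – | scan range; the upper bound only needs to comfortably exceed the expected number of states |
| k-means `restarts` | 25 | – | best-of-restarts Lloyd with k-means++ seeding; conventional |
| `occ_threshold` | 0.80 | – | non-significant taxa at ≥ 80% occurrence form the stable core |
| `sporadic_occ` | 0.10 | – | non-significant taxa under 10% occurrence (≤ 7 of 70 samples) are sporadic background; in between is stable core with a low-confidence flag |

Derived environmental quantities follow the standard limnological
conventions: DIN = NO3 + NO2 + NH4; DON = TN − DIN and DOP = TDP − SRP (by
difference); seston ratios C:P = PC/PP and N:P = PN/PP; light extinction
k = 1.7/z_sd from Secchi depth and relative irradiance I(z) = exp(−k·z).
In the discriminant analysis every variable except pH and the `*_ratio`
columns is log-transformed as `log(x + δ)` with δ = half the smallest
positive observed value of that variable (admits zeros). No variable
selection is performed: the aim is to *characterise* the environments the
clusters occupy, not to build a parsimonious classifier, so overfitting is
accepted by design and the leave-one-out accuracy reported alongside it
should be read with that in mind.

## The synthetic survey

The generator emulates a one-year profile survey of a deep, dimictic,
seasonally ice-covered oligotrophic lake: 14 four-weekly dates × depths
(2, 10, 20, 35, 60 m) = 70 samples, ice cover in December–May. A
deterministic template maps (month, depth, ice) to six habitat states —
under-ice bulk (31 samples), thaw + stratified-summer hypolimnion (13),
early stratification (6), summer epilimnion (6), autumn overturn + early
ice (10), late-winter deep layer (4) — deliberately unequal, as real
seasonal clusters are.

Planted taxa: 60 resistant (flat expected profile), 60 ice-on-resilient
(each favoring one of the three ice-associated states), 40
ice-off-resilient (one of the two epilimnetic states), 20 deep
specialists, 20 sporadic (present in 2–5 random samples only). A favored
state multiplies the taxon's log-normal baseline (σ = 1) relative
abundance by `effect_size` (default 4). Counts are Dirichlet-multinomial
with concentration 1/`dispersion` = 2000 at log-normal library sizes
(median ≈ 2000 reads, σ_log = 0.2).

Two generator choices deserve explanation:

- Each seasonal taxon favors exactly *one* state. Broad favored sets
  (e.g. "everywhere except the epilimnion") make their members'
  indicator values largest on coarse two-way partitions, and the scan
  then legitimately prefers k = 2; single-state indicators are what give
  the optimum at the true state count, and they match how real indicator
  taxa behave (blooms confined to a window).
- The sequencing depth is moderate on purpose. A 4-fold mean effect
  produces genuine absences outside the favored window only when
  unfavored expected counts are of order one read; those absences let
  fidelity B anchor the fine-grained clusters. At very large depths every
  taxon is present everywhere and a 4-fold contrast alone cannot make the
  true k win — a property of the statistic, not a bug in the
  implementation. The noise-free limit behaves the same way: with no
  sampling noise *every* taxon is significant at every k and the scan
  collapses to k = 2, which is why the test suite exercises recovery at
  realistic noise and the structureless null rather than a noise-free
  fixture.

What the generator does **not** emulate: real taxonomic composition
(taxonomy strings are placeholders), temporal autocorrelation beyond the
state template, depth gradients within a state, chemistry covariance
structure (variables are drawn independently around state means), or
detection bias. Passing the recovery tests therefore shows the procedure
identifies planted state structure under overdispersed compositional
noise — not that any particular real lake has six states.

## Numerical choices

- Rarefaction draws from the multivariate hypergeometric distribution
  (without replacement), so rarefied columns sum to the depth exactly.
- PCA and LDA axis signs are fixed by making each axis's
  largest-magnitude loading positive, so runs are reproducible
  bit-for-bit.
- k-means ties and degenerate inputs: an empty cluster (possible only
  with duplicate profiles) is repaired by reassigning a sample from the
  largest cluster; inertia is recomputed from the final labels.
- All-zero taxa have undefined specificity; their IndVal is set to 0 and
  they are flagged, never significant.
- Best-cluster ties break toward the lower cluster index (argmax).
- A singular within-class scatter in the LDA is ridge-regularised with a
  logged epsilon scaled to `trace(Sw)/p`.
- Tukey HSD uses the studentized-range distribution with the
  Tukey–Kramer standard error for unequal group sizes; clusters with
  fewer than two samples are excluded from the diversity comparison with
  a warning.
- One seed drives everything; stages draw from named `SeedSequence`
  substreams, so stage outputs are reproducible independently.

## Problem sizes

The bundled analyses run at the survey's native size (70 samples, 200
planted taxa, scan k = 2..12). The acceptance script uses 999
permutations for the single end-to-end survey and 199 for the 20-seed
recovery experiment and the 2000-taxon null calibration; those
permutation counts give p-value resolutions of 1/1000 and 1/200, which is
ample for 5% decisions at these community sizes.

## Known limitations

- The cumulative-IndVal criterion compares sums over *different*
  significant sets across k; it has no penalty for complexity other than
  indicator dilution, and with weak effects or very deep sequencing it
  can prefer coarse partitions (see above).
- Permutation p-values are exchangeable-sample tests; they ignore
  temporal autocorrelation, which a real monthly series has.
- The stable-core/sporadic occurrence thresholds are conventions, not
  estimates; the low-confidence flag marks the band between them.
- LDA assumes shared within-cluster covariance of the (log) variables;
  with 5 axes and ~20 variables on 70 samples it *will* overfit, which is
  accepted (characterisation, not prediction).
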