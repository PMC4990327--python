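# Methods

## Model and assumptions

`ctprofiler` treats a cohort's normalized log2 expression matrix
(probes × samples) as the unit of analysis. For every probe the cohort mean
is subtracted and the deviation is discretized into {-1, 0, +1} at
±`threshold_factor · σ_g`. The working assumption behind the default
threshold is that per-probe deviations are approximately Gaussian: with
`threshold_factor = Φ⁻¹(2/3) ≈ 0.4307` (used as 0.43 everywhere) the three
codes are equally frequent, so no code dominates and a binary
expressed/not-expressed scheme's loss of the "near mean" state is avoided.
The per-sample ternary profiles are clustered into exactly three groups;
k = 3 is a model commitment, not a tuned choice — the method exists to
detect and transfer a three-group structure. Group-mean ternary profiles
(entries in [-1, 1]) are the CTP target vectors; single samples are assigned
by maximum Pearson correlation with them.

Everything is relative to the analyzed cohort's own per-probe mean and
standard deviation. A transferred model is therefore applied to a new cohort
only after that cohort is discretized against *its own* statistics; this is
deliberate and is what removes tissue-of-origin level shifts. The
corollary: a single sample cannot be classified in isolation — it needs a
cohort to define the means.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `threshold_factor` | 0.43 | discretization cut, as a fraction of per-probe σ (dimensionless) |
| `std_mode` | `sample` | σ estimator: n−1 (`sample`) or n (`population`) denominator |
| `method` | `kmeans` | grouping back-end; `som` gives the 1×3 self-organizing map |
| `n_restarts` | 10 | k-means restarts; best inertia kept |
| `min_common_probes` | 100 | refuse model transfer below this probe-id intersection |

σ defaults to the sample estimator because it is the usual cohort statistic;
the flag keeps the choice auditable (the two differ negligibly at cohort
sizes where the method is meaningful). Boundary deviations exactly at
±0.43σ code 0 — the "high"/"low" conditions are read strictly; on continuous
data this is a measure-zero event. Zero-σ probes code 0 for every sample
rather than erroring: they are uninformative and 0 is the neutral state.

## Numerical and convention choices

* **k-means**: scikit-learn, squared-Euclidean objective on the raw ternary
  coordinates, deterministic given `(seed, n_restarts)`.
* **SOM**: a 1×3 map (one unit per group), weights initialized from three
  random input profiles, Gaussian neighborhood with radius decaying linearly
  1.0 → 0.1 and learning rate 0.5 → 0.01 over a fixed epoch count. The map
  is implemented in-package; it is small enough that a dependency would cost
  more than it saves. Its quantization error is reported as the grouping
  diagnostic.
* **Label convention**: freshly clustered groups are named A/B/C by
  decreasing size, ties broken by the lexicographically smallest member
  sample id. Labels carry survival meaning only for the cohort that defined
  them; for everything else they are arbitrary, which is why all
  partition-agreement statistics (`overlap`, subset robustness) maximize
  over label bijections (Hungarian matching on the 3×3 confusion matrix —
  identical to enumerating the 6 permutations).
* **Assignment ties** (exactly equal correlations) are broken toward the
  first label in model order and flagged on the result.
* **Probe matching** between a model and a new cohort is by identifier
  intersection in model order; model probes missing from the cohort are
  dropped, never zero-filled (zero-filling would bias r toward 0
  asymmetrically). Transfers with fewer than `min_common_probes` shared
  probes are refused.
* **Undefined correlations** (profile or centroid constant on the common
  support) are hard errors naming the offender, not silent zeros.
* **De Finetti mapping**: the three correlations are clamped at zero,
  normalized into proportions, and the point is pulled toward the triangle
  center by the overall strength `s = min(1, Σ max(r_i, 0))`;
  all-nonpositive triples sit exactly at the center. Retaining the magnitude
  is essential: pure clamp-and-normalize would send a noise sample with
  correlations like (0.02, 0.01, −0.01) two-thirds of the way to a vertex,
  destroying the diagnostic contrast between weakly correlated (central)
  and strongly correlated (peripheral) samples. The exact transform used in
  the original analyses is not published; this one is a declared convention
  chosen to reproduce the qualitative geometry. Vertices are fixed at
  (0,0), (1,0), (0.5, √3/2) with the first label lower-left.
* **Cluster diameter** of an empty CTP is reported as undefined, never 0.
* **Diameter comparison** defaults to Welch's t with a rank-sum alternative;
  the test family behind published diameter contrasts is unnamed, so both
  are exposed and the choice is recorded in the result.
* **Subset robustness** rebuilds centroids from the restricted ternary data
  using a fixed sample grouping (the full model's own assignments unless an
  explicit grouping is passed) rather than re-clustering, so the subset
  effect is not confounded with clustering instability. Similarity is the
  permutation-matched percent agreement with the full-model calls.

## What the synthetic generators emulate

`generate_noise_cohort` draws i.i.d. standard-normal values — the null in
which every deviation is pure fluctuation. The scale (mean 0, sd 1) is
irrelevant by construction, since discretization is σ-relative.

`generate_planted_cohort` draws three groups whose *signal probes*
(`signal_fraction`, default 0.3 of probes) carry group means that are a
random permutation of `(-1, 0, +1) · effect_size · noise_sd` (defaults:
effect 3, noise sd 1), so every signal probe separates the groups and the
three ternary prototypes are pairwise distinct; remaining probes are pure
noise. The standard test cohort is 150 samples × 2000 probes in three equal
groups. These generators emulate the structure the method assumes — they do
**not** model probe–probe correlation, batch effects, platform noise or
unbalanced real-world cohort composition, so green tests demonstrate
algorithmic correctness and recoverability under the stated model, not
performance on any real cohort.

## The null simulation

`run_null_simulation` builds several independent pure-noise "virtual cancer
types" (defaults: 14 types × 50 patients), runs each through the full
pipeline de novo, restricts all centroids to one shared random probe subset
(default 716), and averages the matched-label (size-ordered) centroid
Pearson correlations over all cross-type pairs; within-type A-B/A-C/B-C
correlations are reported alongside. Cross-type correlations hover near 0 —
clustering noise produces groups, but not *the same* groups twice — which is
the yardstick against which high cross-cancer CTP correlations in real data
are judged. Within-type correlations are systematically negative (the three
centroids partition one cohort's variation) and are reported but not used
as a benchmark, because their value depends on the assignment reference
convention. The acceptance script runs this study at 14 × 50 with a
716-probe subset over 10 replicates on 5,000 simulated probes, a
chip-scale-independent choice (the cross-type statistic is insensitive to
the pre-subset probe count, which the tests verify).

## Known limitations

* Exactly three groups, by design; no model selection over k.
* No cross-platform probe translation: transfers assume a shared identifier
  space and refuse thin intersections.
* Assignment is hard (argmax); the correlation triple and de Finetti
  weights are the only soft information exposed.
* Preprocessing/normalization is out of scope: inputs must already be
  normalized log2 matrices.
* The Gaussian-deviation rationale for 0.43σ makes the equal-tercile
  property approximate on heavy-tailed real data; the threshold remains
  configurable.
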