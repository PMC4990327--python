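# ctprofiler

Ternary gene-expression deviation profiling: discover and transfer the three
recurring **Cancer Transcriptomic Profiles (CTPs)** in bulk expression
cohorts.

Many cancer cohorts profiled on expression microarrays separate into three
patient groups that are defined not by the absolute expression of any marker
gene but by the *pattern of deviations from the cohort mean* across the whole
chip. `ctprofiler` implements that analysis for computational biologists
working with normalized log2 expression matrices: it mean-centers each probe,
discretizes the deviations into three levels, clusters the resulting ternary
profiles into three groups, and classifies individual samples — from the same
or a different cancer type — by correlation with the three group centroids.
Because every step is relative to the cohort's own per-probe mean and spread,
the classification is invariant to tissue-of-origin expression-level shifts,
which is what makes cross-cancer transfer meaningful.

## The method

For probe $g$ and sample $s$ with normalized log2 expression $x_{gs}$:

1. **Deviation.** $d_{gs} = x_{gs} - \bar{x}_{g\cdot}$, the deviation from the
   probe's cohort mean.
2. **Ternary discretization.** With $\sigma_g$ the probe's standard deviation,

   $$c_{gs} = \begin{cases} +1 & d_{gs} > +0.43\,\sigma_g \\ -1 & d_{gs} < -0.43\,\sigma_g \\ 0 & \text{otherwise.} \end{cases}$$

   The cut $0.43 = \Phi^{-1}(2/3)$ is the standard-normal tercile, so under
   Gaussian deviations each code occurs with probability 1/3.
3. **Grouping.** The per-sample ternary profiles $c_{\cdot s}$ are clustered
   into $k = 3$ groups (k-means or a 1×3 self-organizing map), and each
   group's per-probe mean code forms its CTP target vector
   $\mu^{(A)}, \mu^{(B)}, \mu^{(C)} \in [-1,1]^G$.
4. **Assignment.** A sample — after discretization *within its own cohort* —
   is assigned to $\arg\max_{L} \; r\!\left(c_{\cdot s}, \mu^{(L)}\right)$,
   the CTP with the highest Pearson correlation.

Supporting analyses: barycentric (de Finetti) triangle plots of the three
correlations, per-CTP "cluster diameter" (mean member–centroid correlation),
gene-subset robustness of the calls, and a pure-noise null simulation that
shows the three-group structure found in noise does not reproduce across
independent cohorts.

## Worked example

Generate a synthetic three-group cohort, build a model, and classify:

```
$ ctp synth --samples 90 --probes 800 --seed 7 --output cohort.tsv --labels labels.tsv
wrote 800 x 90 cohort to cohort.tsv
$ ctp build --input cohort.tsv --method kmeans --seed 17 --output model.json
wrote model (kmeans, 800 probes) to model.json
$ ctp assign --model model.json --input cohort.tsv --output assignments.tsv
assigned 90 samples; wrote assignments.tsv
$ ctp diameter --assignments assignments.tsv --model model.json
CTP-A: diameter 0.551 (n=30)
CTP-B: diameter 0.535 (n=30)
CTP-C: diameter 0.530 (n=30)
$ ctp overlap --gold labels.tsv --test <(cut -f1,2 assignments.tsv)
agreement: 100.0% of 90 samples
permutation (test -> gold): {'A': 'A', 'B': 'B', 'C': 'C'}
```

The diameters (~0.53–0.55) say each group's members correlate strongly with
their own centroid — a tight, real structure; pure-noise cohorts give much
smaller values. The overlap line confirms the clustering recovered the
planted groups exactly (labels matched up to permutation). `ctp definetti`
maps each sample's three correlations into the reference triangle
(`--plot fig.png` renders it), `ctp robustness` measures how stable the calls
are when the model is rebuilt from a probe subset, and `ctp simulate` runs
the noise-null study.

The same pipeline is available as a library: see `ctprofiler.build_model`,
`assign_cohort`, `overlap`, `cluster_diameter`, `subset_robustness`,
`run_null_simulation`.

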