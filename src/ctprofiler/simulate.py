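"""Synthetic cohorts and the pure-noise null simulation.

Two generators back the package's tests and the simulation study:

* ``generate_noise_cohort`` — the null: every probe's deviation from its
  cohort mean is i.i.d. Gaussian fluctuation, so any 3-group structure a
  clustering finds is an artifact of the algorithm, not of the data.
* ``generate_planted_cohort`` — the alternative: three groups whose signal
  probes carry group-specific mean shifts arranged so the three ternary
  prototypes are pairwise distinct, with tunable signal fraction and effect
  size, for recovery and robustness experiments.

``run_null_simulation`` reproduces the study design of the noise experiment:
several independent "virtual cancer types" of pure noise are each taken
through the full pipeline (discretize, cluster into 3 CTPs, average), the
centroids are restricted to a random probe subset, and matched-label
centroid correlations are averaged across all pairs of virtual types.  Under
the null these cross-type correlations sit near zero — the benchmark against
which the high cross-cancer correlations of real cohorts are judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    DEFAULT_LABELS,
    DiscretizationParams,
    ExpressionMatrix,
)
from .model import cluster_ternary, compute_centroids
from .ternary import discretize_matrix

__all__ = [
    "SimulationConfig",
    "PlantedCohortConfig",
    "SimulationReport",
    "generate_noise_cohort",
    "generate_planted_cohort",
    "run_null_simulation",
]

_PAIR_NAMES = (("A", "B"), ("A", "C"), ("B", "C"))


@dataclass(frozen=True)
class SimulationConfig:
    """Scale and knobs of the noise-null experiment.

    Defaults follow the study design: 14 virtual cancer types of 50 patients
    each, centroids compared on a random subset of 716 probes.
    """

    n_groups: int = 14
    n_patients_per_group: int = 50
    n_probes: int = 20000
    subset_size: int = 716
    threshold_factor: float = 0.43
    seed: int = 0
    n_seeds: int = 10
    clustering_method: str = "kmeans"

    def __post_init__(self) -> None:
        for name in ("n_groups", "n_patients_per_group", "n_probes", "subset_size", "n_seeds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.subset_size > self.n_probes:
            raise ValueError("subset_size cannot exceed n_probes")
        if self.n_groups < 2:
            raise ValueError("cross-type correlations need at least 2 groups")


@dataclass(frozen=True)
class PlantedCohortConfig:
    """Three-group cohort with planted, mutually distinct ternary prototypes.

    ``signal_fraction`` of the probes carry group-specific mean offsets: for
    each signal probe the three group means are a random permutation of
    ``(-1, 0, +1) * effect_size * noise_sd``, so every signal probe separates
    the groups and the three prototypes differ pairwise.  The remaining
    probes are pure noise.
    """

    n_samples: int = 150
    n_probes: int = 2000
    group_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    signal_fraction: float = 0.3
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.group_proportions, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("group_proportions must be three nonnegatives summing to 1")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.n_samples < 3 or self.n_probes < 1:
            raise ValueError("cohort too small")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class SimulationReport:
    """Per-seed and aggregate centroid correlations of the null experiment."""

    config: SimulationConfig
    per_seed_cross: tuple[float, ...]  # mean matched-label cross-type r, one per seed
    per_seed_within: tuple[dict, ...]  # per-seed {pair: mean within-type r}
    seeds: tuple[int, ...]

    @property
    def cross_type_mean_correlation(self) -> float:
        return float(np.mean(self.per_seed_cross))

    @property
    def mean_abs_cross_correlation(self) -> float:
        """Seed-averaged |mean cross-type correlation| — the headline null statistic."""
        return float(np.mean(np.abs(self.per_seed_cross)))

    @property
    def within_type_pair_correlations(self) -> dict[str, float]:
        return {
            f"{a}-{b}": float(np.mean([w[(a, b)] for w in self.per_seed_within]))
            for a, b in _PAIR_NAMES
        }


def generate_noise_cohort(
    n_samples: int,
    n_probes: int,
    seed: int,
    sample_prefix: str = "s",
    probe_prefix: str = "p",
) -> ExpressionMatrix:
    """Pure-noise cohort: i.i.d. standard-normal values, probes x samples."""
    if n_samples < 1 or n_probes < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_probes, n_samples))
    probes = tuple(f"{probe_prefix}{i:05d}" for i in range(n_probes))
    samples = tuple(f"{sample_prefix}{j:04d}" for j in range(n_samples))
    return ExpressionMatrix(probes, samples, values)


def _group_counts(n: int, proportions: tuple[float, float, float]) -> np.ndarray:
    """Largest-remainder apportionment; rejects empty groups."""
    p = np.asarray(proportions, dtype=float)
    raw = n * p
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    for i in np.argsort(-(raw - counts), kind="stable")[:rem]:
        counts[i] += 1
    if (counts == 0).any():
        raise ValueError(
            f"group proportions {tuple(p)} leave an empty group at n={n}; "
            "all three groups must be populated"
        )
    return counts


def generate_planted_cohort(cfg: PlantedCohortConfig) -> tuple[ExpressionMatrix, np.ndarray]:
    """Generate a planted three-group cohort and its ground-truth labels.

    Returns the expression matrix and an integer label array (0/1/2, aligned
    with the matrix's sample order).
    """
    rng = np.random.default_rng(cfg.seed)
    counts = _group_counts(cfg.n_samples, cfg.group_proportions)
    labels = np.repeat(np.arange(3), counts)
    n_signal = int(round(cfg.signal_fraction * cfg.n_probes))
    signal_rows = rng.choice(cfg.n_probes, size=n_signal, replace=False)
    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_probes, cfg.n_samples))
    base = np.array([-1.0, 0.0, 1.0]) * cfg.effect_size * cfg.noise_sd
    for row in signal_rows:
        group_means = rng.permutation(base)
        values[row, :] += group_means[labels]
    probes = tuple(f"p{i:05d}" for i in range(cfg.n_probes))
    samples = tuple(f"s{j:04d}" for j in range(cfg.n_samples))
    return ExpressionMatrix(probes, samples, values), labels


def _matched_label_correlations(c1: np.ndarray, c2: np.ndarray) -> list[float]:
    """Pearson r between same-row centroids of two models (rows = labels)."""
    out = []
    for row in range(3):
        a = c1[row] - c1[row].mean()
        b = c2[row] - c2[row].mean()
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        out.append(float((a * b).sum() / denom))
    return out


def run_null_simulation(cfg: SimulationConfig) -> SimulationReport:
    """Run the pure-noise experiment and collect centroid correlations.

    For each of ``n_seeds`` replicates: generate ``n_groups`` independent
    noise cohorts, take each through discretize -> cluster (3 groups) ->
    centroid averaging, restrict all centroids to one shared random subset
    of ``subset_size`` probes, then average the matched-label (size-ordered
    A/B/C) Pearson correlations over all cross-group pairs, and the
    within-group A-B/A-C/B-C correlations over groups.  Deterministic given
    ``cfg.seed``.
    """
    params = DiscretizationParams(threshold_factor=cfg.threshold_factor)
    master = np.random.default_rng(cfg.seed)
    seeds = tuple(int(s) for s in master.integers(0, 2**31 - 1, size=cfg.n_seeds))
    per_seed_cross: list[float] = []
    per_seed_within: list[dict] = []
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        subset = rng.choice(cfg.n_probes, size=cfg.subset_size, replace=False)
        centroids = []
        for _ in range(cfg.n_groups):
            cohort_seed = int(rng.integers(0, 2**31 - 1))
            cluster_seed = int(rng.integers(0, 2**31 - 1))
            x = generate_noise_cohort(cfg.n_patients_per_group, cfg.n_probes, cohort_seed)
            t = discretize_matrix(x, params)
            g = cluster_ternary(t, method=cfg.clustering_method, seed=cluster_seed)
            model = compute_centroids(
                t, g, DEFAULT_LABELS, threshold_factor=cfg.threshold_factor, seed=cluster_seed
            )
            centroids.append(model.centroids[:, subset])
        cross: list[float] = []
        for i in range(cfg.n_groups):
            for j in range(i + 1, cfg.n_groups):
                cross.extend(_matched_label_correlations(centroids[i], centroids[j]))
        within = {pair: [] for pair in _PAIR_NAMES}
        for c in centroids:
            for (la, lb), (ia, ib) in zip(_PAIR_NAMES, ((0, 1), (0, 2), (1, 2))):
                a = c[ia] - c[ia].mean()
                b = c[ib] - c[ib].mean()
                denom = np.sqrt((a * a).sum() * (b * b).sum())
                within[(la, lb)].append(float((a * b).sum() / denom))
        per_seed_cross.append(float(np.mean(cross)))
        per_seed_within.append({pair: float(np.mean(v)) for pair, v in within.items()})
    return SimulationReport(cfg, tuple(per_seed_cross), tuple(per_seed_within), seeds)
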