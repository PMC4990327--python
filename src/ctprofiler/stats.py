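"""Cohort-level statistics: cluster diameters and gene-subset robustness.

The "cluster diameter" of a CTP is the average Pearson correlation of its
assigned members with the CTP's own target vector — a tightness measure that
separates tumor cohorts (high) from normal-tissue cohorts (low).  The
subset-robustness analysis asks how much the per-sample CTP calls change
when the model is rebuilt from only a subset of probes (random or
functionally defined), keeping the full model's sample grouping fixed so
the subset effect is not confounded with clustering instability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .assign import assign_cohort, labels_to_dict, overlap
from .containers import (
    AssignmentResult,
    CTPModel,
    DiscretizationParams,
    ExpressionMatrix,
    GeneSubset,
)
from .model import compute_centroids, grouping_from_labels
from .ternary import discretize_matrix

__all__ = [
    "DiameterReport",
    "DiameterComparison",
    "RobustnessReport",
    "cluster_diameter",
    "compare_diameters",
    "subset_robustness",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiameterReport:
    """Per-CTP mean member-centroid correlation and member counts.

    ``mean_correlation[label]`` is None when no sample was assigned to that
    label (undefined, never reported as 0).
    """

    mean_correlation: Mapping[str, float | None]
    member_count: Mapping[str, int]
    cohort_tag: str = ""

    @property
    def n_samples(self) -> int:
        return sum(self.member_count.values())


@dataclass(frozen=True)
class DiameterComparison:
    statistic: float
    pvalue: float
    test: str


@dataclass(frozen=True)
class RobustnessReport:
    """Agreement between subset-model and full-model CTP calls, in percent."""

    subset_name: str
    subset_size: int
    similarity: float  # mean over replicates, percent in [0, 100]
    replicate_similarities: tuple[float, ...] = field(default_factory=tuple)
    similarity_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 100.0 + 1e-9:
            raise ValueError("similarity must be a percentage in [0, 100]")


def cluster_diameter(
    assignments: Sequence[AssignmentResult], model: CTPModel, cohort_tag: str = ""
) -> DiameterReport:
    """Average each CTP's members' winning correlations."""
    means: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    for label in model.labels:
        members = [a.winning_correlation for a in assignments if a.label == label]
        counts[label] = len(members)
        means[label] = float(np.mean(members)) if members else None
    return DiameterReport(means, counts, cohort_tag)


def compare_diameters(
    group1: Sequence[float], group2: Sequence[float], test: str = "welch"
) -> DiameterComparison:
    """Two-sided location test between two sets of per-cohort diameters.

    ``test`` is ``"welch"`` (unequal-variance t, default) or ``"ranksum"``
    (Wilcoxon rank-sum).  Degenerate input (all values identical within and
    across groups) is rejected rather than yielding a meaningless p-value.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 diameter values")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("degenerate input: all diameter values identical")
    if test == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
    elif test == "ranksum":
        res = sps.ranksums(a, b)
    else:
        raise ValueError(f"unknown test: {test!r} (use 'welch' or 'ranksum')")
    return DiameterComparison(float(res.statistic), float(res.pvalue), test)


def _one_subset_similarity(
    x: ExpressionMatrix,
    ids: Sequence[str],
    grouping: Mapping[str, str],
    reference: Mapping[str, str],
    params: DiscretizationParams,
    min_common_probes: int,
) -> float:
    x_sub = x.subset_probes(ids)
    t_sub = discretize_matrix(x_sub, params)
    g, labels = grouping_from_labels(t_sub, grouping)
    sub_model = compute_centroids(
        t_sub,
        g,
        labels,
        threshold_factor=params.threshold_factor,
        source_tag="subset",
        reorder_by_size=False,
    )
    calls = labels_to_dict(assign_cohort(x, sub_model, params, min_common_probes))
    return 100.0 * overlap(reference, calls).agreement_fraction


def subset_robustness(
    x: ExpressionMatrix,
    full_model: CTPModel,
    subset: GeneSubset | None = None,
    size: int | None = None,
    n_replicates: int = 1,
    seed: int = 0,
    params: DiscretizationParams | None = None,
    grouping: Mapping[str, str] | None = None,
    min_common_probes: int = 10,
) -> RobustnessReport:
    """How stable are the CTP calls when the model uses only a probe subset?

    Either a fixed ``subset`` (identifiers not present in ``x`` are warned
    about and dropped) or ``size`` plus ``n_replicates`` for random subsets
    drawn without replacement.  Subset centroids are rebuilt from the
    restricted ternary data using the full model's sample ``grouping``
    (defaulting to the full model's own assignments of ``x``, which also
    serve as the reference calls).  Similarity is the permutation-matched
    percent agreement between subset-model and full-model calls.
    """
    params = params or DiscretizationParams(threshold_factor=full_model.threshold_factor)
    reference = labels_to_dict(assign_cohort(x, full_model, params, min_common_probes))
    if grouping is None:
        grouping = reference
    if subset is not None:
        present = [p for p in x.probe_ids if p in subset.ids]
        dropped = len(subset) - len(present)
        if not present:
            raise ValueError(f"subset {subset.name!r} shares no probes with the matrix")
        if dropped:
            logger.warning(
                "subset %r: %d of %d identifiers absent from the matrix; intersecting",
                subset.name,
                dropped,
                len(subset),
            )
        if len(present) < 10:
            raise ValueError(f"subset {subset.name!r} has only {len(present)} usable probes (<10)")
        sim = _one_subset_similarity(x, present, grouping, reference, params, min_common_probes)
        return RobustnessReport(subset.name, len(present), sim, (sim,), None)
    if size is None:
        raise ValueError("provide either a GeneSubset or a random subset size")
    if size < 10 or size > x.n_probes:
        raise ValueError(f"random subset size {size} outside [10, {x.n_probes}]")
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_replicates):
        idx = rng.choice(x.n_probes, size=size, replace=False)
        ids = [x.probe_ids[i] for i in idx]
        sims.append(_one_subset_similarity(x, ids, grouping, reference, params, min_common_probes))
    sims_arr = np.asarray(sims)
    sd = float(sims_arr.std(ddof=1)) if len(sims) > 1 else None
    return RobustnessReport(
        f"random-{size}", size, float(sims_arr.mean()), tuple(sims), sd
    )
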