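"""Correlation-based CTP assignment, transfer and overlap scoring.

A sample is assigned to the CTP whose target vector has the highest Pearson
correlation with the sample's ternary profile.  New cohorts — including
cohorts of a different cancer type — are always discretized against their
OWN per-probe means and sigmas before assignment; that is what makes the
transfer insensitive to tissue-of-origin expression-level differences.
Probe matching between model and cohort is by identifier intersection in
model order; model probes absent from the cohort are dropped rather than
zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .containers import (
    AssignmentResult,
    CTPModel,
    DiscretizationParams,
    ExpressionMatrix,
)
from .ternary import discretize_matrix

__all__ = [
    "assign_sample",
    "assign_cohort",
    "overlap",
    "reverse_transfer",
    "OverlapReport",
    "labels_to_dict",
]

#: Below this many shared probes a model transfer is refused: the method
#: assumes near-complete probe overlap between model and cohort.
DEFAULT_MIN_COMMON_PROBES = 100


@dataclass(frozen=True)
class OverlapReport:
    """Best-permutation agreement between two 3-group labelings.

    ``permutation`` maps test labels to the gold labels they were matched
    with; ``agreement_fraction`` is the fraction of samples whose mapped test
    label equals their gold label, maximized over label bijections.
    ``confusion`` has gold labels as rows and (unmapped) test labels as
    columns.
    """

    n_samples: int
    agreement_fraction: float
    permutation: Mapping[str, str]
    confusion: pd.DataFrame

    def __post_init__(self) -> None:
        if not 0.0 <= self.agreement_fraction <= 1.0:
            raise ValueError("agreement_fraction outside [0, 1]")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = float(np.sqrt((a * a).sum()))
    nb = float(np.sqrt((b * b).sum()))
    if na == 0.0 or nb == 0.0:
        raise ZeroDivisionError
    return float(np.clip((a * b).sum() / (na * nb), -1.0, 1.0))


def assign_sample(
    profile: pd.Series,
    model: CTPModel,
    min_common_probes: int = DEFAULT_MIN_COMMON_PROBES,
) -> AssignmentResult:
    """Assign one ternary profile to the best-correlated CTP.

    Parameters
    ----------
    profile
        Ternary codes indexed by probe id (a ``pandas.Series``; the name, if
        set, becomes the sample id).
    model
        CTP model supplying the three target vectors.
    min_common_probes
        Refuse the assignment when the model/profile probe intersection is
        smaller than this.

    Correlations are computed over the probe intersection in model probe
    order.  Exact ties are broken toward the first label in model order and
    flagged on the result.
    """
    common = [p for p in model.probe_ids if p in profile.index]
    if len(common) < max(2, min_common_probes):
        raise ValueError(
            f"only {len(common)} probes shared between profile and model "
            f"(minimum {max(2, min_common_probes)}); transfer assumes near-complete overlap"
        )
    v = profile.loc[common].to_numpy(dtype=float)
    if np.ptp(v) == 0:
        raise ValueError(
            "undefined correlation: profile is constant on the common probe support"
        )
    corrs: dict[str, float] = {}
    for label in model.labels:
        c = model.centroid(label).loc[common].to_numpy(dtype=float)
        try:
            corrs[label] = _pearson(v, c)
        except ZeroDivisionError:
            raise ValueError(
                f"undefined correlation: centroid {label!r} is constant on the common support"
            ) from None
    ranked = sorted(model.labels, key=lambda l: -corrs[l])
    # stable sort keeps model label order among exact ties
    winner, runner_up = ranked[0], ranked[1]
    margin = corrs[winner] - corrs[runner_up]
    return AssignmentResult(
        sample_id=str(profile.name) if profile.name is not None else "",
        label=winner,
        correlations=corrs,
        margin=margin,
        tie=margin == 0.0,
    )


def assign_cohort(
    x: ExpressionMatrix,
    model: CTPModel,
    params: DiscretizationParams | None = None,
    min_common_probes: int = DEFAULT_MIN_COMMON_PROBES,
) -> list[AssignmentResult]:
    """Discretize a cohort against its own means/sigmas and assign each sample."""
    params = params or DiscretizationParams(threshold_factor=model.threshold_factor)
    t = discretize_matrix(x, params)
    frame = t.to_frame()
    results = []
    for sample in t.sample_ids:
        results.append(assign_sample(frame[sample], model, min_common_probes))
    return results


def labels_to_dict(assignments: Sequence[AssignmentResult]) -> dict[str, str]:
    """Collapse assignment results to a sample -> label mapping."""
    return {a.sample_id: a.label for a in assignments}


def overlap(gold: Mapping[str, str], test: Mapping[str, str]) -> OverlapReport:
    """Best-permutation agreement between two labelings of the same samples.

    All bijections between the two (at most 3-element) label sets are
    considered and the one maximizing agreement is reported, since cluster
    labels are arbitrary.  Symmetric in its arguments up to inversion of the
    reported permutation.
    """
    gset, tset = set(gold), set(test)
    if gset != tset:
        only_gold = sorted(gset - tset)
        only_test = sorted(tset - gset)
        raise ValueError(
            f"sample sets differ: {len(only_gold)} only in gold (e.g. {only_gold[:3]}), "
            f"{len(only_test)} only in test (e.g. {only_test[:3]})"
        )
    samples = sorted(gset)
    gold_labels = sorted({gold[s] for s in samples})
    test_labels = sorted({test[s] for s in samples})
    if len(gold_labels) > 3 or len(test_labels) > 3:
        raise ValueError("labelings with more than 3 groups are not CTP labelings")
    confusion = pd.DataFrame(0, index=gold_labels, columns=test_labels, dtype=int)
    for s in samples:
        confusion.loc[gold[s], test[s]] += 1
    # Hungarian matching == max over label bijections for 3x3 confusions
    cost = -confusion.to_numpy()
    rows, cols = linear_sum_assignment(cost)
    matched = int(-cost[rows, cols].sum())
    perm = {test_labels[c]: gold_labels[r] for r, c in zip(rows, cols)}
    return OverlapReport(
        n_samples=len(samples),
        agreement_fraction=matched / len(samples),
        permutation=perm,
        confusion=confusion,
    )


def reverse_transfer(
    source: ExpressionMatrix,
    target: ExpressionMatrix,
    target_gold: Mapping[str, str],
    method: str = "kmeans",
    seed: int = 0,
    params: DiscretizationParams | None = None,
    min_common_probes: int = DEFAULT_MIN_COMMON_PROBES,
) -> OverlapReport:
    """Cluster a fresh model on ``source``, assign ``target``, score overlap.

    This is the concept-transfer experiment: CTPs built on one cancer type's
    cohort classify another cohort, and the result is compared with that
    cohort's own gold grouping (permutation-matched).
    """
    from .model import build_model

    model = build_model(source, params=params, method=method, seed=seed, source_tag="source")
    assignments = assign_cohort(target, model, params=params, min_common_probes=min_common_probes)
    return overlap(target_gold, labels_to_dict(assignments))
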