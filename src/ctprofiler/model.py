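"""Building CTP models: clustering ternary profiles and averaging per group.

Samples are clustered as points in probe space using their ternary codes as
coordinates (discretize first, cluster second).  k = 3 is fixed: the whole
CTP concept is three recurring groups.  Two clustering back-ends are
offered — k-means (scikit-learn, best of ``n_restarts`` by inertia) and a
deterministic 1x3 self-organizing map where each map unit is one group.
The per-group arithmetic means of the ternary codes are the CTP "target
vectors"; their entries necessarily lie in [-1, 1].

Freshly clustered groups are named A/B/C in order of decreasing size (ties
broken by the lexicographically smallest member sample id) so that reruns
and cross-method comparisons are reproducible; the names carry no survival
semantics outside the original cohort.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .containers import (
    DEFAULT_LABELS,
    CTPModel,
    DiscretizationParams,
    ExpressionMatrix,
    GroupingResult,
    TernaryMatrix,
)
from .ternary import discretize_matrix

__all__ = ["cluster_ternary", "compute_centroids", "build_model", "grouping_from_labels"]


def _som_1x3(
    points: np.ndarray,
    seed: int,
    n_epochs: int = 30,
    lr_start: float = 0.5,
    lr_end: float = 0.01,
    radius_start: float = 1.0,
    radius_end: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Train a 1x3 self-organizing map and return (unit index per point, QE).

    Units sit on a line at coordinates 0, 1, 2; the neighborhood is Gaussian
    in unit distance with linearly decaying radius, and the learning rate
    decays linearly over a fixed epoch count.  Weights are initialized from
    three distinct random input points.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = points.shape[0]
    init = rng.choice(n, size=3, replace=False)
    weights = points[init].astype(float).copy()
    unit_pos = np.arange(3.0)
    total_steps = n_epochs
    for epoch in range(n_epochs):
        frac = epoch / max(1, total_steps - 1)
        lr = lr_start + (lr_end - lr_start) * frac
        radius = radius_start + (radius_end - radius_start) * frac
        order = rng.permutation(n)
        for i in order:
            p = points[i]
            bmu = int(np.argmin(((weights - p) ** 2).sum(axis=1)))
            h = np.exp(-((unit_pos - unit_pos[bmu]) ** 2) / (2.0 * radius**2))
            weights += lr * h[:, None] * (p - weights)
    d2 = ((points[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
    bmus = d2.argmin(axis=1)
    qe = float(np.sqrt(d2[np.arange(n), bmus]).mean())
    return bmus, qe


def cluster_ternary(
    t: TernaryMatrix,
    method: str = "kmeans",
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> GroupingResult:
    """Partition samples into three groups by their ternary profiles.

    Deterministic given ``(method, seed, n_restarts)``.  Raises if any group
    ends up empty (the model contract requires three populated groups) or if
    ``k != 3``.
    """
    if k != 3:
        raise ValueError("the CTP model is defined for exactly 3 groups; k must be 3")
    if t.n_samples < 3:
        raise ValueError(f"need at least 3 samples to form 3 groups, got {t.n_samples}")
    points = t.codes.T.astype(float)  # samples as points in probe space
    if method == "kmeans":
        km = KMeans(n_clusters=3, n_init=n_restarts, random_state=seed)
        idx = km.fit_predict(points)
        inertia = float(km.inertia_)
    elif method == "som":
        idx, inertia = _som_1x3(points, seed=seed, n_epochs=max(10, 3 * n_restarts))
    else:
        raise ValueError(f"unknown clustering method: {method!r} (use 'kmeans' or 'som')")
    return GroupingResult(t.sample_ids, idx, inertia, method=method)


def _canonical_group_order(t: TernaryMatrix, g: GroupingResult) -> list[int]:
    """Group indices ordered by decreasing size, then smallest member id."""
    keys = []
    for grp in range(3):
        members = [t.sample_ids[i] for i in np.flatnonzero(g.group_index == grp)]
        keys.append((-len(members), min(members), grp))
    return [grp for _, _, grp in sorted(keys)]


def compute_centroids(
    t: TernaryMatrix,
    g: GroupingResult,
    labels: Sequence[str] = DEFAULT_LABELS,
    *,
    threshold_factor: float = 0.43,
    seed: int | None = None,
    source_tag: str = "",
    reorder_by_size: bool = True,
) -> CTPModel:
    """Average the ternary codes per group into the three CTP target vectors.

    With ``reorder_by_size`` (the default for freshly clustered groups) the
    first label goes to the largest group; with it off, ``labels[i]`` names
    group index ``i`` as-is (used when the grouping carries a priori labels).
    """
    if tuple(g.sample_ids) != tuple(t.sample_ids):
        raise ValueError("grouping does not cover the ternary matrix's samples")
    order = _canonical_group_order(t, g) if reorder_by_size else [0, 1, 2]
    centroids = np.empty((3, t.n_probes))
    for row, grp in enumerate(order):
        members = np.flatnonzero(g.group_index == grp)
        if members.size == 0:
            raise ValueError(f"group {grp} is empty")
        centroids[row] = t.codes[:, members].mean(axis=1)
    return CTPModel(
        labels=tuple(labels),
        probe_ids=t.probe_ids,
        centroids=centroids,
        threshold_factor=threshold_factor,
        clustering_method=g.method,
        seed=seed,
        source_tag=source_tag,
    )


def grouping_from_labels(
    t: TernaryMatrix, groups: Mapping[str, str], labels: Sequence[str] | None = None
) -> tuple[GroupingResult, tuple[str, str, str]]:
    """Turn a sample -> group-name mapping into a GroupingResult.

    Returns the grouping plus the ordered label tuple so that group index i
    corresponds to label i.  The mapping must cover every sample of ``t``
    and realize exactly three group names.
    """
    missing = [s for s in t.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"predefined groups missing {len(missing)} sample(s), e.g. {missing[0]!r}")
    if labels is None:
        labels = tuple(sorted({groups[s] for s in t.sample_ids}))
    labels = tuple(labels)
    if len(labels) != 3:
        raise ValueError(f"predefined groups realize {len(labels)} labels; exactly 3 required")
    pos = {lab: i for i, lab in enumerate(labels)}
    try:
        idx = np.array([pos[groups[s]] for s in t.sample_ids])
    except KeyError as e:
        raise ValueError(f"group name {e.args[0]!r} not among labels {labels}") from None
    return GroupingResult(t.sample_ids, idx, inertia=float("nan"), method="predefined"), labels


def build_model(
    x: ExpressionMatrix,
    params: DiscretizationParams | None = None,
    method: str = "kmeans",
    seed: int = 0,
    n_restarts: int = 10,
    labels: Sequence[str] = DEFAULT_LABELS,
    predefined_groups: Mapping[str, str] | None = None,
    source_tag: str = "",
) -> CTPModel:
    """Full model pipeline: center -> discretize -> group -> average.

    If ``predefined_groups`` maps every sample id to one of three group
    names, clustering is bypassed and those groups define the centroids
    (the a-priori-labels path); otherwise the ternary profiles are clustered
    with ``method``.
    """
    params = params or DiscretizationParams()
    t = discretize_matrix(x, params)
    if predefined_groups is not None:
        g, ordered_labels = grouping_from_labels(t, predefined_groups)
        return compute_centroids(
            t,
            g,
            ordered_labels,
            threshold_factor=params.threshold_factor,
            seed=None,
            source_tag=source_tag,
            reorder_by_size=False,
        )
    g = cluster_ternary(t, method=method, seed=seed, n_restarts=n_restarts)
    return compute_centroids(
        t,
        g,
        labels,
        threshold_factor=params.threshold_factor,
        seed=seed,
        source_tag=source_tag,
    )
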