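"""De Finetti (ternary-plot) mapping of CTP correlation triples.

Each sample's three centroid correlations are converted into a barycentric
weight triple and placed in an equilateral triangle whose vertices stand for
the three CTPs.  Strongly correlated samples sit near "their" vertex; weakly
correlated samples (normal tissue, pure noise) fall near the center.

Convention: negative correlations are clamped to zero, the clamped triple is
normalized into proportions, and the point is pulled toward the triangle
center by the overall correlation strength ``s = min(1, sum of clamped
correlations)``.  Retaining the magnitude this way is what sends weakly
correlated samples to the center — pure proportions would amplify tiny noise
correlations into arbitrary triangle positions.  An all-nonpositive triple
maps exactly to the center.  Vertex layout is fixed — first label lower-left
(0,0), second lower-right (1,0), third top (0.5, sqrt(3)/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import AssignmentResult

__all__ = [
    "TRIANGLE_VERTICES",
    "TRIANGLE_CENTER",
    "DeFinettiPoint",
    "to_barycentric",
    "to_cartesian",
    "map_cohort",
    "points_frame",
    "plot_points",
]

TRIANGLE_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])
TRIANGLE_CENTER = TRIANGLE_VERTICES.mean(axis=0)  # (0.5, sqrt(3)/6)


@dataclass(frozen=True)
class DeFinettiPoint:
    sample_id: str
    weights: tuple[float, float, float]
    xy: tuple[float, float]
    label: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a probability triple")


def to_barycentric(correlations: Sequence[float]) -> tuple[float, float, float]:
    """Correlation triple -> probability triple over the three CTP vertices.

    Negatives are clamped to 0 and the clamped values normalized into
    proportions ``p``; the result is ``s*p + (1-s)*(1/3, 1/3, 1/3)`` with
    strength ``s = min(1, sum(clamped))``, so strongly correlated samples
    approach their vertex while weakly correlated ones (normal tissue, pure
    noise) stay near the center.  When no correlation is positive the sample
    sits exactly at the center.
    """
    r = np.asarray(correlations, dtype=float)
    if r.shape != (3,):
        raise ValueError("expected exactly three correlations")
    if (np.abs(r) > 1 + 1e-9).any():
        raise ValueError("correlations must lie in [-1, 1]")
    w = np.clip(r, 0.0, None)
    total = w.sum()
    if total <= 0.0:
        return (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    strength = min(1.0, total)
    w = strength * (w / total) + (1.0 - strength) / 3.0
    return (float(w[0]), float(w[1]), float(w[2]))


def to_cartesian(weights: Sequence[float]) -> tuple[float, float]:
    """Barycentric triple -> 2-D position inside the reference triangle."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("expected a probability triple")
    xy = w @ TRIANGLE_VERTICES
    return (float(xy[0]), float(xy[1]))


def map_cohort(assignments: Sequence[AssignmentResult], labels=None) -> list[DeFinettiPoint]:
    """One triangle point per assigned sample, weight order following ``labels``.

    ``labels`` defaults to the sorted label set of the assignments' model;
    pass the model's label tuple to fix vertex order explicitly.
    """
    if not assignments:
        return []
    if labels is None:
        labels = tuple(sorted(assignments[0].correlations))
    points = []
    for a in assignments:
        r = [a.correlations[l] for l in labels]
        w = to_barycentric(r)
        points.append(DeFinettiPoint(a.sample_id, w, to_cartesian(w), a.label))
    return points


def points_frame(points: Sequence[DeFinettiPoint], labels=("A", "B", "C")) -> pd.DataFrame:
    """Plot-ready table: sample_id, the three weights, x, y, label."""
    rows = [
        {
            "sample_id": p.sample_id,
            f"w_{labels[0]}": p.weights[0],
            f"w_{labels[1]}": p.weights[1],
            f"w_{labels[2]}": p.weights[2],
            "x": p.xy[0],
            "y": p.xy[1],
            "label": p.label,
        }
        for p in points
    ]
    return pd.DataFrame(rows)


def plot_points(points: Sequence[DeFinettiPoint], path: str, labels=("A", "B", "C")) -> None:
    """Render the triangle with one dot per sample, colored by CTP label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5.5))
    tri = np.vstack([TRIANGLE_VERTICES, TRIANGLE_VERTICES[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    offsets = [(-0.03, -0.04), (0.03, -0.04), (0.0, 0.04)]
    for (vx, vy), lab, (dx, dy) in zip(TRIANGLE_VERTICES, labels, offsets):
        ax.text(vx + dx, vy + dy, lab, ha="center", va="center", fontsize=12)
    by_label: dict[str, list[DeFinettiPoint]] = {}
    for p in points:
        by_label.setdefault(p.label, []).append(p)
    for lab in sorted(by_label):
        xy = np.array([p.xy for p in by_label[lab]])
        ax.scatter(xy[:, 0], xy[:, 1], s=12, alpha=0.7, label=lab)
    ax.legend(loc="upper right", frameon=False)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
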