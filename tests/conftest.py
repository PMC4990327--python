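"""Shared fixtures: prototype cohorts and the standard planted cohort."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from ctprofiler import (
    DiscretizationParams,
    ExpressionMatrix,
    TernaryMatrix,
    build_model,
    generate_planted_cohort,
)
from ctprofiler.simulate import PlantedCohortConfig

GROUP_NAMES = ("A", "B", "C")


def _prototype_vectors(block: int = 50) -> np.ndarray:
    """Three mutually orthogonal ternary prototypes over 6*block probes.

    Prototype i is +1 on its own positive block and -1 on its own negative
    block, 0 elsewhere, so the pairwise dot products are exactly zero.
    """
    protos = np.zeros((3, 6 * block))
    for i in range(3):
        protos[i, 2 * i * block : (2 * i + 1) * block] = 1
        protos[i, (2 * i + 1) * block : (2 * i + 2) * block] = -1
    return protos


@pytest.fixture(scope="session")
def prototype_codes() -> tuple[TernaryMatrix, np.ndarray]:
    """30 samples: 10 exact copies of each orthogonal ternary prototype."""
    protos = _prototype_vectors()
    codes = np.repeat(protos, 10, axis=0).T  # probes x samples
    labels = np.repeat(np.arange(3), 10)
    probe_ids = tuple(f"p{i:04d}" for i in range(protos.shape[1]))
    sample_ids = tuple(f"s{j:02d}" for j in range(30))
    return TernaryMatrix(probe_ids, sample_ids, codes.astype(int)), labels


@pytest.fixture(scope="session")
def prototype_expression() -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Zero-noise expression cohort whose discretization is exactly known.

    Each of the six 50-probe blocks carries one permutation of (1, 0, -1) as
    the three group expression levels, so after centering every probe has
    10 samples above, 10 at and 10 below the mean and the ternary codes
    reproduce the planted prototype exactly.  Returns (matrix, labels,
    expected ternary prototypes as a 3 x n_probes array).
    """
    block = 50
    pats = list(permutations((1.0, 0.0, -1.0)))  # 6 group-level patterns
    protos = np.zeros((3, 6 * block))
    for b, pat in enumerate(pats):
        for g in range(3):
            protos[g, b * block : (b + 1) * block] = pat[g]
    labels = np.repeat(np.arange(3), 10)
    values = protos[labels].T  # probes x samples, zero noise
    probe_ids = tuple(f"p{i:04d}" for i in range(6 * block))
    sample_ids = tuple(f"s{j:02d}" for j in range(30))
    return ExpressionMatrix(probe_ids, sample_ids, values), labels, protos


@pytest.fixture(scope="session")
def planted():
    """The standard planted cohort: 150 samples, 2000 probes, signal 0.3, effect 3."""
    cfg = PlantedCohortConfig()
    x, truth = generate_planted_cohort(cfg)
    gold = {s: GROUP_NAMES[g] for s, g in zip(x.sample_ids, truth)}
    return x, truth, gold


@pytest.fixture(scope="session")
def planted_model(planted):
    """Full CTP model built on the standard planted cohort from its true groups."""
    x, _, gold = planted
    return build_model(x, DiscretizationParams(), predefined_groups=gold)


@pytest.fixture()
def small_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        ("p1", "p2", "p3"),
        ("s1", "s2"),
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )
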