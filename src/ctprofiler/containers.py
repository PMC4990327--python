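"""Core data containers for ternary expression profiling.

All matrices follow one orientation: probes (microarray probe sets or genes)
in rows, samples (patients) in columns.  Containers are frozen dataclasses
that validate their invariants on construction, so downstream code can rely
on identifiers being unique, grids being finite and shapes being consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DeviationMatrix",
    "TernaryMatrix",
    "GeneSubset",
    "DiscretizationParams",
    "CTPModel",
    "GroupingResult",
    "AssignmentResult",
    "DEFAULT_LABELS",
]

DEFAULT_LABELS: tuple[str, str, str] = ("A", "B", "C")


def _find_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


def _check_ids(ids: Sequence[str], kind: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if not ids:
        raise ValueError(f"empty {kind} identifier list")
    dup = _find_duplicate(ids)
    if dup is not None:
        raise ValueError(f"duplicate {kind} identifier: {dup!r}")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized log2 expression values, probes x samples.

    Parameters
    ----------
    probe_ids
        Unique probe/gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    values
        Real-valued grid of shape ``(len(probe_ids), len(sample_ids))``;
        every entry must be finite (reject or impute missing values before
        constructing the matrix).
    """

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", _check_ids(self.probe_ids, "probe"))
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample"))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at probe "
                f"{self.probe_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "values", values)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.probe_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(dtype=float))

    def subset_probes(self, ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given probes, keeping this matrix's row order."""
        wanted = set(ids)
        keep = [i for i, p in enumerate(self.probe_ids) if p in wanted]
        if not keep:
            raise ValueError("probe subset has empty intersection with the matrix")
        return ExpressionMatrix(
            tuple(self.probe_ids[i] for i in keep), self.sample_ids, self.values[keep, :]
        )


@dataclass(frozen=True)
class DeviationMatrix:
    """Per-probe deviations from the cohort mean, plus the per-probe sigma.

    ``deviations[g, s]`` is sample *s*'s log2 expression of probe *g* minus
    the mean of probe *g* over all samples of the cohort; every row therefore
    sums to zero.  ``probe_sigma`` is the standard deviation of each probe's
    deviations (``std_mode`` records whether the sample, n-1, or population,
    n, estimator was used).
    """

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    deviations: np.ndarray
    probe_sigma: np.ndarray
    std_mode: str = "sample"

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        dev = np.asarray(self.deviations, dtype=float)
        sig = np.asarray(self.probe_sigma, dtype=float)
        if dev.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("deviation grid shape mismatch")
        if sig.shape != (len(self.probe_ids),):
            raise ValueError("probe_sigma length mismatch")
        if (sig < 0).any():
            raise ValueError("negative probe sigma")
        scale = max(1.0, float(np.abs(dev).max(initial=0.0)))
        if np.abs(dev.sum(axis=1)).max(initial=0.0) > 1e-9 * scale * len(self.sample_ids):
            raise ValueError("deviations are not mean-centered")
        object.__setattr__(self, "deviations", dev)
        object.__setattr__(self, "probe_sigma", sig)


@dataclass(frozen=True)
class TernaryMatrix:
    """Discretized expression codes in {-1, 0, +1}, probes x samples."""

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", _check_ids(self.probe_ids, "probe"))
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample"))
        codes = np.asarray(self.codes)
        if codes.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("codes grid shape mismatch")
        if not np.isin(codes, (-1, 0, 1)).all():
            raise ValueError("ternary codes must be -1, 0 or +1")
        object.__setattr__(self, "codes", codes.astype(np.int8))

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_profile(self, sample_id: str) -> pd.Series:
        """One sample's ternary profile as a probe-indexed series."""
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None
        return pd.Series(self.codes[:, j].astype(float), index=list(self.probe_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=list(self.probe_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class GeneSubset:
    """A named set of probe/gene identifiers (order-independent membership)."""

    ids: frozenset[str]
    name: str = "subset"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", frozenset(str(i) for i in self.ids))
        if not self.ids:
            raise ValueError("gene subset is empty")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class DiscretizationParams:
    """Parameters of the three-level discretization.

    ``threshold_factor`` is the cut expressed as a fraction of each probe's
    standard deviation; the default 0.43 makes the three codes equally
    frequent under Gaussian deviations (it is the standard-normal upper
    tercile, see :func:`ctprofiler.ternary.equal_tercile_threshold`).
    """

    threshold_factor: float = 0.43
    std_mode: str = "sample"

    def __post_init__(self) -> None:
        if not self.threshold_factor > 0:
            raise ValueError("threshold_factor must be positive")
        if self.std_mode not in ("sample", "population"):
            raise ValueError("std_mode must be 'sample' or 'population'")

    @property
    def ddof(self) -> int:
        return 1 if self.std_mode == "sample" else 0


@dataclass(frozen=True)
class CTPModel:
    """Three CTP target vectors over an ordered probe list.

    Each centroid is the per-probe mean of the ternary codes of one group's
    member samples, so entries lie in [-1, 1].  Provenance fields record how
    the model was built so a serialized model is self-describing.
    """

    labels: tuple[str, str, str]
    probe_ids: tuple[str, ...]
    centroids: np.ndarray  # shape (3, n_probes), rows ordered like `labels`
    threshold_factor: float = 0.43
    clustering_method: str = "predefined"
    seed: int | None = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != 3 or len(set(labels)) != 3:
            raise ValueError("a CTP model has exactly 3 distinct labels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "probe_ids", _check_ids(self.probe_ids, "probe"))
        cent = np.asarray(self.centroids, dtype=float)
        if cent.shape != (3, len(self.probe_ids)):
            raise ValueError(
                f"centroid grid shape {cent.shape} does not match (3, {len(self.probe_ids)})"
            )
        if not np.isfinite(cent).all():
            raise ValueError("non-finite centroid entry")
        if (np.abs(cent) > 1 + 1e-12).any():
            bad = float(cent[np.abs(cent) > 1 + 1e-12][0])
            raise ValueError(f"centroid entry {bad} outside [-1, 1]")
        object.__setattr__(self, "centroids", cent)
        if self.clustering_method not in ("kmeans", "som", "predefined"):
            raise ValueError(f"unknown clustering_method: {self.clustering_method!r}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def centroid(self, label: str) -> pd.Series:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown CTP label: {label!r}") from None
        return pd.Series(self.centroids[i], index=list(self.probe_ids))


@dataclass(frozen=True)
class GroupingResult:
    """A hard partition of samples into three groups plus a fit diagnostic.

    ``inertia`` is the method-dependent objective: within-cluster sum of
    squares for k-means, mean quantization error for the SOM.
    """

    sample_ids: tuple[str, ...]
    group_index: np.ndarray  # per-sample group in {0, 1, 2}
    inertia: float
    method: str = "kmeans"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample"))
        idx = np.asarray(self.group_index, dtype=int)
        if idx.shape != (len(self.sample_ids),):
            raise ValueError("group_index length mismatch")
        if not np.isin(idx, (0, 1, 2)).all():
            raise ValueError("group indices must be 0, 1 or 2")
        missing = sorted(set(range(3)) - set(idx.tolist()))
        if missing:
            raise ValueError(
                f"empty group(s) {missing}: all three groups must be populated; "
                "try a different seed"
            )
        object.__setattr__(self, "group_index", idx)

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_index, minlength=3)


@dataclass(frozen=True)
class AssignmentResult:
    """One sample's CTP call: the three centroid correlations and the winner."""

    sample_id: str
    label: str
    correlations: Mapping[str, float]
    margin: float
    tie: bool = False

    def __post_init__(self) -> None:
        corr = dict(self.correlations)
        if self.label not in corr:
            raise ValueError("assigned label has no correlation entry")
        for lab, r in corr.items():
            if not -1 - 1e-12 <= r <= 1 + 1e-12:
                raise ValueError(f"correlation {r} for {lab!r} outside [-1, 1]")
        top = max(corr.values())
        if corr[self.label] < top - 1e-12:
            raise ValueError("assigned label is not the maximal correlation")
        if self.margin < -1e-12:
            raise ValueError("negative winning margin")
        object.__setattr__(self, "correlations", corr)

    @property
    def winning_correlation(self) -> float:
        return self.correlations[self.label]
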