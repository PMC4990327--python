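"""Readers and writers for the package's plain-text formats.

Formats (all UTF-8, diff-able):

* Expression / ternary matrix — TSV or CSV; header row of sample ids, first
  column probe ids, numeric body.
* Gene subset — one identifier per line; blank lines and ``#`` comments
  ignored.
* CTP model — a single JSON document with an explicit schema version and
  full provenance (threshold factor, clustering method, seed, source tag).
* Assignment table — TSV with columns sample_id, label, r_<label> per model
  label, margin.
* Label table — two-column TSV (sample_id, label), used for gold groupings.

Readers never silently drop rows or columns: counts in equal counts out, or
a hard error names the offending identifier or cell.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AssignmentResult,
    CTPModel,
    ExpressionMatrix,
    GeneSubset,
    TernaryMatrix,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_ternary_matrix",
    "write_ternary_matrix",
    "read_gene_subset",
    "read_ctp_model",
    "write_ctp_model",
    "read_labels",
    "write_labels",
    "read_assignments",
    "write_assignments",
]

MODEL_SCHEMA_VERSION = 1

logger = logging.getLogger(__name__)


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix (no probes or no samples)")
    for axis, kind in ((df.index, "probe"), (df.columns, "sample")):
        dup = axis[axis.duplicated()]
        if len(dup):
            raise ValueError(f"{path}: duplicate {kind} identifier: {dup[0]!r}")
    return df


def _coerce_numeric(df: pd.DataFrame, path: Path, impute_row_mean: bool) -> pd.DataFrame:
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    missing = num.isna()
    if missing.to_numpy().any():
        if not impute_row_mean:
            i, j = np.argwhere(missing.to_numpy())[0]
            raise ValueError(
                f"{path}: missing value at probe {df.index[i]!r}, sample "
                f"{df.columns[j]!r} (pass impute_row_mean=True to impute)"
            )
        row_means = num.mean(axis=1)
        if row_means.isna().any():
            probe = row_means.index[row_means.isna()][0]
            raise ValueError(f"{path}: probe {probe!r} has no observed values to impute from")
        num = num.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    return num


def read_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    transpose: bool = False,
    impute_row_mean: bool = False,
) -> ExpressionMatrix:
    """Read a probes-x-samples expression matrix from delimited text.

    ``transpose`` accommodates samples-in-rows files; ``impute_row_mean``
    replaces missing cells with the probe's mean across samples (the neutral
    choice: an imputed cell has deviation 0, hence ternary code 0).  Missing
    values are otherwise a hard error, as are duplicate identifiers and
    non-numeric cells.
    """
    df = _read_table(path, delimiter)
    if transpose:
        df = df.T
    df = _coerce_numeric(df, Path(path), impute_row_mean)
    return ExpressionMatrix.from_frame(df)


def write_expression_matrix(
    x: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    x.to_frame().to_csv(path, sep=delimiter, index_label="probe_id")


def read_ternary_matrix(path: str | Path, delimiter: str = "\t") -> TernaryMatrix:
    df = _read_table(path, delimiter)
    df = _coerce_numeric(df, Path(path), impute_row_mean=False)
    vals = df.to_numpy()
    if not np.isin(vals, (-1, 0, 1)).all():
        i, j = np.argwhere(~np.isin(vals, (-1, 0, 1)))[0]
        raise ValueError(
            f"{path}: ternary code {vals[i, j]!r} at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r} is not -1, 0 or +1"
        )
    return TernaryMatrix(tuple(map(str, df.index)), tuple(map(str, df.columns)), vals.astype(np.int8))


def write_ternary_matrix(t: TernaryMatrix, path: str | Path, delimiter: str = "\t") -> None:
    t.to_frame().to_csv(path, sep=delimiter, index_label="probe_id")


def read_gene_subset(path: str | Path, name: str | None = None) -> GeneSubset:
    """Read one identifier per line; ``#`` comments and blanks are skipped.

    Duplicate identifiers are collapsed with a logged warning.
    """
    path = Path(path)
    ids: list[str] = []
    for line in path.read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        ids.append(token)
    if not ids:
        raise ValueError(f"{path}: no identifiers after filtering comments/blanks")
    unique = set(ids)
    if len(unique) < len(ids):
        logger.warning("%s: %d duplicate identifier(s) collapsed", path, len(ids) - len(unique))
    return GeneSubset(frozenset(unique), name or path.stem)


def write_ctp_model(model: CTPModel, path: str | Path) -> None:
    """Serialize a model losslessly to versioned JSON."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "labels": list(model.labels),
        "probe_ids": list(model.probe_ids),
        "centroids": {lab: model.centroids[i].tolist() for i, lab in enumerate(model.labels)},
        "threshold_factor": model.threshold_factor,
        "clustering_method": model.clustering_method,
        "seed": model.seed,
        "source_tag": model.source_tag,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_ctp_model(path: str | Path) -> CTPModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: truncated or invalid model file ({e})") from None
    if not isinstance(doc, dict) or doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported model schema version {doc.get('schema_version')!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    required = {"labels", "probe_ids", "centroids", "threshold_factor", "clustering_method"}
    missing = required - doc.keys()
    if missing:
        raise ValueError(f"{path}: model file missing field(s) {sorted(missing)}")
    labels = doc["labels"]
    cent_map = doc["centroids"]
    absent = [lab for lab in labels if lab not in cent_map]
    if absent:
        raise ValueError(f"{path}: model file missing centroid(s) for {absent}")
    centroids = np.array([cent_map[lab] for lab in labels], dtype=float)
    return CTPModel(
        labels=tuple(labels),
        probe_ids=tuple(doc["probe_ids"]),
        centroids=centroids,
        threshold_factor=float(doc["threshold_factor"]),
        clustering_method=str(doc["clustering_method"]),
        seed=doc.get("seed"),
        source_tag=str(doc.get("source_tag", "")),
    )


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.Series(dict(labels), name="label").rename_axis("sample_id").to_csv(path, sep="\t")


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id and label")
    sids = df.iloc[:, 0]
    dup = sids[sids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample identifier: {dup.iloc[0]!r}")
    return dict(zip(sids, df.iloc[:, 1]))


def write_assignments(
    assignments: Sequence[AssignmentResult], path: str | Path, labels: Sequence[str] | None = None
) -> None:
    """Write the per-sample assignment table (sample, label, r per CTP, margin)."""
    if labels is None:
        labels = tuple(sorted(assignments[0].correlations)) if assignments else ("A", "B", "C")
    rows = [
        {
            "sample_id": a.sample_id,
            "label": a.label,
            **{f"r_{lab}": a.correlations[lab] for lab in labels},
            "margin": a.margin,
        }
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> list[AssignmentResult]:
    df = pd.read_csv(path, sep="\t")
    corr_cols = [c for c in df.columns if c.startswith("r_")]
    if not corr_cols or "sample_id" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: not an assignment table")
    out = []
    for _, row in df.iterrows():
        corrs = {c[2:]: float(row[c]) for c in corr_cols}
        out.append(
            AssignmentResult(
                sample_id=str(row["sample_id"]),
                label=str(row["label"]),
                correlations=corrs,
                margin=float(row["margin"]),
            )
        )
    return out
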