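"""ROI feature matrices and cohort summary statistics.

Each subject's fitted tensor maps inside the shared ROI mask are
arranged as a components x voxels matrix (6 x V for the diffusion
tensor, 15 x V for the kurtosis tensor, 1 x V for a scalar map), with a
voxel ordering fixed by a row-major scan of the mask so that columns
align across subjects.  All-zero rows and columns — zero in every
subject of the cohort — are pruned cohort-wide before classification,
preserving a common feature space.  Per-subject max / min / avg
summaries of the matrix entries feed two-group significance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectFeatureMatrix",
    "CohortSummary",
    "extract_subject_matrix",
    "prune_zero_rows_columns",
    "flatten_features",
    "cohort_summary",
    "cohort_summary_tests",
]

TENSOR_KIND_ROWS = {"DT": 6, "KT": 15, "scalar": 1}


@dataclass(frozen=True)
class SubjectFeatureMatrix:
    """One subject's ROI tensor components, components x voxels."""

    tensor_kind: str
    matrix: np.ndarray
    voxel_index: np.ndarray  # (V, 3) grid coordinates, row-major scan order

    def __post_init__(self) -> None:
        if self.tensor_kind not in TENSOR_KIND_ROWS:
            raise ValueError(f"unknown tensor_kind {self.tensor_kind!r}")
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D (components x voxels)")
        object.__setattr__(self, "matrix", m)

    @property
    def n_components(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]


def extract_subject_matrix(
    tensor_maps: dict[str, np.ndarray] | np.ndarray,
    mask: np.ndarray,
    tensor_kind: str,
) -> SubjectFeatureMatrix:
    """Arrange a subject's in-mask tensor components as components x voxels.

    ``tensor_maps`` is either the dict returned by ``fit_volume`` (the
    'D' or 'W' entry is picked by ``tensor_kind``) or a grid-shaped array
    (..., n_components) / (...,) for a scalar map.  Voxels enumerate the
    mask in row-major (C) scan order, identical for every subject that
    shares the mask.
    """
    msk = np.asarray(mask).astype(bool)
    if isinstance(tensor_maps, dict):
        key = {"DT": "D", "KT": "W"}.get(tensor_kind)
        if key is None:
            raise ValueError("pass the scalar map array directly for tensor_kind='scalar'")
        arr = tensor_maps[key]
    else:
        arr = np.asarray(tensor_maps, dtype=float)

    n_rows = TENSOR_KIND_ROWS[tensor_kind]
    if arr.ndim == msk.ndim:  # scalar map
        arr = arr[..., None]
    if arr.shape[:-1] != msk.shape:
        raise ValueError("tensor map grid does not match mask grid")
    if arr.shape[-1] != n_rows:
        raise ValueError(
            f"{tensor_kind} expects {n_rows} components, map has {arr.shape[-1]}"
        )
    voxel_index = np.argwhere(msk)  # row-major order
    matrix = arr[msk].T  # (components, V)
    return SubjectFeatureMatrix(tensor_kind=tensor_kind, matrix=matrix, voxel_index=voxel_index)


def prune_zero_rows_columns(
    cohort: list[SubjectFeatureMatrix], atol: float = 0.0
) -> tuple[list[SubjectFeatureMatrix], dict[str, np.ndarray]]:
    """Remove rows/columns that are (near-)zero in every subject.

    Pruning is cohort-wide: a row or column survives if any subject has a
    nonzero entry there, so all subjects keep an identical feature space.
    Returns the pruned cohort and the surviving row/column indices.
    """
    if not cohort:
        raise ValueError("empty cohort")
    shapes = {m.matrix.shape for m in cohort}
    if len(shapes) > 1:
        raise ValueError("subjects have differing matrix shapes")
    kinds = {m.tensor_kind for m in cohort}
    if len(kinds) > 1:
        raise ValueError("subjects have differing tensor kinds")

    nonzero = np.zeros(cohort[0].matrix.shape, dtype=bool)
    for m in cohort:
        nonzero |= np.abs(m.matrix) > atol
    keep_rows = np.flatnonzero(nonzero.any(axis=1))
    keep_cols = np.flatnonzero(nonzero.any(axis=0))
    if keep_rows.size == 0 or keep_cols.size == 0:
        raise ValueError("pruning removed every feature")
    pruned = [
        SubjectFeatureMatrix(
            tensor_kind=m.tensor_kind,
            matrix=m.matrix[np.ix_(keep_rows, keep_cols)],
            voxel_index=m.voxel_index[keep_cols],
        )
        for m in cohort
    ]
    return pruned, {"rows": keep_rows, "columns": keep_cols}


def flatten_features(matrix: SubjectFeatureMatrix) -> np.ndarray:
    """Row-major flatten: component index is the outer loop, voxel the inner."""
    return matrix.matrix.ravel(order="C")


@dataclass(frozen=True)
class CohortSummary:
    """Per-subject max/min/avg of the feature-matrix entries, with labels."""

    table: pd.DataFrame  # columns: subject, group, max, min, avg

    def __post_init__(self) -> None:
        missing = {"subject", "group", "max", "min", "avg"} - set(self.table.columns)
        if missing:
            raise ValueError(f"summary table missing columns {sorted(missing)}")
        bad = self.table["min"] > self.table["avg"]
        bad |= self.table["avg"] > self.table["max"]
        if bad.any():
            raise ValueError("min <= avg <= max violated for some subject")


def cohort_summary(
    cohort: list[SubjectFeatureMatrix], groups: list | np.ndarray
) -> CohortSummary:
    """Summarize each subject's matrix by its max, min and average entry."""
    groups = np.asarray(groups)
    if groups.size != len(cohort):
        raise ValueError("one group label per subject required")
    rows = [
        {
            "subject": i,
            "group": groups[i],
            "max": float(m.matrix.max()),
            "min": float(m.matrix.min()),
            "avg": float(m.matrix.mean()),
        }
        for i, m in enumerate(cohort)
    ]
    return CohortSummary(table=pd.DataFrame(rows))


def cohort_summary_tests(summary: CohortSummary) -> pd.DataFrame:
    """Two-group Welch t-test and one-way ANOVA per summary statistic.

    With exactly two groups the ANOVA F statistic equals the square of
    the pooled-variance t statistic, a useful internal consistency check.
    Returns one row per statistic in (max, min, avg) order.
    """
    tab = summary.table
    names = tab["group"].unique()
    if names.size != 2:
        raise ValueError("exactly two groups required")
    a = tab[tab["group"] == names[0]]
    b = tab[tab["group"] == names[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    out = []
    for stat in ("max", "min", "avg"):
        t, tp = stats.ttest_ind(a[stat], b[stat], equal_var=False)
        f, fp = stats.f_oneway(a[stat], b[stat])
        out.append(
            {
                "statistic": stat,
                "t": float(t),
                "t_p": float(tp),
                "anova_F": float(f),
                "anova_p": float(fp),
            }
        )
    return pd.DataFrame(out)
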