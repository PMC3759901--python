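"""Validation and presentation statistics.

Cross-platform concordance (Spearman rank correlation), paired t-tests
of before/after expression within patients, and the heat-map layout
machinery: row z-scores plus single-linkage hierarchical clustering with
1 − Pearson correlation as the distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr, ttest_rel

from .errors import ValidationError
from .matrix import LongitudinalMatrix


@dataclass
class PairedComparison:
    """Paired t-test of one feature's before/after values across patients."""

    feature: str
    before: np.ndarray
    after: np.ndarray
    t_stat: float
    p_value: float
    direction: str  # up / down / none

    def __post_init__(self) -> None:
        if len(self.before) != len(self.after) or len(self.before) < 2:
            raise ValidationError("paired samples need equal lengths >= 2")


def paired_t_test(
    before: np.ndarray | list[float],
    after: np.ndarray | list[float],
    feature: str = "",
) -> PairedComparison:
    """Two-sided paired t-test of after versus baseline values.

    The statistic is d̄ / (s_d / √n) with n−1 degrees of freedom on the
    patient-wise differences.  Zero variance of the differences leaves
    the p-value undefined (NaN sentinel); direction follows the sign of
    the mean difference.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.size < 2:
        raise ValidationError("paired samples need equal lengths >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        t, p = float("nan"), float("nan")
    else:
        t, p = ttest_rel(a, b)
    mean_diff = float(diff.mean())
    direction = "none"
    if np.isfinite(t) and mean_diff > 0:
        direction = "up"
    elif np.isfinite(t) and mean_diff < 0:
        direction = "down"
    return PairedComparison(
        feature=feature, before=b, after=a, t_stat=float(t), p_value=float(p), direction=direction
    )


def paired_t_table(
    before: pd.DataFrame, after: pd.DataFrame, alpha: float | None = None
) -> pd.DataFrame:
    """Feature-wise paired t-tests of two patient-aligned matrices.

    Columns must be the same patients in the same order.  ``alpha``
    optionally adds a plain (uncorrected) significance flag column.
    """
    if list(before.columns) != list(after.columns):
        raise ValidationError("before/after matrices must share patient columns")
    common = before.index.intersection(after.index)
    rows = []
    for feat in common:
        res = paired_t_test(before.loc[feat].to_numpy(), after.loc[feat].to_numpy(), feat)
        rows.append(
            {
                "feature": feat,
                "t_stat": res.t_stat,
                "p_value": res.p_value,
                "direction": res.direction,
            }
        )
    table = pd.DataFrame(rows).set_index("feature")
    if alpha is not None:
        table["significant"] = table["p_value"] < alpha
    return table


def spearman_rho(x: np.ndarray | list[float], y: np.ndarray | list[float]) -> float:
    """Spearman rank correlation (mid-ranks on ties); NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("spearman_rho needs equal lengths >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan")
    rho, _ = spearmanr(x, y)
    return float(rho)


# ---------------------------------------------------------------------------
# heat-map layout


@dataclass
class ClusterLayout:
    """Row/column orders, merge trees, and row z-scores for a heat map."""

    row_order: list[str]
    column_order: list[str]
    row_linkage: np.ndarray | None
    column_linkage: np.ndarray | None
    zscores: pd.DataFrame
    constant_rows: list[str]

    def column_subtrees(self) -> tuple[set[str], set[str]]:
        """Leaves of the two children of the column dendrogram's root."""
        if self.column_linkage is None:
            raise ValidationError("no column dendrogram available")
        n = len(self.column_order)
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for idx, (left, right, _, _) in enumerate(self.column_linkage):
            members[n + idx] = members[int(left)] | members[int(right)]
        left, right = int(self.column_linkage[-1][0]), int(self.column_linkage[-1][1])
        cols = self.zscores.columns
        return (
            {cols[i] for i in members[left]},
            {cols[i] for i in members[right]},
        )


def row_zscores(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Center and scale each row to mean 0, sample SD 1; constant rows → 0."""
    mat = values.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    constant = (sd.ravel() == 0.0) | ~np.isfinite(sd.ravel())
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (mat - mean) / safe_sd
    z[constant, :] = 0.0
    frame = pd.DataFrame(z, index=values.index, columns=values.columns)
    return frame, list(values.index[constant])


def _pearson_single_linkage(profiles: np.ndarray) -> np.ndarray:
    """Single-linkage merge tree over 1 − Pearson(r) distances."""
    r = np.corrcoef(profiles)
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    return linkage(condensed, method="single")


def cluster_heatmap(
    matrix: LongitudinalMatrix | pd.DataFrame,
    cluster_columns: bool = True,
) -> ClusterLayout:
    """Heat-map layout: z-scored rows ordered by single-linkage clustering.

    Row and column profiles are clustered with distance 1 − r (Pearson);
    leaf order comes from the dendrogram.  Rows with zero variance carry
    no correlation signal: they are excluded from the distance
    computation, appended after the clustered rows, and flagged.
    """
    values = matrix.values if isinstance(matrix, LongitudinalMatrix) else matrix
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 rows and 2 columns")
    zs, constant_rows = row_zscores(values)
    variable = [f for f in values.index if f not in set(constant_rows)]
    if len(variable) < 2:
        raise ValidationError("need at least 2 non-constant rows to cluster")
    row_link = _pearson_single_linkage(values.loc[variable].to_numpy(dtype=float))
    row_order = [variable[i] for i in leaves_list(row_link)] + constant_rows

    col_link = None
    col_order = list(values.columns)
    if cluster_columns:
        col_link = _pearson_single_linkage(values.loc[variable].to_numpy(dtype=float).T)
        col_order = [values.columns[i] for i in leaves_list(col_link)]
    return ClusterLayout(
        row_order=row_order,
        column_order=col_order,
        row_linkage=row_link,
        column_linkage=col_link,
        zscores=zs,
        constant_rows=constant_rows,
    )
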