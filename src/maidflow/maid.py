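"""Intensity-dependent fold-change (MAID) scoring and filtering.

For each patient and each post-baseline comparison, the expression
matrix yields an MA cloud: M = log2 ratio (treated vs baseline),
A = mean log2 signal.  The spread of M shrinks with A — low-abundance
features are noisier — and is summarized by an exponential regression
curve f(A) = a·exp(−b·A) + c fitted to per-bin standard deviations of M.
The MAID score of a feature is M / f(A): an adjusted fold change on the
scale of the local noise, so a larger raw fold change is required at low
abundance to reach a fixed cutoff.  A feature counts as up-regulated in
a comparison when its score exceeds the cutoff C in at least k of the n
patients (and symmetrically below −C for down-regulation); the study
design here is C = 2 for mRNA intensities, C = 1 for the noisier miRNA
cards, with k = 4 of n = 6 patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.isotonic import IsotonicRegression


from .errors import DesignError, ValidationError
from .matrix import LongitudinalMatrix

Comparison = tuple[str, str]  # (time_point, baseline)


@dataclass
class MAPair:
    """One patient's MA transform for one (time point, baseline) comparison."""

    patient: str
    comparison: Comparison
    features: pd.Index
    M: np.ndarray
    A: np.ndarray
    usable: np.ndarray  # False where both sides are censored
    fully_detected: np.ndarray | None = None  # True where neither side is censored

    def __post_init__(self) -> None:
        if not (len(self.M) == len(self.A) == len(self.usable) == len(self.features)):
            raise ValidationError("M, A, usable and features must have equal length")
        if not np.all(np.isfinite(self.M[self.usable])):
            raise ValidationError("M must be finite where usable")
        if self.fully_detected is None:
            self.fully_detected = self.usable.copy()


@dataclass
class MaidCurve:
    """Fitted spread-versus-intensity function f(A) = a·exp(−b·A) + c.

    When the constrained exponential fit fails, ``fallback`` is set and
    the curve is a monotone non-increasing interpolation of the per-bin
    spreads instead.
    """

    a: float
    b: float
    c: float
    bin_centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    bin_spreads: np.ndarray = field(default_factory=lambda: np.empty(0))
    residual_norm: float = float("nan")
    fallback: bool = False
    _fallback_values: np.ndarray | None = None
    # amplitude/origin of the numerically stable shifted form
    # f(A) = a_shifted·exp(−b·(A − shift)) + c, identical to a·exp(−b·A)+c
    _a_shifted: float | None = None
    _shift: float = 0.0

    def __post_init__(self) -> None:
        if not self.fallback:
            if self.a < 0 or self.b < 0 or self.c <= 0:
                raise ValidationError(
                    f"curve parameters a={self.a}, b={self.b}, c={self.c} violate "
                    "a, b >= 0 and c > 0"
                )
        if self._a_shifted is None:
            object.__setattr__(self, "_a_shifted", self.a)

    def __call__(self, A: np.ndarray | float) -> np.ndarray | float:
        if self.fallback:
            assert self._fallback_values is not None
            return np.interp(A, self.bin_centers, self._fallback_values)
        rel = np.asarray(A, dtype=float) - self._shift
        return self._a_shifted * np.exp(-self.b * rel) + self.c


def exponential_spread(A: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-b * A) + c


# ---------------------------------------------------------------------------
# MA transform


def ma_transform(
    matrix: LongitudinalMatrix,
    patient: str,
    comparison: Comparison,
    floor: float,
) -> MAPair:
    """M/A coordinates of one patient's (treated, baseline) sample pair.

    Values are floored before taking logs so censored wells sit at the
    detection-floor signal.  Features censored on both sides carry no
    evidence: they are flagged unusable and their M is zeroed.
    """
    tp, baseline = comparison
    design = matrix.design
    try:
        col_t = design.column_for(patient, tp)
        col_b = design.column_for(patient, baseline)
    except DesignError as exc:
        raise DesignError(f"missing sample for comparison {comparison}: {exc}") from exc
    x_t = np.maximum(matrix.values[col_t].to_numpy(dtype=float), floor)
    x_b = np.maximum(matrix.values[col_b].to_numpy(dtype=float), floor)
    m = np.log2(x_t) - np.log2(x_b)
    a = 0.5 * (np.log2(x_t) + np.log2(x_b))
    if matrix.detection_mask is not None:
        det_t = matrix.detection_mask[col_t].to_numpy(dtype=bool)
        det_b = matrix.detection_mask[col_b].to_numpy(dtype=bool)
        usable = det_t | det_b
        fully = det_t & det_b
    else:
        usable = np.ones_like(m, dtype=bool)
        fully = usable.copy()
    m = np.where(usable, m, 0.0)
    return MAPair(
        patient=patient,
        comparison=comparison,
        features=matrix.features,
        M=m,
        A=a,
        usable=usable,
        fully_detected=fully,
    )


# ---------------------------------------------------------------------------
# spread-curve fit


def _bin_spreads(
    pair: MAPair, n_bins: int, robust: bool
) -> tuple[np.ndarray, np.ndarray, int]:
    # the curve estimates measurement spread, so only comparisons with a
    # genuine quantification on both sides inform it; half-censored
    # features are still scored against the fitted curve
    assert pair.fully_detected is not None
    fit_on = pair.fully_detected
    if fit_on.sum() < 6:
        fit_on = pair.usable
    a = pair.A[fit_on]
    m = pair.M[fit_on]
    n_usable = a.size
    if n_usable < 6:
        raise ValidationError(
            f"only {n_usable} usable features; need >= 6 to estimate a spread curve"
        )
    bins = min(n_bins, n_usable // 5)
    bins = max(bins, 3)
    order = np.argsort(a, kind="stable")
    centers = np.empty(bins)
    spreads = np.empty(bins)
    for idx, chunk in enumerate(np.array_split(order, bins)):
        centers[idx] = a[chunk].mean()
        if robust:
            med = np.median(m[chunk])
            spreads[idx] = 1.4826 * np.median(np.abs(m[chunk] - med))
        else:
            spreads[idx] = m[chunk].std(ddof=1)
    return centers, spreads, bins


def fit_maid_curve(pair: MAPair, n_bins: int = 20, robust_spread: bool = False) -> MaidCurve:
    """Fit the exponential spread curve to binned M-spreads.

    Usable features are sorted by A into equal-count bins (reduced to
    floor(usable/5), at least 3, when features are scarce); the sample
    SD of M per bin (or 1.4826×MAD with ``robust_spread``) is fitted by
    constrained nonlinear least squares with a, b ≥ 0 and c ≥ 1e-6,
    restarting from b ∈ {0.1, 0.3, 1, 3}.  If every start fails, a monotone
    non-increasing isotonic interpolation of the bin spreads is returned
    and flagged in the diagnostics.
    """
    centers, spreads, _ = _bin_spreads(pair, n_bins, robust_spread)
    c_floor = 1e-6
    # fit in shifted coordinates A' = A − min(A): the family is
    # shift-invariant and the exponential stays O(1) over the data range,
    # which keeps the least-squares problem well conditioned when A spans
    # negative values (signals below 1 on the linear scale)
    shift = float(centers.min())
    rel = centers - shift
    p0_a = max(float(spreads[0] - spreads.min()), 1e-3)
    p0_c = max(float(spreads.min()), c_floor)
    best: tuple[float, np.ndarray] | None = None
    for b0 in (0.1, 0.3, 1.0, 3.0):
        try:
            popt, _ = curve_fit(
                exponential_spread,
                rel,
                spreads,
                p0=[p0_a, b0, p0_c],
                bounds=([0.0, 0.0, c_floor], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(exponential_spread(rel, *popt) - spreads))
        if best is None or resid < best[0]:
            best = (resid, popt)
    if best is not None:
        resid, (a_sh, b, c) = best
        # unshifted amplitude, clamped against overflow in the report form
        a = float(a_sh * np.exp(min(b * shift, 700.0)))
        return MaidCurve(
            a=a,
            b=float(b),
            c=float(c),
            bin_centers=centers,
            bin_spreads=spreads,
            residual_norm=resid,
            _a_shifted=float(a_sh),
            _shift=shift,
        )
    iso = IsotonicRegression(increasing=False, y_min=c_floor)
    fitted = iso.fit_transform(centers, spreads)
    resid = float(np.linalg.norm(fitted - spreads))
    return MaidCurve(
        a=0.0,
        b=0.0,
        c=c_floor,
        bin_centers=centers,
        bin_spreads=spreads,
        residual_norm=resid,
        fallback=True,
        _fallback_values=np.asarray(fitted, dtype=float),
    )


def maid_score(pair: MAPair, curve: MaidCurve) -> np.ndarray:
    """Adjusted fold change M / f(A); unusable features score 0.

    Antisymmetric under swapping treated and baseline, because M flips
    sign while A (and hence the fitted spread) is unchanged.
    """
    f = np.asarray(curve(pair.A), dtype=float)
    if (f <= 0).any():
        raise ValidationError("spread curve must be positive everywhere")
    score = pair.M / f
    return np.where(pair.usable, score, 0.0)


# ---------------------------------------------------------------------------
# score tables and filtering


@dataclass
class ScoreTable:
    """MAID scores as a feature × patient × comparison tensor."""

    features: pd.Index
    patients: tuple[str, ...]
    comparisons: tuple[Comparison, ...]
    scores: np.ndarray  # shape (F, P, C)
    curves: dict[tuple[str, Comparison], MaidCurve] = field(default_factory=dict)
    platform: str = ""

    def __post_init__(self) -> None:
        expect = (len(self.features), len(self.patients), len(self.comparisons))
        if self.scores.shape != expect:
            raise ValidationError(
                f"score tensor shape {self.scores.shape} != {expect}"
            )

    def frame(self, comparison: Comparison) -> pd.DataFrame:
        j = self.comparisons.index(comparison)
        return pd.DataFrame(
            self.scores[:, :, j], index=self.features, columns=list(self.patients)
        )


def compute_scores(
    matrix: LongitudinalMatrix,
    floor: float,
    n_bins: int = 20,
    robust_spread: bool = False,
    platform: str = "",
) -> ScoreTable:
    """MAID scores for every patient and post-baseline comparison.

    One spread curve is fitted per (patient, comparison) array pair,
    from that pair's own MA cloud.
    """
    design = matrix.design
    comparisons = tuple(design.comparisons)
    patients = tuple(design.patients)
    scores = np.zeros((len(matrix.features), len(patients), len(comparisons)))
    curves: dict[tuple[str, Comparison], MaidCurve] = {}
    for pi, patient in enumerate(patients):
        for ci, comp in enumerate(comparisons):
            pair = ma_transform(matrix, patient, comp, floor)
            curve = fit_maid_curve(pair, n_bins=n_bins, robust_spread=robust_spread)
            scores[:, pi, ci] = maid_score(pair, curve)
            curves[(patient, comp)] = curve
    return ScoreTable(
        features=matrix.features,
        patients=patients,
        comparisons=comparisons,
        scores=scores,
        curves=curves,
        platform=platform,
    )


@dataclass
class FilterResult:
    """Up/down feature sets per comparison and their unions.

    A feature filtered up at one comparison and down at another appears
    in both union sets and in ``conflicts``.
    """

    per_comparison: dict[Comparison, tuple[set[str], set[str]]]
    union_up: set[str]
    union_down: set[str]
    conflicts: set[str]
    k_required: int
    n_patients: int
    cutoff: float

    @property
    def union_count(self) -> int:
        """Total distinct filtered features (the permutation-test statistic)."""
        return len(self.union_up | self.union_down)


def filter_features(scores: ScoreTable, C: float, k: int) -> FilterResult:
    """Apply the ≥k-of-n per-patient MAID cutoff per comparison.

    A feature is up in a comparison iff its score exceeds C in at least
    k patients, down iff below −C in at least k patients.  Union sets
    across comparisons are returned with direction; raising C or k can
    only shrink every set.
    """
    if k > len(scores.patients):
        raise ValidationError(f"k={k} exceeds the {len(scores.patients)} patients")
    if C < 0:
        raise ValidationError("cutoff C must be non-negative")
    per_comparison: dict[Comparison, tuple[set[str], set[str]]] = {}
    feats = np.asarray(scores.features)
    for ci, comp in enumerate(scores.comparisons):
        block = scores.scores[:, :, ci]
        up = feats[(block > C).sum(axis=1) >= k]
        down = feats[(block < -C).sum(axis=1) >= k]
        per_comparison[comp] = (set(up), set(down))
    union_up = set().union(*(u for u, _ in per_comparison.values()))
    union_down = set().union(*(d for _, d in per_comparison.values()))
    return FilterResult(
        per_comparison=per_comparison,
        union_up=union_up,
        union_down=union_down,
        conflicts=union_up & union_down,
        k_required=k,
        n_patients=len(scores.patients),
        cutoff=C,
    )


def summarize_counts(result: FilterResult) -> pd.DataFrame:
    """Per-comparison and union ('Total') counts of filtered features."""
    rows = []
    for comp, (up, down) in result.per_comparison.items():
        rows.append(
            {
                "comparison": f"{comp[0]} vs {comp[1]}",
                "up": len(up),
                "down": len(down),
                "total": len(up | down),
            }
        )
    rows.append(
        {
            "comparison": "Total",
            "up": len(result.union_up),
            "down": len(result.union_down),
            "total": result.union_count,
        }
    )
    return pd.DataFrame(rows, columns=["comparison", "up", "down", "total"])
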