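"""Preprocessing of TaqMan Ct and array intensity time-course matrices.

The TaqMan low-density-array pipeline is: censor threshold cycles at the
detection limit (Ct 38), convert to linear expression signals via
``S = 2^(−Ct) × 10^9`` (so the floor signal at Ct 38 is ≈ 0.004 and
Ct 20 maps to ≈ 953), remove intensity-dependent systematic differences
between a patient's arrays by cyclic loess on the log2 scale, and anchor
each patient's 95% quantile per card so patients are comparable.
Single-tube assays instead use relative quantification against the
housekeeping miRNA hsa-miR-191-5p.  Coefficients of variation on the
linear scale serve as the normalization quality metric.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigurationError, MaidflowError, ValidationError
from .matrix import LongitudinalMatrix


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable preprocessing constants.

    detection_limit_ct
        Ct above which a well counts as not detected (default 38).
    undetermined_ct
        Sentinel the instrument software writes for undetermined wells.
    linear_scale_factor
        Multiplier of 2^(−Ct); 1e9 makes Ct 38 ↦ 0.004 and Ct 20 ↦ 953.
    quantile
        Quantile anchored across patients per card (default 0.95).
    loess_span
        Fraction of points in each local loess fit (default 0.7).
    hk_feature
        Housekeeping feature for single-tube relative quantification.
    report_scale
        Convenience factor applied to housekeeping ratios (default 1000).
    """

    detection_limit_ct: float = 38.0
    undetermined_ct: float = 45.0
    linear_scale_factor: float = 1e9
    quantile: float = 0.95
    loess_span: float = 0.7
    hk_feature: str = "hsa-miR-191-5p"
    report_scale: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ConfigurationError("quantile must lie in (0, 1)")
        if not 0.0 < self.loess_span <= 1.0:
            raise ConfigurationError("loess_span must lie in (0, 1]")
        if self.detection_limit_ct >= self.undetermined_ct:
            raise ConfigurationError("detection limit must be below the undetermined sentinel")

    @property
    def floor_signal(self) -> float:
        """Linear signal of a censored well."""
        return 2.0 ** (-self.detection_limit_ct) * self.linear_scale_factor


DEFAULT_PARAMS = PreprocessParams()


# ---------------------------------------------------------------------------
# Ct → linear


def ct_to_linear(
    ct_matrix: LongitudinalMatrix, params: PreprocessParams = DEFAULT_PARAMS
) -> LongitudinalMatrix:
    """Censor Ct values at the detection limit and convert to linear signals.

    Every Ct above the limit (including the 45 sentinel) is floored to
    the limit and flagged undetected; detected values map through
    ``S = 2^(−Ct) × linear_scale_factor``, which is strictly decreasing
    in Ct and doubles per cycle.
    """
    if ct_matrix.scale != "ct":
        raise ValidationError(f"expected a ct-scale matrix, got {ct_matrix.scale!r}")
    ct = ct_matrix.values.to_numpy(dtype=float)
    if (ct < 0).any():
        raise ValidationError("negative Ct values are not meaningful")
    detected = ct <= params.detection_limit_ct
    censored_ct = np.minimum(ct, params.detection_limit_ct)
    signal = np.power(2.0, -censored_ct) * params.linear_scale_factor
    values = pd.DataFrame(signal, index=ct_matrix.features, columns=ct_matrix.samples)
    mask = pd.DataFrame(detected, index=ct_matrix.features, columns=ct_matrix.samples)
    return LongitudinalMatrix(
        values=values, scale="linear", design=ct_matrix.design, detection_mask=mask
    )


def ct_to_signal(ct: float, params: PreprocessParams = DEFAULT_PARAMS) -> float:
    """Scalar Ct → linear signal (censoring included); convenience anchor."""
    if ct < 0:
        raise ValidationError("negative Ct values are not meaningful")
    ct = min(ct, params.detection_limit_ct)
    return 2.0 ** (-ct) * params.linear_scale_factor


# ---------------------------------------------------------------------------
# grouping helpers


def _groups(
    matrix: LongitudinalMatrix, group_by: str
) -> list[tuple[str, list[str], np.ndarray]]:
    """(label, sample columns, feature row-selector) per normalization group."""
    design = matrix.design
    if group_by == "all_samples":
        return [("all", list(matrix.samples), np.ones(len(matrix.features), bool))]
    if group_by != "patient_and_card":
        raise ConfigurationError(f"unknown group_by {group_by!r}")
    card_of = design.card_of_assay
    out = []
    for patient in design.patients:
        cols = [c for c in matrix.samples if design.sample_map[c][0] == patient]
        for card in design.cards():
            if card_of is None:
                rows = np.ones(len(matrix.features), bool)
            else:
                rows = np.array([card_of.get(f) == card for f in matrix.features])
            if rows.any():
                out.append((f"{patient}/card{card}", cols, rows))
    return out


# ---------------------------------------------------------------------------
# cyclic loess


def loess_normalize(
    matrix: LongitudinalMatrix,
    params: PreprocessParams = DEFAULT_PARAMS,
    group_by: str = "patient_and_card",
    iterations: int = 1,
) -> LongitudinalMatrix:
    """Remove intensity-dependent differences between arrays by cyclic loess.

    Within each group (a patient's samples on one card, or all samples),
    each sample pair (i, j) contributes a loess fit of
    M = log2(x_i) − log2(x_j) against A = (log2(x_i) + log2(x_j))/2;
    sample i receives −fit/2 and j receives +fit/2 on the log2 scale.
    Corrections within a cycle are computed from a common snapshot and
    averaged over a sample's n−1 pairs, so the result does not depend on
    column order.  Undetected features are excluded from curve fitting
    but still transformed.
    """
    if matrix.scale != "linear":
        raise ValidationError("loess normalization expects a linear-scale matrix")
    values = matrix.values.copy()
    mask = matrix.detection_mask
    for label, cols, rows in _groups(matrix, group_by):
        if len(cols) < 2:
            raise ConfigurationError(
                f"group {label!r} has {len(cols)} sample(s); cyclic loess needs >= 2"
            )
        block = values.loc[rows, cols].to_numpy(dtype=float)
        detected = (
            mask.loc[rows, cols].to_numpy(dtype=bool)
            if mask is not None
            else np.ones_like(block, dtype=bool)
        )
        log2x = np.log2(np.maximum(block, np.finfo(float).tiny))
        n = len(cols)
        for _ in range(max(1, iterations)):
            adjust = np.zeros_like(log2x)
            for i, j in itertools.combinations(range(n), 2):
                m = log2x[:, i] - log2x[:, j]
                a = 0.5 * (log2x[:, i] + log2x[:, j])
                fit_on = detected[:, i] & detected[:, j]
                if fit_on.sum() < 10 or np.allclose(m[fit_on], m[fit_on][0]):
                    # constant M: the correction is that constant everywhere
                    correction = np.full_like(m, m[fit_on].mean() if fit_on.any() else 0.0)
                else:
                    af = a[fit_on]
                    # delta: interpolate between local fits over 1% of the
                    # A-range (the standard lowess speedup)
                    smoothed = lowess(
                        m[fit_on],
                        af,
                        frac=params.loess_span,
                        delta=0.01 * (af.max() - af.min()),
                        return_sorted=True,
                    )
                    correction = np.interp(a, smoothed[:, 0], smoothed[:, 1])
                adjust[:, i] -= correction / 2.0
                adjust[:, j] += correction / 2.0
            log2x = log2x + adjust / max(1, n - 1)
        values.loc[rows, cols] = np.power(2.0, log2x)
    return matrix.with_values(values)


# ---------------------------------------------------------------------------
# quantile anchoring


def quantile_scale(
    matrix: LongitudinalMatrix,
    params: PreprocessParams = DEFAULT_PARAMS,
    group_by: str = "patient_and_card",
) -> LongitudinalMatrix:
    """Scale each patient's card so its pooled quantile matches the cohort.

    Per card, every patient's pooled values (all of that patient's
    samples on the card) are multiplied by one scalar so that each
    patient's 95% quantile equals the cross-patient median of the
    pre-scaling quantiles, taken on the log scale (for an even number of
    patients this is the geometric mean of the two central quantiles:
    scale factors are symmetric in log space).  Within-patient ratios
    are unchanged, and the operation is idempotent.
    """
    if matrix.scale != "linear":
        raise ValidationError("quantile scaling expects a linear-scale matrix")
    if group_by != "patient_and_card":
        raise ConfigurationError("quantile scaling is defined per patient and card")
    design = matrix.design
    values = matrix.values.copy()
    mask = matrix.detection_mask
    for card in design.cards():
        per_patient: dict[str, tuple[list[str], np.ndarray, float]] = {}
        for label, cols, rows in _groups(matrix, "patient_and_card"):
            patient, card_label = label.split("/card")
            if card_label != card:
                continue
            pooled = values.loc[rows, cols].to_numpy(dtype=float).ravel()
            if mask is not None and not mask.loc[rows, cols].to_numpy().any():
                warnings.warn(
                    f"patient {patient}: all wells on card {card} censored; scale 1",
                    stacklevel=2,
                )
                per_patient[patient] = (cols, rows, np.nan)
                continue
            per_patient[patient] = (cols, rows, float(np.quantile(pooled, params.quantile)))
        quantiles = [q for _, _, q in per_patient.values() if np.isfinite(q) and q > 0]
        if not quantiles:
            continue
        target = float(np.exp(np.median(np.log(quantiles))))
        for patient, (cols, rows, q) in per_patient.items():
            factor = 1.0 if not np.isfinite(q) or q == 0.0 else target / q
            values.loc[rows, cols] = values.loc[rows, cols] * factor
    return matrix.with_values(values)


# ---------------------------------------------------------------------------
# single-tube relative quantification


def relative_quantify(
    ct_matrix: LongitudinalMatrix, params: PreprocessParams = DEFAULT_PARAMS
) -> LongitudinalMatrix:
    """Housekeeping-normalized relative quantification of single-tube assays.

    Per sample: mean Ct over technical replicates (after censoring at
    the detection limit), ``S = 2^(−Ct)``, and value =
    ``report_scale × S_feature / S_housekeeping``.  A feature one cycle
    above the housekeeper therefore reports report_scale/2.
    """
    if ct_matrix.scale != "ct":
        raise ValidationError("relative quantification expects a ct-scale matrix")
    if params.hk_feature not in ct_matrix.features:
        raise MaidflowError(
            f"housekeeping feature {params.hk_feature!r} absent from the matrix"
        )
    design = ct_matrix.design
    ct = ct_matrix.values
    censored = np.minimum(ct.to_numpy(dtype=float), params.detection_limit_ct)
    censored = pd.DataFrame(censored, index=ct.index, columns=ct.columns)

    cols_out, data, mask_cols = [], [], []
    for patient in design.patients:
        for tp in design.time_points:
            reps = design.columns_for(patient, tp)
            if not reps:
                continue
            sample_id = f"{patient}_{tp}"
            mean_ct = censored[reps].mean(axis=1)
            hk_ct = mean_ct.loc[params.hk_feature]
            if ct.loc[params.hk_feature, reps].gt(params.detection_limit_ct).any():
                raise MaidflowError(
                    f"housekeeping feature undetected in sample ({patient}, {tp})"
                )
            ratio = params.report_scale * np.power(2.0, hk_ct - mean_ct)
            cols_out.append(sample_id)
            data.append(ratio)
            mask_cols.append(
                ct[reps].le(params.detection_limit_ct).all(axis=1)
            )
    values = pd.concat(data, axis=1)
    values.columns = cols_out
    mask = pd.concat(mask_cols, axis=1)
    mask.columns = cols_out
    collapsed = design.with_sample_map(
        {f"{p}_{t}": (p, t) for p in design.patients for t in design.time_points}
    )
    return LongitudinalMatrix(
        values=values, scale="linear", design=collapsed, detection_mask=mask
    )


# ---------------------------------------------------------------------------
# CV quality metric


def cv(matrix: LongitudinalMatrix) -> tuple[pd.Series, float]:
    """Per-feature coefficient of variation and its unweighted mean.

    CV = sample (n−1) standard deviation / mean across all samples, on
    the linear scale, censored wells included at the detection-floor
    signal.  Features with zero mean get NaN and are excluded from the
    mean CV.
    """
    if matrix.scale != "linear":
        raise ValidationError("CV is defined on the linear scale")
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mean != 0.0, sd / mean, np.nan)
    series = pd.Series(out, index=matrix.features, name="cv")
    mean_cv = float(np.nanmean(out)) if np.isfinite(out).any() else float("nan")
    return series, mean_cv


def preprocess_taqman(
    ct_matrix: LongitudinalMatrix,
    params: PreprocessParams = DEFAULT_PARAMS,
    loess_iterations: int = 1,
) -> tuple[LongitudinalMatrix, dict]:
    """Full card pipeline: censor/convert → cyclic loess → quantile anchor.

    Returns the normalized linear matrix and a QC dict with per-sample
    detection counts and mean CV at each stage.
    """
    linear = ct_to_linear(ct_matrix, params)
    cv_raw = cv(linear)[1]
    smoothed = loess_normalize(linear, params, "patient_and_card", loess_iterations)
    cv_loess = cv(smoothed)[1]
    scaled = quantile_scale(smoothed, params, "patient_and_card")
    cv_scaled = cv(scaled)[1]
    qc = {
        "detection_counts": linear.detection_counts().to_dict(),
        "mean_cv": {"raw_linear": cv_raw, "post_loess": cv_loess, "post_scaling": cv_scaled},
    }
    return scaled, qc


def preprocess_intensity(
    matrix: LongitudinalMatrix,
    params: PreprocessParams = DEFAULT_PARAMS,
    loess_iterations: int = 1,
) -> LongitudinalMatrix:
    """Array-intensity pipeline: joint cyclic loess over all samples."""
    return loess_normalize(matrix, params, "all_samples", loess_iterations)
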