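"""Synthetic longitudinal cohorts with planted differential expression.

The generator emulates the statistical structure the analysis assumes:
six patients sampled at baseline, ~48 h, ~96 h and one month; per-feature
log2 abundances drawn from a Gaussian; Gaussian log-scale measurement
noise whose standard deviation decays exponentially with abundance (the
premise behind intensity-dependent fold-change adjustment); per-patient
× card multiplicative biases; and, for the TaqMan platform, conversion
to threshold cycles with an instrument ceiling at Ct 45 and detection
censoring at Ct 38 left to preprocessing.  Planted up/down-regulated
features carry configurable log2 effects, by default ramping over the
post-baseline time points the way a dose titration would (quarter dose
in the first week, full dose by one month).  Ground truth is returned
alongside the matrix so every downstream stage can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from scipy.stats import norm

from .design import Platform, StudyDesign
from .errors import ConfigurationError
from .matrix import LongitudinalMatrix

#: log2 of the linear-scale factor: Ct = LOG2_LINEAR_FACTOR − log2(signal).
LOG2_LINEAR_FACTOR = math.log2(1e9)
#: log2 linear signal at the Ct-38 detection limit.
DETECTION_FLOOR_LOG2 = LOG2_LINEAR_FACTOR - 38.0
#: instrument ceiling; wells beyond it are reported as Ct 45.
UNDETERMINED_CT = 45.0

DEFAULT_TIME_POINTS = ("baseline", "t48h", "t96h", "m1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic cohort.

    ``spread_params`` are the (a, b, c) of the true fold-change spread
    curve s(A) = a·exp(−b·A) + c on the log2-signal scale: the standard
    deviation of a null feature's log2 ratio M between two samples at
    abundance A.  Each individual sample therefore carries Gaussian
    noise with SD s/√2, so that the difference of two samples has SD s
    and the spread curve estimated from MA clouds recovers the
    configured curve directly.  With ``effect_mode="spread_multiple"``
    the planted per-feature effect is ``effect_log2 × s(abundance)``,
    i.e. expressed in units of the local fold-change spread;
    ``"absolute"`` plants a fixed log2 fold change.
    ``effect_ramp`` scales the effect per post-baseline time point
    (default quarter-dose titration: half effect in the first week, full
    effect at one month).  TaqMan abundances are a two-component
    mixture: features expressed in the assayed tissue
    (Normal(baseline_mean_log2, baseline_sd_log2), default ≈ Ct 32 ± 4.5
    cycles) and features absent from it, parked far below the detection
    floor; the absent weight is solved so the expected share of wells
    beyond the Ct-38 limit equals ``frac_undetected``.
    """

    platform: str = Platform.TAQMAN_CARD.value
    n_patients: int = 6
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    n_features: int = 651
    n_up: int = 50
    n_down: int = 20
    effect_log2: float = 3.0
    effect_mode: str = "spread_multiple"
    effect_ramp: tuple[float, ...] = (0.5, 0.5, 1.0)
    patient_effect_sd: float = 0.0
    spread_params: tuple[float, float, float] = (0.37, 0.12, 0.25)
    baseline_mean_log2: float | None = None
    baseline_sd_log2: float = 4.5
    patient_bias_sd: float = 0.25
    frac_undetected: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_features:
            raise ConfigurationError("n_up + n_down exceeds n_features")
        if not 0.0 <= self.frac_undetected < 1.0:
            raise ConfigurationError("frac_undetected must lie in [0, 1)")
        a, b, c = self.spread_params
        if a < 0 or b < 0 or c <= 0:
            raise ConfigurationError("spread_params must satisfy a, b >= 0 and c > 0")
        if len(self.effect_ramp) != len(self.time_points) - 1:
            raise ConfigurationError(
                "effect_ramp needs one entry per post-baseline time point"
            )
        if self.effect_mode not in ("spread_multiple", "absolute"):
            raise ConfigurationError(f"unknown effect_mode {self.effect_mode!r}")
        if not math.isfinite(self.effect_log2):
            raise ConfigurationError("effect_log2 must be finite")

    def spread(self, abundance: np.ndarray | float) -> np.ndarray | float:
        a, b, c = self.spread_params
        return a * np.exp(-b * np.asarray(abundance, dtype=float)) + c


@dataclass
class SimulationTruth:
    """Planted ground truth of one simulated cohort."""

    planted_up: set[str]
    planted_down: set[str]
    true_effects: pd.DataFrame  # feature × post-baseline time point, signed log2
    sample_bias_log2: Mapping[tuple[str, str], float]  # (patient, card) → bias
    abundance_log2: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self) -> None:
        if self.planted_up & self.planted_down:
            raise ConfigurationError("planted up/down sets must be disjoint")


#: location/scale of the "absent in this tissue" abundance component,
#: deep enough below the detection floor that its wells are censored.
ABSENT_MEAN_LOG2 = DETECTION_FLOOR_LOG2 - 7.0
ABSENT_SD_LOG2 = 1.5
#: default location of the expressed component (≈ Ct 32 at the mean).
EXPRESSED_MEAN_LOG2 = -2.5


def _expressed_censored_frac(config: SimulationConfig, mean_log2: float) -> float:
    """Expected share of censored wells among expressed features.

    Gauss–Hermite quadrature over the expressed abundance component;
    per-well SD combines measurement noise (s/√2) and the patient bias.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    weights = weights / weights.sum()
    mu = mean_log2 + config.baseline_sd_log2 * nodes
    sd = np.sqrt(np.asarray(config.spread(mu)) ** 2 / 2.0 + config.patient_bias_sd**2)
    return float(np.sum(weights * norm.cdf((DETECTION_FLOOR_LOG2 - mu) / sd)))


def _derive_absent_weight(config: SimulationConfig, mean_log2: float) -> float:
    """Mixture weight of the absent component matching frac_undetected.

    Real cards show a bimodal picture: miRNAs expressed in the assayed
    tissue (detectable threshold cycles) and miRNAs simply absent from
    it (undetermined wells).  The expressed component already loses a
    small fraction p_e of wells to the detection limit, so the absent
    weight w solves w + (1 − w)·p_e = frac_undetected, clamped at 0.
    """
    if config.frac_undetected <= 0.0:
        return 0.0
    p_e = _expressed_censored_frac(config, mean_log2)
    return max(0.0, (config.frac_undetected - p_e) / (1.0 - p_e))


def _feature_ids(config: SimulationConfig) -> list[str]:
    if config.platform == Platform.AFFY_MRNA.value:
        return [f"GENE{i:05d}" for i in range(1, config.n_features + 1)]
    return [f"sim-miR-{i:04d}" for i in range(1, config.n_features + 1)]


def simulate_cohort(config: SimulationConfig) -> tuple[LongitudinalMatrix, SimulationTruth]:
    """Draw one cohort and its ground truth; byte-reproducible given the seed.

    Per-sample log2 signal = abundance + bias(patient, card) +
    effect(feature, time point) + Gaussian noise with SD equal to the
    fold-change spread curve at the feature's abundance divided by √2
    (so two-sample log2 ratios have SD s).  TaqMan output is converted
    to Ct (ceiling 45); array output stays a linear intensity matrix.
    Planted features are drawn among features whose abundance clears the
    detection floor by one log2 unit, since effects on unexpressed
    features are unobservable by construction.
    """
    rng = np.random.default_rng(config.seed)
    features = _feature_ids(config)
    taqman = config.platform == Platform.TAQMAN_CARD.value

    mu0 = (
        config.baseline_mean_log2
        if config.baseline_mean_log2 is not None
        else EXPRESSED_MEAN_LOG2
    )
    abundance = rng.normal(mu0, config.baseline_sd_log2, size=config.n_features)
    if taqman and config.frac_undetected > 0.0:
        # absent-in-tissue component: wells beyond the detection limit
        w_absent = _derive_absent_weight(config, mu0)
        absent = rng.random(config.n_features) < w_absent
        abundance[absent] = rng.normal(
            ABSENT_MEAN_LOG2, ABSENT_SD_LOG2, size=int(absent.sum())
        )

    # planted features must be observable
    eligible = np.flatnonzero(abundance >= DETECTION_FLOOR_LOG2 + 1.0) if taqman else np.arange(config.n_features)
    n_planted = config.n_up + config.n_down
    if n_planted > eligible.size:
        raise ConfigurationError(
            f"only {eligible.size} features clear the detection floor; "
            f"cannot plant {n_planted}"
        )
    chosen = rng.choice(eligible, size=n_planted, replace=False)
    up_idx, down_idx = chosen[: config.n_up], chosen[config.n_up :]

    base_effect = np.zeros(config.n_features)
    if config.effect_mode == "spread_multiple":
        local = np.asarray(config.spread(abundance))
        base_effect[up_idx] = config.effect_log2 * local[up_idx]
        base_effect[down_idx] = -config.effect_log2 * local[down_idx]
    else:
        base_effect[up_idx] = config.effect_log2
        base_effect[down_idx] = -config.effect_log2

    cards = (
        {f: ("A" if i < config.n_features / 2 else "B") for i, f in enumerate(features)}
        if taqman
        else None
    )
    patients = tuple(f"Pat{i + 1}" for i in range(config.n_patients))
    bias: dict[tuple[str, str], float] = {}
    card_labels = sorted(set(cards.values())) if cards else ["A"]
    for pat in patients:
        for card in card_labels:
            bias[(pat, card)] = rng.normal(0.0, config.patient_bias_sd)
    card_index = (
        np.array([card_labels.index(cards[f]) for f in features]) if cards else np.zeros(len(features), int)
    )

    # per-sample noise: the configured curve is the spread of M (a
    # two-sample difference), so one sample contributes s/sqrt(2)
    noise_sd = np.asarray(config.spread(abundance)) / math.sqrt(2.0)
    post_tps = config.time_points[1:]
    effects = pd.DataFrame(
        {tp: base_effect * ramp for tp, ramp in zip(post_tps, config.effect_ramp)},
        index=features,
    )

    columns: dict[str, np.ndarray] = {}
    sample_map: dict[str, tuple[str, str]] = {}
    for pat in patients:
        pat_effect_jitter = (
            rng.normal(0.0, config.patient_effect_sd, size=config.n_features)
            if config.patient_effect_sd > 0
            else 0.0
        )
        pat_bias = np.array([bias[(pat, card_labels[ci])] for ci in card_index])
        for tp in config.time_points:
            eff = np.zeros(config.n_features)
            if tp != config.time_points[0]:
                eff = effects[tp].to_numpy()
                if config.patient_effect_sd > 0:
                    eff = eff + np.where(eff != 0.0, pat_effect_jitter, 0.0)
            log2_signal = abundance + pat_bias + eff + rng.normal(0.0, noise_sd)
            sid = f"{pat}_{tp}"
            columns[sid] = log2_signal
            sample_map[sid] = (pat, tp)

    design = StudyDesign(
        patients=patients,
        time_points=config.time_points,
        sample_map=sample_map,
        platform=Platform(config.platform),
        card_of_assay=cards,
    )
    log2_frame = pd.DataFrame(columns, index=features)
    if taqman:
        ct = np.minimum(LOG2_LINEAR_FACTOR - log2_frame, UNDETERMINED_CT)
        matrix = LongitudinalMatrix(
            values=ct, scale="ct", design=design, detection_mask=ct <= 38.0
        )
    else:
        matrix = LongitudinalMatrix(
            values=np.power(2.0, log2_frame), scale="linear", design=design
        )
    truth = SimulationTruth(
        planted_up={features[i] for i in up_idx},
        planted_down={features[i] for i in down_idx},
        true_effects=effects,
        sample_bias_log2=bias,
        abundance_log2=pd.Series(abundance, index=features),
    )
    return matrix, truth


def simulate_null(config: SimulationConfig) -> LongitudinalMatrix:
    """A cohort with no planted effects: time points exchangeable within patient."""
    matrix, _ = simulate_cohort(replace(config, n_up=0, n_down=0))
    return matrix


def simulate_ma_cloud(
    n_features: int,
    spread_params: tuple[float, float, float],
    a_range: tuple[float, float] = (0.0, 12.0),
    seed: int = 0,
):
    """An MA cloud with known spread curve, for estimator-recovery checks.

    A is uniform over ``a_range``; M ~ Normal(0, s(A)) with
    s(A) = a·exp(−b·A) + c.  Returns an :class:`~maidflow.maid.MAPair`.
    """
    from .maid import MAPair  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    a, b, c = spread_params
    A = rng.uniform(a_range[0], a_range[1], size=n_features)
    s = a * np.exp(-b * A) + c
    M = rng.normal(0.0, s)
    return MAPair(
        patient="sim",
        comparison=("t", "b"),
        features=pd.Index([f"f{i}" for i in range(n_features)]),
        M=M,
        A=A,
        usable=np.ones(n_features, dtype=bool),
    )


def simulate_single_tube(
    features: list[str],
    effects_log2: Mapping[str, float],
    n_patients: int = 12,
    hk_feature: str = "hsa-miR-191-5p",
    n_replicates: int = 3,
    baseline_ct_mean: float = 28.0,
    baseline_ct_sd: float = 2.0,
    technical_sd_ct: float = 0.15,
    biological_sd_ct: float = 0.5,
    seed: int = 0,
) -> LongitudinalMatrix:
    """Triplicate single-tube Ct measurements before/after treatment.

    Emulates a validation experiment: each assayed miRNA (plus the
    housekeeper, which carries no effect) is measured in
    ``n_replicates`` wells per sample for ``n_patients`` patients at
    baseline and one month.  ``effects_log2`` gives the planted log2
    fold change per feature (positive = up after a month; note one Ct
    cycle is one log2 unit, with Ct falling as expression rises).
    """
    rng = np.random.default_rng(seed)
    all_features = list(features)
    if hk_feature not in all_features:
        all_features.append(hk_feature)
    patients = tuple(f"VPat{i + 1}" for i in range(n_patients))
    time_points = ("baseline", "m1")
    base_ct = {f: rng.normal(baseline_ct_mean, baseline_ct_sd) for f in all_features}
    base_ct[hk_feature] = rng.normal(24.0, 0.5)

    columns: dict[str, np.ndarray] = {}
    sample_map: dict[str, tuple[str, str]] = {}
    for pat in patients:
        pat_shift = {f: rng.normal(0.0, biological_sd_ct) for f in all_features}
        for tp in time_points:
            true_ct = np.array(
                [
                    base_ct[f]
                    + pat_shift[f]
                    - (effects_log2.get(f, 0.0) if tp == "m1" else 0.0)
                    for f in all_features
                ]
            )
            for rep in range(1, n_replicates + 1):
                sid = f"{pat}_{tp}_rep{rep}"
                columns[sid] = np.clip(
                    true_ct + rng.normal(0.0, technical_sd_ct, len(all_features)),
                    0.0,
                    UNDETERMINED_CT,
                )
                sample_map[sid] = (pat, tp)
    design = StudyDesign(
        patients=patients,
        time_points=time_points,
        sample_map=sample_map,
        platform=Platform.TAQMAN_SINGLE,
    )
    values = pd.DataFrame(columns, index=all_features)
    return LongitudinalMatrix(
        values=values, scale="ct", design=design, detection_mask=values <= 38.0
    )
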