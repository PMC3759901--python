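"""Shared fixtures: small hand-built designs and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from maidflow import (
    LongitudinalMatrix,
    Platform,
    PreprocessParams,
    SimulationConfig,
    StudyDesign,
    simulate_cohort,
)


def make_design(
    n_patients: int = 2,
    time_points: tuple[str, ...] = ("baseline", "t48h"),
    platform: Platform = Platform.TAQMAN_CARD,
    card_of_assay=None,
) -> StudyDesign:
    patients = tuple(f"Pat{i + 1}" for i in range(n_patients))
    sample_map = {
        f"{p}_{t}": (p, t) for p in patients for t in time_points
    }
    return StudyDesign(
        patients=patients,
        time_points=time_points,
        sample_map=sample_map,
        platform=platform,
        card_of_assay=card_of_assay,
    )


def make_matrix(
    values: np.ndarray,
    design: StudyDesign,
    scale: str = "linear",
    features=None,
    mask: np.ndarray | None = None,
) -> LongitudinalMatrix:
    cols = design.ordered_columns()
    features = features or [f"f{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=features, columns=cols)
    mask_frame = None
    if mask is not None:
        mask_frame = pd.DataFrame(mask, index=features, columns=cols)
    return LongitudinalMatrix(
        values=frame, scale=scale, design=design, detection_mask=mask_frame
    )


@pytest.fixture(scope="session")
def params() -> PreprocessParams:
    return PreprocessParams()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced six-patient cohort with planted effects (fast to process)."""
    cfg = SimulationConfig(n_features=160, n_up=12, n_down=5, seed=202)
    return simulate_cohort(cfg), cfg
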