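"""Study designs for longitudinal expression cohorts.

A :class:`StudyDesign` records which sample column belongs to which
(patient, time point) pair, which time point is the pre-treatment
baseline, and — for two-card TaqMan low-density arrays — which card each
assay sits on.  All downstream comparisons ("time point t versus
baseline, within patient p") are driven by this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

from .errors import DesignError


class Platform(str, Enum):
    """Measurement platform of a matrix."""

    TAQMAN_CARD = "taqman_card"
    AFFY_MRNA = "affy_mrna"
    AFFY_MIRNA = "affy_mirna"
    TAQMAN_SINGLE = "taqman_single"


@dataclass(frozen=True)
class StudyDesign:
    """Patient / time-point / platform / card mapping with a designated baseline.

    Parameters
    ----------
    patients
        Patient identifiers, in reporting order.
    time_points
        Ordered time-point labels; the first is the baseline.
    sample_map
        Mapping from sample-column id to ``(patient, time_point)``.
        Several columns may map to the same pair only when they are
        technical replicates (single-tube assays measured in triplicate).
    platform
        Measurement platform.
    card_of_assay
        Optional mapping from assay (feature) id to card label
        (``"A"``/``"B"``); only meaningful for :attr:`Platform.TAQMAN_CARD`.
    """

    patients: tuple[str, ...]
    time_points: tuple[str, ...]
    sample_map: Mapping[str, tuple[str, str]]
    platform: Platform = Platform.TAQMAN_CARD
    card_of_assay: Mapping[str, str] | None = None
    baseline_label: str = field(default="")

    def __post_init__(self) -> None:
        if not self.baseline_label:
            object.__setattr__(self, "baseline_label", self.time_points[0])
        self.validate()

    def validate(self) -> None:
        if len(self.patients) < 1:
            raise DesignError("a study design needs at least one patient")
        if len(self.time_points) < 2:
            raise DesignError("a study design needs at least two time points")
        if self.baseline_label != self.time_points[0]:
            raise DesignError(
                f"baseline label {self.baseline_label!r} must be the first "
                f"time point (got order {list(self.time_points)})"
            )
        if len(set(self.patients)) != len(self.patients):
            raise DesignError("duplicate patient identifiers")
        if len(set(self.time_points)) != len(self.time_points):
            raise DesignError("duplicate time-point labels")
        known = set(self.patients), set(self.time_points)
        for col, (pat, tp) in self.sample_map.items():
            if pat not in known[0]:
                raise DesignError(f"sample {col!r} refers to unknown patient {pat!r}")
            if tp not in known[1]:
                raise DesignError(f"sample {col!r} refers to unknown time point {tp!r}")

    # -- lookups ---------------------------------------------------------

    def columns_for(self, patient: str, time_point: str) -> list[str]:
        """All sample columns (replicates included) of one (patient, time point)."""
        return [c for c, key in self.sample_map.items() if key == (patient, time_point)]

    def column_for(self, patient: str, time_point: str) -> str:
        """The unique sample column of one (patient, time point)."""
        cols = self.columns_for(patient, time_point)
        if len(cols) != 1:
            raise DesignError(
                f"expected exactly one sample for ({patient}, {time_point}), "
                f"found {len(cols)}"
            )
        return cols[0]

    @property
    def has_replicates(self) -> bool:
        seen: set[tuple[str, str]] = set()
        for key in self.sample_map.values():
            if key in seen:
                return True
            seen.add(key)
        return False

    def require_complete(self) -> None:
        """Check that every (patient, time point) pair has exactly one column."""
        for pat in self.patients:
            for tp in self.time_points:
                n = len(self.columns_for(pat, tp))
                if n != 1:
                    raise DesignError(
                        f"({pat}, {tp}) maps to {n} sample columns, expected 1"
                    )

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        """Post-baseline comparisons, as (time_point, baseline) pairs."""
        return [(tp, self.baseline_label) for tp in self.time_points[1:]]

    def cards(self) -> list[str]:
        if self.card_of_assay is None:
            return ["A"]
        return sorted(set(self.card_of_assay.values()))

    def with_sample_map(self, sample_map: Mapping[str, tuple[str, str]]) -> "StudyDesign":
        return replace(self, sample_map=dict(sample_map))

    def ordered_columns(self, columns: Sequence[str] | None = None) -> list[str]:
        """Sample columns sorted by (patient order, time-point order)."""
        cols = list(self.sample_map) if columns is None else list(columns)
        pat_rank = {p: i for i, p in enumerate(self.patients)}
        tp_rank = {t: i for i, t in enumerate(self.time_points)}

        def key(c: str) -> tuple[int, int, str]:
            pat, tp = self.sample_map[c]
            return pat_rank[pat], tp_rank[tp], c

        return sorted(cols, key=key)
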