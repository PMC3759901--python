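"""Longitudinal feature × sample matrices and their TSV/CSV plumbing.

Matrices are tab-delimited text with one header row of sample ids and the
feature id in the first column.  The accompanying sample sheet is a CSV
with columns ``sample_id, patient, time_point, platform, card`` (``card``
may be empty for single-card platforms); an optional ``replicate`` column
marks technical replicates of one sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Platform, StudyDesign
from .errors import DesignError, ParseError, ValidationError

#: Sentinel Ct for wells the instrument reported as "Undetermined".
UNDETERMINED_CT = 45.0

_SCALES = ("ct", "linear", "log2")


@dataclass
class LongitudinalMatrix:
    """Feature × sample expression values tied to a :class:`StudyDesign`.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample.  ``scale`` is one of ``ct`` (PCR threshold cycles),
    ``linear`` (expression signals ≥ 0) or ``log2``.  ``detection_mask``
    (same shape, boolean, True = detected) accompanies ct/linear data.
    """

    values: pd.DataFrame
    scale: str
    design: StudyDesign
    detection_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("matrix contains non-finite values")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.scale == "linear" and (vals < 0).any():
            raise ValidationError("linear-scale values must be >= 0")
        missing = [c for c in self.values.columns if c not in self.design.sample_map]
        if missing:
            raise DesignError(f"sample sheet has no entry for column(s) {missing}")
        if self.detection_mask is not None:
            if self.detection_mask.shape != self.values.shape:
                raise ValidationError("detection mask shape mismatch")
        elif self.scale in ("ct", "linear"):
            # default: everything detected
            self.detection_mask = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )

    # -- convenience -----------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def column(self, patient: str, time_point: str) -> pd.Series:
        return self.values[self.design.column_for(patient, time_point)]

    def detected(self, patient: str, time_point: str) -> pd.Series:
        col = self.design.column_for(patient, time_point)
        assert self.detection_mask is not None
        return self.detection_mask[col]

    def with_values(
        self,
        values: pd.DataFrame,
        scale: str | None = None,
        detection_mask: pd.DataFrame | None = None,
    ) -> "LongitudinalMatrix":
        return LongitudinalMatrix(
            values=values,
            scale=self.scale if scale is None else scale,
            design=self.design,
            detection_mask=self.detection_mask if detection_mask is None else detection_mask,
        )

    def with_design(self, design: StudyDesign) -> "LongitudinalMatrix":
        return replace(self, design=design)

    def detection_counts(self) -> pd.Series:
        """Detected features per sample (Table-2 style: raw Ct below the limit)."""
        assert self.detection_mask is not None
        return self.detection_mask.sum(axis=0)


# ---------------------------------------------------------------------------
# sample sheets


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype=str).fillna("")
    required = {"sample_id", "patient", "time_point"}
    missing = required - set(sheet.columns)
    if missing:
        raise ParseError(f"sample sheet {path} lacks column(s) {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ParseError(f"sample sheet {path} has duplicate sample_id entries")
    return sheet


def design_from_sheet(
    sheet: pd.DataFrame,
    time_point_order: list[str] | None = None,
    card_of_assay: dict[str, str] | None = None,
) -> StudyDesign:
    patients = tuple(dict.fromkeys(sheet["patient"]))
    if time_point_order is None:
        time_points = tuple(dict.fromkeys(sheet["time_point"]))
    else:
        time_points = tuple(time_point_order)
    platform = Platform.TAQMAN_CARD
    if "platform" in sheet.columns and sheet["platform"].iloc[0]:
        platform = Platform(sheet["platform"].iloc[0])
    sample_map = {
        row.sample_id: (row.patient, row.time_point) for row in sheet.itertuples()
    }
    return StudyDesign(
        patients=patients,
        time_points=time_points,
        sample_map=sample_map,
        platform=platform,
        card_of_assay=card_of_assay,
    )


# ---------------------------------------------------------------------------
# matrix IO


def read_matrix(
    path: str | Path,
    sample_sheet: str | Path | pd.DataFrame,
    scale: str,
    time_point_order: list[str] | None = None,
    card_of_assay: dict[str, str] | None = None,
    detection_limit_ct: float = 38.0,
    feature_blacklist: set[str] | None = None,
) -> LongitudinalMatrix:
    """Read a TSV feature × sample matrix validated against a sample sheet.

    Ct matrices may contain the literal ``Undetermined``, which is
    converted to the Ct 45 sentinel.  ``feature_blacklist`` drops assays
    known to be dead entries before validation.  Columns are reordered by
    (patient, time point); rows with duplicate feature ids are rejected.
    """
    if isinstance(sample_sheet, pd.DataFrame):
        sheet = sample_sheet
    else:
        sheet = read_sample_sheet(sample_sheet)
    design = design_from_sheet(sheet, time_point_order, card_of_assay)

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if feature_blacklist:
        raw = raw.loc[[f for f in raw.index if f not in feature_blacklist]]
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids {dups}")

    missing = [c for c in raw.columns if c not in design.sample_map]
    if missing:
        raise DesignError(f"{path}: column(s) {missing} absent from the sample sheet")

    text = raw.apply(lambda s: s.astype(str).str.strip())
    if scale == "ct":
        text = text.replace(
            {r"(?i)^undetermined$": str(UNDETERMINED_CT)}, regex=True
        )
    # np.asarray parsing is correctly rounded (unlike the fast csv float
    # path), which keeps write→read round trips exact to the last ulp
    converted = {}
    for j, col in enumerate(text.columns):
        try:
            converted[col] = np.asarray(text[col].to_list(), dtype=float)
        except ValueError:
            for i, cell in enumerate(text[col]):
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} at row "
                        f"{raw.index[i]!r} (line {i + 2}), column {col!r}"
                    ) from None
            raise
    values = pd.DataFrame(converted, index=raw.index)
    bad = ~np.isfinite(values.to_numpy(dtype=float))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"{path}: non-finite value at row {raw.index[i]!r}, column {values.columns[j]!r}"
        )

    values = values[design.ordered_columns(list(values.columns))]
    mask = None
    if scale == "ct":
        mask = values <= detection_limit_ct
    elif _mask_path(path).exists():
        mask = (
            pd.read_csv(_mask_path(path), sep="\t", index_col=0)
            .astype(bool)
            .reindex(index=values.index, columns=values.columns)
        )
        if mask.isna().any().any():
            raise ParseError(f"{_mask_path(path)}: mask does not cover the matrix")
    return LongitudinalMatrix(values=values, scale=scale, design=design, detection_mask=mask)


def _mask_path(path: str | Path) -> Path:
    return Path(str(path) + ".mask")


def write_matrix(matrix: LongitudinalMatrix, path: str | Path) -> None:
    """Write the matrix as TSV, round-trippable by :func:`read_matrix`.

    When the matrix carries a non-trivial detection mask that is not
    derivable from the values (any scale but ct), a sidecar
    ``<path>.mask`` TSV of 0/1 flags is written alongside and picked up
    automatically on re-read, so round trips preserve censoring state.
    """
    out = matrix.values.copy()
    out.index.name = out.index.name or "feature"
    out.to_csv(path, sep="\t", float_format=None)
    mask = matrix.detection_mask
    if mask is not None and matrix.scale != "ct" and not mask.to_numpy().all():
        flags = mask.astype(int).copy()
        flags.index.name = out.index.name
        flags.to_csv(_mask_path(path), sep="\t")
    else:
        _mask_path(path).unlink(missing_ok=True)


def write_sample_sheet(design: StudyDesign, path: str | Path) -> None:
    rows = []
    for col in design.ordered_columns():
        pat, tp = design.sample_map[col]
        card = ""
        rows.append(
            {
                "sample_id": col,
                "patient": pat,
                "time_point": tp,
                "platform": design.platform.value,
                "card": card,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def ct_floor_signal(detection_limit_ct: float = 38.0, linear_scale_factor: float = 1e9) -> float:
    """Linear signal at the detection limit (the censoring floor)."""
    return math.pow(2.0, -detection_limit_ct) * linear_scale_factor
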