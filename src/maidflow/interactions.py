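"""miRNA → gene interaction tables (prediction-consensus + validated exports).

The prediction file emulates a miRWalk-style export: one row per
(miRNA, gene) pair with the number of supporting prediction algorithms
out of 10.  The validated file emulates a miRTarBase-style export: one
row per experimentally verified pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError

MAX_ALGORITHMS = 10

_COLUMNS = ["mirna", "gene", "n_algorithms", "validated", "source"]


@dataclass
class InteractionTable:
    """Merged prediction/validation records.

    ``records`` has columns ``mirna, gene, n_algorithms, validated,
    source``; (mirna, gene, source) is unique and 0 ≤ n_algorithms ≤ 10.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"interaction table lacks column(s) {sorted(missing)}")
        n = df["n_algorithms"].to_numpy()
        if ((n < 0) | (n > MAX_ALGORITHMS)).any():
            bad = df.loc[(df.n_algorithms < 0) | (df.n_algorithms > MAX_ALGORITHMS)]
            raise ValidationError(
                f"n_algorithms outside 0–{MAX_ALGORITHMS}: "
                f"{bad[['mirna', 'gene', 'n_algorithms']].to_dict('records')}"
            )
        if df.duplicated(subset=["mirna", "gene", "source"]).any():
            dup = df.loc[df.duplicated(subset=["mirna", "gene", "source"])]
            raise ValidationError(
                f"duplicate (mirna, gene, source) records: "
                f"{dup[['mirna', 'gene', 'source']].to_dict('records')}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> pd.DataFrame:
        """One row per (mirna, gene) pair with merged evidence.

        A pair present in both the predicted and the validated source
        keeps its algorithm count and is flagged validated.
        """
        agg = self.records.groupby(["mirna", "gene"], as_index=False).agg(
            n_algorithms=("n_algorithms", "max"),
            validated=("validated", "any"),
        )
        return agg


def read_interactions(
    predicted_path: str | Path | None,
    validated_path: str | Path | None,
) -> InteractionTable:
    """Read predicted and validated interaction exports into one table.

    The predicted CSV needs columns (mirna, gene, n_algorithms); the
    validated CSV needs (mirna, gene).  A pair present in both files is
    merged at the :meth:`InteractionTable.pairs` level.
    """
    frames = []
    if predicted_path is not None:
        pred = pd.read_csv(predicted_path)
        _require(pred, {"mirna", "gene", "n_algorithms"}, predicted_path)
        pred = pred[["mirna", "gene", "n_algorithms"]].copy()
        pred["n_algorithms"] = pred["n_algorithms"].astype(int)
        pred["validated"] = False
        pred["source"] = "predicted"
        frames.append(pred)
    if validated_path is not None:
        val = pd.read_csv(validated_path)
        _require(val, {"mirna", "gene"}, validated_path)
        val = val[["mirna", "gene"]].copy()
        val["n_algorithms"] = 0
        val["validated"] = True
        val["source"] = "validated"
        frames.append(val)
    if not frames:
        raise ValidationError("at least one of predicted/validated paths is required")
    records = pd.concat(frames, ignore_index=True)[_COLUMNS]
    return InteractionTable(records=records)


def _require(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
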