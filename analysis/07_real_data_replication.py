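#!/usr/bin/env python
"""Optional replication on the real GEO cohort (GSE46293).

This driver is not part of the default analysis: it needs the deposited
TaqMan card Ct tables from the GEO SuperSeries GSE46293, which are not
bundled with the repository.  To run it, download the series matrices
(e.g. with GEOparse or from the GEO website), export the raw Ct table
as a TSV feature × sample matrix plus a sample sheet with columns
``sample_id, patient, time_point, platform, card``, and place them at

    results/real/GSE46293_ct.tsv
    results/real/GSE46293_samples.csv

The script then reruns the exact preprocessing entry points used for
the synthetic cohorts — censoring at Ct 38, 2^−Ct × 10⁹ conversion,
cyclic loess per patient and card, 95%-quantile anchoring — and prints
the mean coefficient of variation over all assays before and after
normalization plus the CV of the housekeeping miRNA hsa-miR-191-5p, the
quality metrics reported for this cohort.
"""

from pathlib import Path

from maidflow import PreprocessParams, ct_to_linear, cv, read_matrix
from maidflow.preprocess import preprocess_taqman

REAL = Path(__file__).resolve().parents[1] / "results" / "real"


def main() -> None:
    matrix_path = REAL / "GSE46293_ct.tsv"
    sheet_path = REAL / "GSE46293_samples.csv"
    if not matrix_path.exists() or not sheet_path.exists():
        print(__doc__)
        print("real-data inputs not found; nothing to do.")
        return

    params = PreprocessParams()
    cards = read_matrix(matrix_path, sheet_path, scale="ct")
    raw_cv = cv(ct_to_linear(cards, params))[1]
    normalized, qc = preprocess_taqman(cards, params)
    norm_cv_series, norm_cv = cv(normalized)
    print(f"mean CV over {cards.values.shape[0]} assays: raw {raw_cv:.3f} → normalized {norm_cv:.3f}")
    if params.hk_feature in norm_cv_series.index:
        print(f"housekeeping {params.hk_feature}: CV {norm_cv_series[params.hk_feature]:.3f}")
    print(f"per-sample detection counts (Ct < 38): {qc['detection_counts']}")


if __name__ == "__main__":
    main()
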