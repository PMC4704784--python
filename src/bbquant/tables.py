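"""CSV result tables for per-unit enrichment measurements.

Column order is fixed and documented so downstream scripts can rely on it:

``unit_id, mode, n_centrosomes, mean_nuclear, mean_adjacent,
mean_nonadjacent, norm_adjacent, norm_nonadjacent, fold, qc_flags``

Undefined values (e.g. fold when the normalized nonadjacent mean is <= 0)
are written as empty fields, with the reason recorded in ``qc_flags``
(semicolon-separated, sorted).  Floats are written at full ``repr``
precision so a written table reads back bit-exactly.
"""

from __future__ import annotations

import pandas as pd

from .enrichment import EnrichmentResult
from .errors import EmptyInputError

RESULT_COLUMNS = [
    "unit_id",
    "mode",
    "n_centrosomes",
    "mean_nuclear",
    "mean_adjacent",
    "mean_nonadjacent",
    "norm_adjacent",
    "norm_nonadjacent",
    "fold",
    "qc_flags",
]

_FLOAT_COLUMNS = RESULT_COLUMNS[3:9]


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    if not results:
        raise EmptyInputError("no results to tabulate")
    rows = []
    for r in results:
        rows.append(
            {
                "unit_id": r.unit_id,
                "mode": r.mode,
                "n_centrosomes": r.n_centrosomes,
                "mean_nuclear": r.mean_nuclear,
                "mean_adjacent": r.mean_adjacent,
                "mean_nonadjacent": r.mean_nonadjacent,
                "norm_adjacent": r.norm_adjacent,
                "norm_nonadjacent": r.norm_nonadjacent,
                "fold": r.fold,
                "qc_flags": ";".join(sorted(r.qc_flags)),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_result_table(results: list[EnrichmentResult], path) -> None:
    frame = results_to_frame(results)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(RESULT_COLUMNS) + "\n")
        for _, row in frame.iterrows():
            fields = []
            for col in RESULT_COLUMNS:
                v = row[col]
                if col in _FLOAT_COLUMNS:
                    fields.append("" if v is None or pd.isna(v) else repr(float(v)))
                else:
                    fields.append(str(v))
            fh.write(",".join(fields) + "\n")


def read_result_table(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, dtype={"unit_id": str, "qc_flags": str}, float_precision="round_trip"
    )
    frame["qc_flags"] = frame["qc_flags"].fillna("")
    return frame
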