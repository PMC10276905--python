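"""Build the patient-level analysis cohort from raw stay-level records.

The analysis unit is one randomly selected hospital stay per adult patient.
Selecting a single stay avoids over-representing codes from patients
readmitted repeatedly for the same condition, and under-representing codes
that drift as diagnostic work-up improves over successive stays.  Diagnosis
codes are normalised to the 4-character ICD-10 category+subdivision form
(uppercase, dot-free) before any frequency counting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: wide-format diagnosis columns accepted in stay CSVs
DX_COLUMNS = [f"dx_{i}" for i in range(1, 51)]


class DataError(ValueError):
    """Raised when input records violate the stay-table contract."""


def truncate_code(code: str) -> str:
    """Normalise an ICD-10 code: uppercase, strip dots, clip to 4 characters.

    ``"M5499" -> "M549"``, ``"e10.9" -> "E109"``; codes shorter than four
    characters after dot removal are returned unchanged.

    Raises
    ------
    DataError
        If *code* is empty or whitespace-only.
    """
    if not isinstance(code, str) or not code.strip():
        raise DataError(f"empty or blank diagnosis code: {code!r}")
    return code.strip().upper().replace(".", "")[:4]


def codes_from_wide(stays: pd.DataFrame) -> pd.Series:
    """Collapse ``dx_1..dx_50`` columns into a list-of-codes column.

    Empty cells (NaN or empty string) mean "no code in this slot".
    """
    dx_cols = [c for c in DX_COLUMNS if c in stays.columns]
    if not dx_cols:
        raise DataError("no dx_1..dx_50 columns found in stay table")
    arr = stays[dx_cols].to_numpy(dtype=object)
    out = []
    for row in arr:
        out.append([c for c in row if isinstance(c, str) and c.strip() != ""])
    return pd.Series(out, index=stays.index, name="codes")


def _ensure_codes_column(stays: pd.DataFrame) -> pd.DataFrame:
    if "codes" in stays.columns:
        return stays
    stays = stays.copy()
    stays["codes"] = codes_from_wide(stays)
    return stays.drop(columns=[c for c in DX_COLUMNS if c in stays.columns])


def filter_adults(stays: pd.DataFrame) -> pd.DataFrame:
    """Keep stays of patients aged >= 18 at admission; log the removed count.

    Raises
    ------
    DataError
        If any row is missing ``age``, naming the offending row.
    """
    if "age" not in stays.columns:
        raise DataError("stay table has no 'age' column")
    missing = stays.index[stays["age"].isna()]
    if len(missing):
        raise DataError(f"missing age at row(s) {list(missing[:5])}")
    kept = stays[stays["age"] >= 18]
    n_removed = len(stays) - len(kept)
    if n_removed:
        logger.info("filter_adults: removed %d stays of minors", n_removed)
    return kept


def select_random_stay(stays: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Select exactly one stay per patient, uniformly at random.

    Rows are sorted by ``(patient_id, stay_id)`` before drawing so the
    selection is reproducible regardless of the storage order of the input.

    Raises
    ------
    DataError
        On duplicate ``(patient_id, stay_id)`` pairs.
    """
    if stays.duplicated(subset=["patient_id", "stay_id"]).any():
        raise DataError("duplicate (patient_id, stay_id) pairs in stay table")
    if stays.empty:
        return stays.copy()
    ordered = stays.sort_values(["patient_id", "stay_id"], kind="mergesort")
    sizes = ordered.groupby("patient_id", sort=True).size()
    starts = np.concatenate([[0], np.cumsum(sizes.to_numpy())[:-1]])
    rng = np.random.default_rng(seed)
    offsets = np.floor(rng.random(len(sizes)) * sizes.to_numpy()).astype(np.int64)
    take = starts + offsets
    return ordered.iloc[take]


def build_patient_table(stays: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Raw stays -> patient-level cohort table.

    Applies, in order: the adult filter, one-random-stay selection, code
    truncation and within-stay de-duplication.  The returned frame has one
    row per patient with a ``codes`` tuple column (first-occurrence order)
    and ``n_diagnoses`` = number of distinct truncated codes.  Idempotent:
    running it on its own output returns the same table.
    """
    stays = _ensure_codes_column(stays)
    adults = filter_adults(stays)
    selected = select_random_stay(adults, seed).copy()
    trunc = []
    for codes in selected["codes"]:
        seen: dict[str, None] = {}
        for c in codes:
            seen.setdefault(truncate_code(c), None)
        trunc.append(tuple(seen))
    selected["codes"] = trunc
    selected["n_diagnoses"] = [len(t) for t in trunc]
    return selected.reset_index(drop=True)


def write_stays_csv(stays: pd.DataFrame, path) -> None:
    """Write a stay table in the wide ``dx_1..dx_50`` CSV dialect."""
    stays = stays.copy()
    if "codes" in stays.columns:
        codes = stays.pop("codes")
        width = max((len(c) for c in codes), default=1)
        wide = pd.DataFrame(
            [list(c) + [""] * (width - len(c)) for c in codes],
            columns=[f"dx_{i}" for i in range(1, width + 1)],
            index=stays.index,
        )
        stays = pd.concat([stays, wide], axis=1)
    stays.to_csv(path, index=False)


def read_stays_csv(path) -> pd.DataFrame:
    """Read a wide stay CSV back into the list-column representation."""
    df = pd.read_csv(path, dtype={"patient_id": str, "stay_id": str})
    return _ensure_codes_column(df)
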