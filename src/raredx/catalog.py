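"""Catalog-based rare-disease flagging.

The comparator to frequency-based classification: a patient "has a rare
disease" if at least one of their truncated diagnosis codes appears in an
ICD-10 rare-disease reference catalog.  Matching is exact on the 4-character
truncated code — no prefix or range semantics, which would silently broaden
the catalog's definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cohort import DataError, truncate_code

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RDCatalog:
    name: str
    codes: frozenset

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError(f"catalog {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.codes)


def load_catalog(path, name: str) -> RDCatalog:
    """Read a one-column CSV (header ``icd10_code``) into a catalog.

    Codes are normalised with :func:`raredx.cohort.truncate_code`;
    duplicates after normalisation collapse with a logged count.
    """
    df = pd.read_csv(path)
    if "icd10_code" not in df.columns:
        raise DataError(f"{path}: expected a column named 'icd10_code'")
    if df.empty:
        raise DataError(f"{path}: catalog file contains no codes")
    codes = []
    for i, raw in enumerate(df["icd10_code"]):
        if not isinstance(raw, str) or not raw.strip():
            raise DataError(f"{path}: malformed code at row {i + 2}")
        codes.append(truncate_code(raw))
    unique = frozenset(codes)
    n_dup = len(codes) - len(unique)
    if n_dup:
        logger.info("load_catalog(%s): collapsed %d duplicate codes", name, n_dup)
    return RDCatalog(name=name, codes=unique)


def match_patients(patients: pd.DataFrame, catalog: RDCatalog) -> pd.DataFrame:
    """Per-patient catalog match: ``n_rd`` = |codes ∩ catalog|, ``has_rd`` = n_rd >= 1."""
    n_rd = [sum(1 for c in set(codes) if c in catalog.codes) for codes in patients["codes"]]
    return pd.DataFrame(
        {"patient_id": patients["patient_id"].to_numpy(), "n_rd": n_rd,
         "has_rd": [n >= 1 for n in n_rd]}
    )
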