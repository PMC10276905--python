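"""Frequency-based rare-diagnosis (FB-RDx) classification.

A diagnosis code's rarity is defined entirely within the analysis dataset:
its frequency is the number of patients whose selected stay carries the
code.  Each patient's *rarity key* is the frequency of their least frequent
code; patients are then partitioned into ten quantile groups (deciles) of
that key, decile 1 holding the ~10% of patients with the rarest diagnoses.
A configurable chapter filter supports the sensitivity variant that ignores
ICD-10 chapters XVIII-XXII (symptoms, injuries, external causes, health-care
contacts, special-purpose codes) before scoring rarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ICD-10 chapter boundaries as (leading letter, 2-digit numeric range).
_CHAPTER_RANGES: list[tuple[str, int, int, str]] = [
    ("A", 0, 99, "I"),
    ("B", 0, 99, "I"),
    ("C", 0, 99, "II"),
    ("D", 0, 48, "II"),
    ("D", 50, 89, "III"),
    ("E", 0, 90, "IV"),
    ("F", 0, 99, "V"),
    ("G", 0, 99, "VI"),
    ("H", 0, 59, "VII"),
    ("H", 60, 95, "VIII"),
    ("I", 0, 99, "IX"),
    ("J", 0, 99, "X"),
    ("K", 0, 93, "XI"),
    ("L", 0, 99, "XII"),
    ("M", 0, 99, "XIII"),
    ("N", 0, 99, "XIV"),
    ("O", 0, 99, "XV"),
    ("P", 0, 96, "XVI"),
    ("Q", 0, 99, "XVII"),
    ("R", 0, 99, "XVIII"),
    ("S", 0, 99, "XIX"),
    ("T", 0, 98, "XIX"),
    ("V", 1, 99, "XX"),
    ("W", 0, 99, "XX"),
    ("X", 0, 99, "XX"),
    ("Y", 0, 98, "XX"),
    ("Z", 0, 99, "XXI"),
    ("U", 0, 99, "XXII"),
]

NON_DISEASE_CHAPTERS = frozenset({"XVIII", "XIX", "XX", "XXI", "XXII"})


def chapter_of(code: str) -> str:
    """ICD-10 chapter (roman numeral I-XXII) of a truncated code.

    Codes outside every known letter/number range map to ``"unknown"``.
    """
    if not code or not code[0].isalpha():
        return "unknown"
    letter = code[0].upper()
    try:
        num = int(code[1:3])
    except (ValueError, IndexError):
        return "unknown"
    for lt, lo, hi, chap in _CHAPTER_RANGES:
        if letter == lt and lo <= num <= hi:
            return chap
    return "unknown"


@dataclass(frozen=True)
class ChapterFilter:
    """Excludes codes of selected ICD-10 chapters from rarity scoring."""

    excluded_chapters: frozenset = field(default_factory=lambda: NON_DISEASE_CHAPTERS)

    def __post_init__(self) -> None:
        unknown = set(self.excluded_chapters) - {c for *_, c in _CHAPTER_RANGES}
        if unknown:
            raise ValueError(f"unknown chapter label(s): {sorted(unknown)}")

    def allows(self, code: str) -> bool:
        return chapter_of(code) not in self.excluded_chapters


@dataclass
class FrequencyTable:
    """Per-code patient counts over the analysis cohort."""

    counts: dict[str, int]
    total_patients: int

    @property
    def n_distinct_codes(self) -> int:
        return len(self.counts)


def compute_code_frequencies(patients: pd.DataFrame) -> FrequencyTable:
    """Count, for every truncated code, the patients whose stay carries it.

    Expects one row per patient with de-duplicated ``codes``; each code
    therefore contributes at most 1 per patient, so the sum of counts equals
    the sum of ``n_diagnoses`` over patients.
    """
    if patients.empty:
        raise ValueError("cannot compute code frequencies on an empty cohort")
    counts: dict[str, int] = {}
    for codes in patients["codes"]:
        for c in codes:
            counts[c] = counts.get(c, 0) + 1
    return FrequencyTable(counts=counts, total_patients=len(patients))


def patient_rarity_key(
    codes,
    freq_table: FrequencyTable,
    chapter_filter: ChapterFilter | None = None,
) -> tuple[int, str] | None:
    """Minimum code frequency over a patient's (optionally filtered) codes.

    Returns ``(rarity_key, rarest_code)`` with ties on the key broken
    lexicographically on the code, or ``None`` if the chapter filter removed
    every code (the patient is unclassifiable in that sensitivity variant).

    Raises
    ------
    KeyError
        If a code is absent from *freq_table* (cohort/table mismatch).
    """
    best: tuple[int, str] | None = None
    for c in codes:
        if chapter_filter is not None and not chapter_filter.allows(c):
            continue
        n = freq_table.counts[c]
        if best is None or (n, c) < best:
            best = (n, c)
    return best


def assign_deciles(rarity_keys: np.ndarray, n_quantiles: int = 10) -> np.ndarray:
    """Quantile-group patients by rarity key, keeping tie blocks together.

    Uses ``q(key) = ceil(n_quantiles * F(key))`` clamped to
    ``[1, n_quantiles]``, with ``F`` the empirical CDF (proportion of
    patients with key <= the given key).  Patients sharing a key always
    share a group, so group sizes are only approximately ``N/n_quantiles``
    when large tie blocks straddle a boundary.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    keys = np.asarray(rarity_keys)
    if keys.size == 0:
        return np.zeros(0, dtype=np.int64)
    order = np.argsort(keys, kind="mergesort")
    sorted_keys = keys[order]
    # rightmost index of each tie block -> F(key) = (idx+1)/N
    is_block_end = np.empty(keys.size, dtype=bool)
    is_block_end[:-1] = sorted_keys[:-1] != sorted_keys[1:]
    is_block_end[-1] = True
    ends = np.nonzero(is_block_end)[0]
    block_sizes = np.diff(np.concatenate([[-1], ends]))
    # every member of a tie block gets the block's rightmost cumulative count
    frac = np.repeat(ends + 1, block_sizes) / keys.size
    dec_sorted = np.ceil(n_quantiles * frac - 1e-12).astype(np.int64)
    np.clip(dec_sorted, 1, n_quantiles, out=dec_sorted)
    deciles = np.empty(keys.size, dtype=np.int64)
    deciles[order] = dec_sorted
    return deciles


def flag_fb_rdx(deciles: np.ndarray, cutoff_quantiles: int = 1, n_quantiles: int = 10) -> np.ndarray:
    """FB-RDx indicator: decile <= cutoff (1 = primary, 2/3 = 20%/30%)."""
    if not 1 <= cutoff_quantiles <= n_quantiles:
        raise ValueError(f"cutoff must be in [1, {n_quantiles}]")
    return np.asarray(deciles) <= cutoff_quantiles


def classify(
    patients: pd.DataFrame,
    freq_table: FrequencyTable | None = None,
    chapter_filter: ChapterFilter | None = None,
    n_quantiles: int = 10,
    cutoff: int = 1,
) -> pd.DataFrame:
    """Full FB-RDx assignment for a patient cohort.

    Returns a frame aligned to classifiable patients with columns
    ``patient_id, rarity_key, rarest_code, decile, fb_rdx``.  Patients whose
    codes are all removed by *chapter_filter* are dropped with a logged
    count.  If *freq_table* is not given it is computed from *patients*.
    """
    if freq_table is None:
        freq_table = compute_code_frequencies(patients)
    rows = []
    n_unclassifiable = 0
    for pid, codes in zip(patients["patient_id"], patients["codes"]):
        best = patient_rarity_key(codes, freq_table, chapter_filter)
        if best is None:
            n_unclassifiable += 1
            continue
        rows.append((pid, best[0], best[1]))
    if n_unclassifiable:
        logger.info("classify: dropped %d unclassifiable patients", n_unclassifiable)
    out = pd.DataFrame(rows, columns=["patient_id", "rarity_key", "rarest_code"])
    out["decile"] = assign_deciles(out["rarity_key"].to_numpy(), n_quantiles)
    out["fb_rdx"] = flag_fb_rdx(out["decile"].to_numpy(), cutoff, n_quantiles)
    return out


def rare_code_set(freq_table: FrequencyTable, assignments: pd.DataFrame, cutoff: int = 1) -> frozenset:
    """Codes whose frequency places them in the lowest *cutoff* quantile(s).

    A code is "rare" if a patient whose rarest code it was would land in
    decile <= cutoff; used to exclude rare diagnoses from the
    number-of-diagnoses covariate in the outcome models.
    """
    key_of_flagged = assignments.loc[assignments["decile"] <= cutoff, "rarity_key"]
    if key_of_flagged.empty:
        return frozenset()
    threshold = key_of_flagged.max()
    return frozenset(c for c, n in freq_table.counts.items() if n <= threshold)


def frequency_table_frame(
    freq_table: FrequencyTable,
    assignments: pd.DataFrame,
    catalogs: dict[str, frozenset] | None = None,
) -> pd.DataFrame:
    """Tidy per-code table: count, decile a patient with this rarest code
    would receive, and catalog-membership flags (one column per catalog)."""
    codes = sorted(freq_table.counts)
    counts = np.array([freq_table.counts[c] for c in codes])
    keys = assignments["rarity_key"].to_numpy()
    keys_sorted = np.sort(keys)
    # decile of a hypothetical patient whose rarity key equals the code count
    frac = np.searchsorted(keys_sorted, counts, side="right") / len(keys_sorted)
    dec = np.clip(np.ceil(10 * np.maximum(frac, 1.0 / len(keys_sorted)) - 1e-12), 1, 10)
    df = pd.DataFrame({"code": codes, "count": counts, "decile_of_code": dec.astype(int)})
    for name, cat in (catalogs or {}).items():
        df[f"in_{name}"] = df["code"].isin(cat)
    return df
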