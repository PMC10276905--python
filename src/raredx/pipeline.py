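"""End-to-end orchestration: stays -> cohort -> rarity/catalog -> models.

The prepared *analysis frame* is the single patient-level table all outcome
models are built from: cohort covariates joined with the frequency-based
rarity assignment, the catalog match, and the number-of-diagnoses counts
that exclude rare codes (frequency-rare codes for FB-RDx/decile models,
catalog codes for the rare-disease models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import models
from .catalog import RDCatalog, match_patients
from .cohort import build_patient_table
from .models import ModelSpec, OutcomeModel, OutcomeResults
from .rarity import ChapterFilter, FrequencyTable, classify, compute_code_frequencies, rare_code_set


def prepare_analysis_frame(
    patients: pd.DataFrame,
    catalog: RDCatalog | None = None,
    cutoff: int = 1,
    n_quantiles: int = 10,
    chapter_filter: ChapterFilter | None = None,
    frequency_basis: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, FrequencyTable]:
    """Join rarity assignment, catalog match and covariate counts.

    ``frequency_basis`` optionally supplies a different table of records to
    count code frequencies on (e.g. all stays instead of the one-per-patient
    cohort); by default frequencies are computed on *patients* itself.
    """
    freq = compute_code_frequencies(frequency_basis if frequency_basis is not None else patients)
    assignments = classify(patients, freq, chapter_filter, n_quantiles, cutoff)
    frame = patients.merge(assignments, on="patient_id", how="inner")

    rare_codes = rare_code_set(freq, assignments, cutoff)
    frame["n_dx_nonrare_fb"] = [
        sum(1 for c in codes if c not in rare_codes) for codes in frame["codes"]
    ]
    if catalog is not None:
        frame = frame.merge(match_patients(frame, catalog), on="patient_id", how="left")
        frame["n_dx_nonrare_rd"] = frame["n_diagnoses"] - frame["n_rd"]
    return frame, freq


@dataclass
class PipelineResult:
    """Everything one synthetic-or-real run produces."""

    frame: pd.DataFrame
    freq_table: FrequencyTable
    results_fb: dict[str, OutcomeResults] = field(default_factory=dict)
    results_rd: dict[str, OutcomeResults] = field(default_factory=dict)


def fit_all_outcomes(frame: pd.DataFrame, predictor: str, adjusted: bool = True) -> dict[str, OutcomeResults]:
    """Fit the five outcome models for one predictor."""
    out = {}
    for outcome in models.OUTCOME_NAMES:
        spec = ModelSpec(outcome=outcome, predictor=predictor, adjusted=adjusted)
        out[outcome] = OutcomeModel(frame, spec).fit()
    return out


def run_pipeline(
    stays: pd.DataFrame,
    seed: int,
    catalog: RDCatalog | None = None,
    cutoff: int = 1,
    fit: bool = True,
) -> PipelineResult:
    """stays -> patient cohort -> classification -> (optionally) all fits."""
    patients = build_patient_table(stays, seed=seed)
    frame, freq = prepare_analysis_frame(patients, catalog=catalog, cutoff=cutoff)
    result = PipelineResult(frame=frame, freq_table=freq)
    if fit:
        result.results_fb = fit_all_outcomes(frame, "fb_rdx")
        if catalog is not None:
            result.results_rd = fit_all_outcomes(frame, "has_rd")
    return result
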