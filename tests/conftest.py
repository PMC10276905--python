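import numpy as np
import pandas as pd
import pytest

from raredx.cohort import build_patient_table
from raredx.models import ModelSpec, OutcomeModel
from raredx.pipeline import prepare_analysis_frame, run_pipeline
from raredx.simulate import SimulationConfig, generate_cohort, generate_rd_catalog


def make_stays(rows):
    """Handcrafted stay table from (patient_id, stay_id, age, codes) tuples."""
    base = {
        "sex": "F", "citizen": True, "admitted_from_home": True,
        "admission_type": "emergency", "insurance_class": "mandatory",
        "hospital_category": "tier2_center", "died": False, "los_days": 3.0,
        "icu": False, "icu_hours": 0.0, "days_to_readmission": np.nan,
    }
    recs = []
    for pid, sid, age, codes in rows:
        recs.append({"patient_id": pid, "stay_id": sid, "age": age, "codes": list(codes), **base})
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def cohort20k():
    """Medium synthetic cohort with its truth table and universe."""
    stays, truth, universe = generate_cohort(SimulationConfig(n_patients=20_000, seed=7))
    return stays, truth, universe


@pytest.fixture(scope="session")
def frame20k(cohort20k):
    """Prepared analysis frame for the medium cohort, with a catalog match."""
    stays, truth, universe = cohort20k
    catalog = generate_rd_catalog(universe, seed=7)
    patients = build_patient_table(stays, seed=8)
    frame, freq = prepare_analysis_frame(patients, catalog=catalog)
    return frame, freq


@pytest.fixture(scope="session")
def cohort50k():
    """Full-scale default-configuration cohort (one stay table + truth)."""
    return generate_cohort(SimulationConfig(n_patients=50_000, seed=11))


@pytest.fixture(scope="session")
def recovery_fits():
    """Adjusted death-model fits across 20 seeded 50k replicates.

    Returns a list of (estimate, ci_low, ci_high) for the FB-RDx odds ratio
    with the generator's configured rarity effect of 1.5 on death.
    """
    out = []
    for seed in range(20):
        stays, _, _ = generate_cohort(SimulationConfig(n_patients=50_000, seed=seed))
        result = run_pipeline(stays, seed=seed + 10_000, catalog=None, fit=False)
        res = OutcomeModel(result.frame, ModelSpec("death", "fb_rdx", adjusted=True)).fit()
        lo, hi = res.predictor_ci
        out.append((res.predictor_estimate, lo, hi))
    return out
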