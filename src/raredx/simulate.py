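"""Seeded synthetic inpatient cohorts with known ground-truth rarity effects.

Emulates the statistical structure of a national hospital-discharge dataset:
a long-tailed (Zipf) diagnosis-code frequency distribution, ~25% of patients
with multiple stays, a median of 6 diagnoses per stay, and configurable
multiplicative effects of a latent "rare patient" indicator on in-hospital
death, 30-day readmission, ICU admission, length of stay (LOS) and ICU LOS.

The latent indicator is defined at generation time from the *generating*
weights (a patient is latently rare when their rarest sampled code sits in
the bottom 10% of patients by weight ranking), so the ground truth is
independent of the frequency-based classifier under test.  It is returned in
a separate truth table and never appears in the observable columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit

from .catalog import RDCatalog
from .rarity import chapter_of

OUTCOMES = ("death", "readmit30", "icu")

#: hospital-category levels of the stay table (8-level factor)
HOSPITAL_CATEGORIES = (
    "tier1_university",
    "tier2_center",
    "tier3_general",
    "tier4_general",
    "tier5_general",
    "other_specialty",
    "rehabilitation_clinic",
    "surgical_clinic",
)


class SimulationConfig(BaseModel):
    """Data-generating parameters for a synthetic cohort.

    Marginal defaults (sex, insurance, admission mix, outcome prevalences,
    diagnoses per stay) mimic a national adult inpatient population; the
    rarity effect sizes are free parameters with a default odds ratio /
    LOS multiplier representing a moderate adverse effect.
    """

    n_patients: int = Field(gt=0)
    n_codes: int = Field(default=2000, ge=20)
    zipf_exponent: float = Field(default=1.5, gt=0)
    p_multi_stay: float = Field(default=0.25, ge=0, le=1)
    extra_stays_mean: float = Field(default=0.62, ge=0)
    diag_nb_r: float = Field(default=2.2, gt=0)
    diag_nb_mean: float = Field(default=11.0, gt=0)
    age_range: tuple[int, int] = (18, 100)
    p_female: float = Field(default=0.56, ge=0, le=1)
    p_swiss: float = Field(default=0.785, ge=0, le=1)
    p_home: float = Field(default=0.904, ge=0, le=1)
    admission_type_probs: tuple[float, float, float] = (0.445, 0.537, 0.018)
    insurance_probs: tuple[float, float, float] = (0.757, 0.150, 0.093)
    hospital_probs: tuple[float, ...] = (0.145, 0.533, 0.086, 0.100, 0.013, 0.017, 0.033, 0.073)
    baseline_risks: dict[str, float] = {"death": 0.02, "readmit30": 0.039, "icu": 0.052}
    rarity_or: dict[str, float] = {"death": 1.5, "readmit30": 1.5, "icu": 1.5}
    # small fixed covariate effects (log-odds): adjustment is non-trivial
    # without dominating the rarity signal
    logodds_age_per_decade: float = 0.10
    logodds_female: float = -0.10
    logodds_emergency: float = 0.20
    los_lognormal: tuple[float, float] = (1.45, 0.75)
    icu_los_lognormal: tuple[float, float] = (3.25, 0.80)
    rarity_los_multiplier: float = Field(default=1.05, gt=0)
    p_late_readmission: float = Field(default=0.20, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.age_range[0] < 18 or self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be [lo >= 18, hi > lo]")
        for d in (self.baseline_risks, self.rarity_or):
            if set(d) != set(OUTCOMES):
                raise ValueError(f"outcome dicts must have keys {OUTCOMES}")
        if any(p <= 0 or p >= 1 for p in self.baseline_risks.values()):
            raise ValueError("baseline risks must be in (0, 1)")
        if any(r <= 0 for r in self.rarity_or.values()):
            raise ValueError("rarity odds ratios must be > 0")
        return self


@dataclass
class CodeUniverse:
    """ICD-10-like code universe ordered by generating frequency rank.

    ``codes[0]`` is the most common code; ``weights`` are the normalised
    Zipf sampling probabilities; ``chapters[i]`` the ICD-10 chapter implied
    by the leading letter of ``codes[i]``.
    """

    codes: list[str]
    weights: np.ndarray
    chapters: list[str]

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("universe codes must be unique")
        if not np.all(self.weights > 0):
            raise ValueError("weights must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be normalised")

    def __len__(self) -> int:
        return len(self.codes)


def generate_code_universe(n_codes: int = 2000, zipf_exponent: float = 1.5, seed: int = 0) -> CodeUniverse:
    """Draw a universe of unique 4-character codes with Zipf weights.

    The weight of the rank-r code is proportional to ``r ** -zipf_exponent``.
    Code strings are sampled without replacement from the letter+3-digit
    grid, so the leading letters (hence ICD-10 chapters) are spread across
    the rank spectrum.
    """
    if n_codes < 20:
        raise ValueError("n_codes must be >= 20")
    rng = np.random.default_rng(seed)
    letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    all_ids = rng.choice(26 * 1000, size=n_codes, replace=False)
    codes = [f"{letters[i // 1000]}{i % 1000:03d}" for i in all_ids]
    ranks = np.arange(1, n_codes + 1, dtype=np.float64)
    w = ranks ** (-zipf_exponent)
    w /= w.sum()
    return CodeUniverse(codes=codes, weights=w, chapters=[chapter_of(c) for c in codes])


def _dedupe_codes_per_stay(stay_idx: np.ndarray, code_idx: np.ndarray, n_stays: int, n_codes: int):
    """Distinct (stay, code) pairs -> per-stay counts and sorted code indices."""
    key = stay_idx.astype(np.int64) * n_codes + code_idx
    uniq = np.unique(key)
    u_stay = uniq // n_codes
    u_code = (uniq % n_codes).astype(np.int64)
    counts = np.bincount(u_stay, minlength=n_stays)
    return counts, u_stay, u_code


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, CodeUniverse]:
    """Generate a synthetic stay table plus its latent truth table.

    Returns ``(stays, truth, universe)``.  ``stays`` has one row per hospital
    stay with a ``codes`` list column and all demographic / administrative /
    outcome fields; ``truth`` carries the latent per-patient rare flag and
    the per-stay linear predictors used at generation time.  Deaths suppress
    readmission; ICU hours are generated only for ICU stays.
    """
    rng = np.random.default_rng(config.seed)
    universe = generate_code_universe(config.n_codes, config.zipf_exponent, seed=int(rng.integers(2**31)))

    n_pat = config.n_patients
    # --- patients -----------------------------------------------------
    multi = rng.random(n_pat) < config.p_multi_stay
    n_stays_per_pat = np.ones(n_pat, dtype=np.int64)
    n_stays_per_pat[multi] = 2 + rng.poisson(config.extra_stays_mean, multi.sum())
    n_stays = int(n_stays_per_pat.sum())

    age = rng.integers(config.age_range[0], config.age_range[1] + 1, n_pat)
    female = rng.random(n_pat) < config.p_female
    swiss = rng.random(n_pat) < config.p_swiss

    pat_of_stay = np.repeat(np.arange(n_pat), n_stays_per_pat)

    # --- per-stay administrative fields -------------------------------
    admission_type = rng.choice(
        np.array(["emergency", "planned", "other"]), size=n_stays, p=config.admission_type_probs
    )
    insurance = rng.choice(
        np.array(["mandatory", "semiprivate", "private"]), size=n_stays, p=config.insurance_probs
    )
    hosp_p = np.asarray(config.hospital_probs, dtype=float)
    hospital = rng.choice(np.array(HOSPITAL_CATEGORIES), size=n_stays, p=hosp_p / hosp_p.sum())
    from_home = rng.random(n_stays) < config.p_home

    # --- diagnosis codes ----------------------------------------------
    # Code sets are drawn per *patient* and repeated on each of the
    # patient's stays: readmissions re-document the same condition (the very
    # over-representation that motivates single-stay selection downstream).
    p_extra = config.diag_nb_r / (config.diag_nb_r + config.diag_nb_mean)
    n_draws = 1 + rng.negative_binomial(config.diag_nb_r, p_extra, n_pat)
    np.clip(n_draws, 1, 50, out=n_draws)
    total = int(n_draws.sum())
    flat_codes = rng.choice(len(universe), size=total, p=universe.weights)
    flat_pat = np.repeat(np.arange(n_pat), n_draws)
    counts, u_pat, u_code = _dedupe_codes_per_stay(flat_pat, flat_codes, n_pat, len(universe))

    code_arr = np.asarray(universe.codes, dtype=object)
    pat_code_lists = [list(c) for c in np.split(code_arr[u_code], np.cumsum(counts)[:-1])]
    codes_col = [pat_code_lists[p] for p in pat_of_stay]

    # --- latent rare flag: rarest sampled code ranked by generating
    # weight; flags the bottom ~10% of patients --------------------------
    max_rank_pat = np.full(n_pat, -1, dtype=np.int64)
    np.maximum.at(max_rank_pat, u_pat, u_code)
    threshold = np.quantile(max_rank_pat, 0.9, method="higher")
    rare_pat = max_rank_pat >= threshold
    rare = rare_pat[pat_of_stay].astype(np.float64)

    # --- outcomes ------------------------------------------------------
    age_c = (age[pat_of_stay] - 59.0) / 10.0
    fem = female[pat_of_stay].astype(np.float64)
    emerg = (admission_type == "emergency").astype(np.float64)
    covar_lp = (
        config.logodds_age_per_decade * age_c
        + config.logodds_female * fem
        + config.logodds_emergency * emerg
    )
    lp = {
        o: logit(config.baseline_risks[o]) + np.log(config.rarity_or[o]) * rare + covar_lp
        for o in OUTCOMES
    }
    died = rng.random(n_stays) < expit(lp["death"])
    icu = rng.random(n_stays) < expit(lp["icu"])
    readmit = (rng.random(n_stays) < expit(lp["readmit30"])) & ~died

    days_to_readm = np.full(n_stays, np.nan)
    days_to_readm[readmit] = rng.integers(1, 31, int(readmit.sum()))
    late = ~readmit & ~died & (rng.random(n_stays) < config.p_late_readmission)
    days_to_readm[late] = rng.integers(31, 366, int(late.sum()))

    mu_los, sd_los = config.los_lognormal
    log_mult = np.log(config.rarity_los_multiplier)
    los = np.exp(rng.normal(mu_los + log_mult * rare, sd_los))
    icu_hours = np.zeros(n_stays)
    mu_ih, sd_ih = config.icu_los_lognormal
    icu_hours[icu] = np.exp(rng.normal(mu_ih + log_mult * rare[icu], sd_ih))

    patient_ids = np.array([f"P{i:07d}" for i in range(n_pat)], dtype=object)
    stays = pd.DataFrame(
        {
            "patient_id": patient_ids[pat_of_stay],
            "stay_id": [f"S{j:08d}" for j in range(n_stays)],
            "age": age[pat_of_stay],
            "sex": np.where(female[pat_of_stay], "F", "M"),
            "citizen": swiss[pat_of_stay],
            "admitted_from_home": from_home,
            "admission_type": admission_type,
            "insurance_class": insurance,
            "hospital_category": hospital,
            "died": died,
            "los_days": np.round(los, 2),
            "icu": icu,
            "icu_hours": np.round(icu_hours, 1),
            "days_to_readmission": days_to_readm,
        }
    )
    stays["codes"] = codes_col

    truth = pd.DataFrame(
        {
            "patient_id": patient_ids[pat_of_stay],
            "stay_id": stays["stay_id"],
            "rare_flag": rare_pat[pat_of_stay],
            "lp_death": lp["death"],
            "lp_readmit30": lp["readmit30"],
            "lp_icu": lp["icu"],
        }
    )
    return stays, truth, universe


def generate_rd_catalog(
    universe: CodeUniverse,
    target_fraction: float = 0.08,
    rarity_bias: float = 3.0,
    seed: int = 0,
) -> RDCatalog:
    """Select a rare-disease code catalog biased towards rare codes.

    A code of frequency rank r (1 = most common) is selected with
    probability proportional to ``exp(rarity_bias * r / n_codes)``, so for
    positive bias the catalog concentrates in the rare tail and
    catalog-flagged patients pile up in the low rarity deciles;
    ``rarity_bias=0`` selects uniformly.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    if rarity_bias < 0:
        raise ValueError("rarity_bias must be >= 0")
    n = len(universe)
    n_sel = int(round(target_fraction * n))
    if n_sel < 1:
        raise ValueError("target_fraction too small: selects no codes; increase it")
    rng = np.random.default_rng(seed)
    r = np.arange(1, n + 1, dtype=np.float64)
    w = np.exp(rarity_bias * (r / n - 1.0))  # shifted for numerical safety
    w /= w.sum()
    idx = rng.choice(n, size=n_sel, replace=False, p=w)
    return RDCatalog(name="synthetic", codes=frozenset(np.asarray(universe.codes, dtype=object)[idx]))


def write_catalog_csv(catalog: RDCatalog, path) -> None:
    pd.DataFrame({"icd10_code": sorted(catalog.codes)}).to_csv(path, index=False)


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
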