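"""Spline basis, exclusion rules, closed-form identities, model fits."""

import numpy as np
import pandas as pd
import pytest

from raredx.models import (
    ModelSpec,
    OutcomeModel,
    apply_exclusions,
    decile_dose_response,
    n_diagnoses_bin,
    rcs_basis,
    rcs_knots,
    unadjusted_or,
)
from conftest import make_stays


# ---------------------------------------------------------------------------
# restricted cubic splines


def rcs_reference(x, t):
    """Independent direct evaluation of the restricted-spline formula."""
    x = np.atleast_1d(np.asarray(x, float))
    k = len(t)
    pos = lambda v: np.where(v > 0, v, 0.0)
    cols = [x]
    for j in range(k - 2):
        num = (
            pos(x - t[j]) ** 3
            - pos(x - t[k - 2]) ** 3 * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + pos(x - t[k - 1]) ** 3 * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        )
        cols.append(num / (t[k - 1] - t[0]) ** 2)
    return np.column_stack(cols)


KNOTS5 = np.array([25.0, 42.0, 59.0, 73.0, 90.0])


def test_rcs_zero_below_first_knot():
    b = rcs_basis(np.array([18.0, 24.9]), KNOTS5)
    assert np.allclose(b[:, 1:], 0.0)
    assert np.allclose(b[:, 0], [18.0, 24.9])


def test_rcs_linear_beyond_last_knot():
    """Second finite differences vanish above the boundary knot."""
    x = np.arange(91.0, 140.0)  # unit grid beyond t_k
    b = rcs_basis(x, KNOTS5)
    second = np.diff(b, n=2, axis=0)
    assert np.max(np.abs(second)) < 1e-8


def test_rcs_continuous_second_derivative_at_knots():
    for t in KNOTS5:
        x = np.array([t - 2e-4, t - 1e-4, t, t + 1e-4, t + 2e-4])
        b = rcs_basis(x, KNOTS5)
        second = np.diff(b, n=2, axis=0) / 1e-8
        assert np.max(np.abs(np.diff(second, axis=0))) < 1e-2


def test_rcs_matches_reference_at_midpoints():
    mids = (KNOTS5[:-1] + KNOTS5[1:]) / 2
    assert np.allclose(rcs_basis(mids, KNOTS5), rcs_reference(mids, KNOTS5), atol=1e-12)


def test_rcs_validates_knots():
    with pytest.raises(ValueError):
        rcs_basis([1.0], [1, 2])
    with pytest.raises(ValueError):
        rcs_basis([1.0], [1, 1, 2])
    with pytest.raises(ValueError):
        rcs_knots([1, 2, 3], n_knots=9)


def test_rcs_knots_are_harrell_quantiles():
    x = np.arange(1000.0)
    np.testing.assert_allclose(
        rcs_knots(x, 5), np.quantile(x, [0.05, 0.275, 0.50, 0.725, 0.95])
    )


# ---------------------------------------------------------------------------
# covariate binning and exclusions


@pytest.mark.parametrize(
    "count, label",
    [(0, "0"), (6, "6"), (10, "10"), (11, "11-12"), (12, "11-12"), (13, "13-15"),
     (14, "13-15"), (15, "13-15"), (16, ">=16"), (40, ">=16")],
)
def test_n_diagnoses_bin(count, label):
    assert n_diagnoses_bin(count) == label


def _toy_cohort():
    df = make_stays([(f"p{i}", f"s{i}", 50, ["A000"]) for i in range(10)])
    df.loc[:1, "died"] = True  # 2 deaths
    df.loc[2:3, "hospital_category"] = "rehabilitation_clinic"
    df.loc[[0, 4, 5], "icu"] = True
    return df


def test_apply_exclusions_rules():
    df = _toy_cohort()
    inc, exc = apply_exclusions(df, "death")
    assert len(inc) == 10 and exc == {}
    inc, exc = apply_exclusions(df, "log_los")
    assert len(inc) == 6 and exc == {"died_in_hospital": 2, "rehabilitation_clinic": 2}
    inc, exc = apply_exclusions(df, "icu_admission")
    assert len(inc) == 8
    inc, exc = apply_exclusions(df, "log_icu_los")
    # 2 died (one of whom was in ICU), 2 rehab, remaining ICU stays only
    assert len(inc) == 2
    with pytest.raises(ValueError):
        apply_exclusions(df, "mortality")


def test_exclusion_accounting_reconciles(frame20k):
    frame, _ = frame20k
    from raredx.models import OUTCOME_NAMES

    for outcome in OUTCOME_NAMES:
        inc, exc = apply_exclusions(frame, outcome)
        assert len(inc) + sum(exc.values()) == len(frame)


# ---------------------------------------------------------------------------
# Woolf odds ratio


def test_unadjusted_or_identities():
    or_, (lo, hi) = unadjusted_or(10, 110, 10, 110)
    assert or_ == pytest.approx(1.0)
    assert lo < 1.0 < hi
    with pytest.raises(ValueError):
        unadjusted_or(0, 10, 2, 10)


def test_unadjusted_or_matches_brute_force():
    rng = np.random.default_rng(12)
    for _ in range(50):
        n1, n2 = rng.integers(20, 200, 2)
        a = rng.integers(1, n1)
        b = rng.integers(1, n2)
        or_, (lo, hi) = unadjusted_or(a, n1, b, n2)
        cross = (a * (n2 - b)) / (b * (n1 - a))
        assert or_ == pytest.approx(cross, rel=1e-12)
        var = 1 / a + 1 / (n1 - a) + 1 / b + 1 / (n2 - b)
        assert np.log(hi / lo) == pytest.approx(2 * 1.96 * np.sqrt(var), rel=1e-12)


# ---------------------------------------------------------------------------
# logistic / log-linear fits


def _binary_frame(n, p_exposed, p1, p0, seed, los=None):
    rng = np.random.default_rng(seed)
    x = rng.random(n) < p_exposed
    y = np.where(x, rng.random(n) < p1, rng.random(n) < p0)
    df = make_stays([(f"p{i}", f"s{i}", 50, ["A000"]) for i in range(n)])
    df["fb_rdx"] = x
    df["died"] = y
    if los is not None:
        df["los_days"] = los
    return df


def test_covariate_free_logistic_equals_crossproduct_or():
    df = _binary_frame(4000, 0.3, 0.15, 0.08, seed=5)
    res = OutcomeModel(df, ModelSpec("death", "fb_rdx", adjusted=False)).fit()
    a = int(df.loc[df["fb_rdx"], "died"].sum())
    n1 = int(df["fb_rdx"].sum())
    b = int(df.loc[~df["fb_rdx"], "died"].sum())
    n2 = int((~df["fb_rdx"]).sum())
    or_, _ = unadjusted_or(a, n1, b, n2)
    assert res.predictor_estimate == pytest.approx(or_, rel=1e-6)


def test_logistic_null_permutation_calibration():
    """Permuted outcomes: the 95% CI covers OR=1 in about 95% of replicates."""
    df = _binary_frame(1500, 0.3, 0.1, 0.1, seed=6)
    rng = np.random.default_rng(7)
    cover = 0
    reps = 60
    for _ in range(reps):
        perm = df.copy()
        perm["died"] = rng.permutation(df["died"].to_numpy())
        res = OutcomeModel(perm, ModelSpec("death", "fb_rdx", adjusted=False)).fit()
        lo, hi = res.predictor_ci
        cover += lo <= 1.0 <= hi
    assert cover / reps >= 0.85


def test_log_linear_exact_identity():
    """Noise-free multiplicative outcome recovers the coefficient exactly."""
    df = make_stays([(f"p{i}", f"s{i}", 50, ["A000"]) for i in range(100)])
    df["fb_rdx"] = np.arange(100) % 2 == 0
    df["los_days"] = 3.0 * np.exp(0.25 * df["fb_rdx"].to_numpy())
    res = OutcomeModel(df, ModelSpec("log_los", "fb_rdx", adjusted=False)).fit()
    assert np.log(res.predictor_estimate) == pytest.approx(0.25, abs=1e-12)


def test_log_linear_equals_geometric_mean_ratio():
    rng = np.random.default_rng(8)
    df = make_stays([(f"p{i}", f"s{i}", 50, ["A000"]) for i in range(500)])
    df["fb_rdx"] = rng.random(500) < 0.4
    df["los_days"] = np.exp(rng.normal(1.5, 0.6, 500))
    res = OutcomeModel(df, ModelSpec("log_los", "fb_rdx", adjusted=False)).fit()
    g1 = np.exp(np.log(df.loc[df["fb_rdx"], "los_days"]).mean())
    g0 = np.exp(np.log(df.loc[~df["fb_rdx"], "los_days"]).mean())
    assert res.predictor_estimate == pytest.approx(g1 / g0, rel=1e-10)


def test_log_linear_rejects_nonpositive_outcome():
    df = make_stays([("p1", "s1", 50, ["A000"]), ("p2", "s2", 50, ["A000"])])
    df["fb_rdx"] = [True, False]
    df.loc[0, "los_days"] = 0.0
    with pytest.raises(ValueError, match="nonpositive"):
        OutcomeModel(df, ModelSpec("log_los", "fb_rdx", adjusted=False)).fit()


def test_perfect_separation_is_flagged():
    df = _binary_frame(200, 0.5, 0.0, 0.0, seed=9)
    df["died"] = df["fb_rdx"]  # exposure determines outcome exactly
    res = OutcomeModel(df, ModelSpec("death", "fb_rdx", adjusted=False)).fit()
    assert res.separation or not res.converged


def test_readmission_definition_and_los_covariate(frame20k):
    """readmit30 = 0 < days <= 30 among survivors; LOS enters the design."""
    frame, _ = frame20k
    model = OutcomeModel(frame, ModelSpec("readmit30", "fb_rdx", adjusted=True))
    assert "log_los" in model.exog.columns
    inc, _ = apply_exclusions(frame, "readmit30")
    d = inc["days_to_readmission"]
    expected = ((d > 0) & (d <= 30)).mean()
    assert model.endog.mean() == pytest.approx(expected)


def test_adjusted_fit_recovers_latent_effect(cohort50k):
    """With the true (latent) exposure the configured death OR of 1.5 is
    recovered without attenuation."""
    from raredx.pipeline import prepare_analysis_frame
    from raredx.cohort import build_patient_table
    from raredx.simulate import SimulationConfig, generate_cohort

    ests = []
    for seed in range(10):
        stays, truth, _ = generate_cohort(SimulationConfig(n_patients=20_000, seed=100 + seed))
        patients = build_patient_table(stays, seed=seed)
        frame, _ = prepare_analysis_frame(patients)
        flag = truth.drop_duplicates("patient_id").set_index("patient_id")["rare_flag"]
        frame = frame.assign(fb_rdx=frame["patient_id"].map(flag).to_numpy())
        res = OutcomeModel(frame, ModelSpec("death", "fb_rdx", adjusted=True)).fit()
        ests.append(res.predictor_estimate)
    assert np.mean(ests) == pytest.approx(1.5, abs=0.1)


def test_rcs_vs_categorical_age_agree(frame20k):
    """Flexible and categorical age adjustment give the same predictor OR
    within 10% — the adjustment style is not load-bearing."""
    frame, _ = frame20k
    a = OutcomeModel(frame, ModelSpec("death", "fb_rdx", adjusted=True, age_adjustment="rcs")).fit()
    b = OutcomeModel(frame, ModelSpec("death", "fb_rdx", adjusted=True, age_adjustment="categorical")).fit()
    assert a.predictor_estimate == pytest.approx(b.predictor_estimate, rel=0.10)


def test_results_interface(frame20k):
    frame, _ = frame20k
    res = OutcomeModel(frame, ModelSpec("death", "fb_rdx", adjusted=True)).fit()
    tidy = res.tidy()
    assert {"term", "estimate", "OR", "ci_low", "ci_high", "se"} <= set(tidy.columns)
    assert (tidy["ci_low"] <= tidy["OR"]).all() and (tidy["OR"] <= tidy["ci_high"]).all()
    assert np.allclose(tidy["OR"], np.exp(tidy["estimate"]))
    assert res.n_included + sum(res.excluded_counts.values()) == len(frame)
    assert "Outcome: death" in res.summary()


# ---------------------------------------------------------------------------
# decile dose-response


def test_dose_response_null_flat(frame20k):
    frame, _ = frame20k
    rng = np.random.default_rng(13)
    null = frame.assign(died=rng.permutation(frame["died"].to_numpy()))
    dr = decile_dose_response(null, "death", adjusted=False)
    assert len(dr.table) == 9
    assert np.all(np.abs(np.log(dr.table["estimate"])) < 1.0)
    assert abs(dr.slope) < 0.1


def test_dose_response_gradient(frame20k):
    """A real rarity effect shows higher ORs in rarer deciles: negative slope
    and decile-1 OR above decile-9."""
    frame, _ = frame20k
    dr = decile_dose_response(frame, "death", adjusted=True)
    assert dr.slope < 0
    est = dr.table.set_index("decile")["estimate"]
    assert est.loc[1] > est.loc[9]
    # reference decile 10 is not among the reported terms
    assert 10 not in dr.table["decile"].to_numpy()
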