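"""Outcome models: adjusted and unadjusted associations of rarity with
in-hospital death, 30-day readmission, ICU admission, LOS and ICU LOS.

The central objects follow the statsmodels idiom: an :class:`OutcomeModel`
is built from a prepared patient-level analysis frame and a
:class:`ModelSpec`; ``fit()`` returns an :class:`OutcomeResults` carrying
coefficients, exponentiated estimates (odds ratios for logistic models,
multiplicative Exp(B) effects for log-linear models), Wald 95% CIs,
inclusion/exclusion accounting and a ``summary()`` table.

Binary outcomes are fitted by maximum-likelihood logistic regression;
length-of-stay outcomes are log-transformed and fitted by OLS, so their
exponentiated coefficients read as multiplicative effects on the geometric
mean.  Age enters through a restricted cubic spline (linear tails, 5 knots
at Harrell's quantiles by default) rather than linearly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

try:  # raised by newton fits on separable designs
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    PerfectSeparationError = RuntimeError

OUTCOME_NAMES = ("death", "readmit30", "icu_admission", "log_los", "log_icu_los")
BINARY_OUTCOMES = {"death", "readmit30", "icu_admission"}
PREDICTORS = ("fb_rdx", "has_rd", "decile_factor")

#: Harrell's default knot placement quantiles by knot count
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}

#: number-of-(non-rare)-diagnoses bins; "0" is the reference level
N_DX_BIN_LABELS = [str(i) for i in range(11)] + ["11-12", "13-15", ">=16"]


# ---------------------------------------------------------------------------
# restricted cubic splines


def rcs_knots(x, n_knots: int = 5) -> np.ndarray:
    """Knot locations at Harrell's default quantiles of *x*."""
    if n_knots not in KNOT_QUANTILES:
        raise ValueError(f"n_knots must be one of {sorted(KNOT_QUANTILES)}")
    return np.quantile(np.asarray(x, dtype=float), KNOT_QUANTILES[n_knots])


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis with linear tails.

    Column 0 is x itself; columns 1..k-2 are the truncated-power terms

        [(x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                    + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2

    which vanish below the first knot and are exactly linear above the
    last, giving a fit with continuous second derivative everywhere.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = len(t)
    scale = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            np.clip(x - t[j], 0, None) ** 3
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# covariate coding and exclusion rules


def n_diagnoses_bin(count: int) -> str:
    """Bin a count of non-rare diagnoses into the model's factor levels."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if count <= 10:
        return str(count)
    if count <= 12:
        return "11-12"
    if count <= 15:
        return "13-15"
    return ">=16"


def apply_exclusions(patients: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, dict[str, int]]:
    """Outcome-specific analysis-population rules.

    death: everyone.  LOS / ICU-LOS / 30-day readmission: drop in-hospital
    deaths.  ICU admission / LOS / ICU-LOS / readmission: drop
    rehabilitation clinics.  ICU-LOS: additionally restrict to ICU stays.
    Returned counts are sequential (each rule counts rows it removed from
    what the previous rules left).
    """
    if outcome not in OUTCOME_NAMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOME_NAMES}")
    df = patients
    excluded: dict[str, int] = {}
    if outcome in ("log_los", "log_icu_los", "readmit30"):
        keep = ~df["died"].astype(bool)
        excluded["died_in_hospital"] = int((~keep).sum())
        df = df[keep]
    if outcome in ("icu_admission", "log_los", "log_icu_los", "readmit30"):
        keep = df["hospital_category"] != "rehabilitation_clinic"
        excluded["rehabilitation_clinic"] = int((~keep).sum())
        df = df[keep]
    if outcome == "log_icu_los":
        keep = df["icu"].astype(bool)
        excluded["not_admitted_to_icu"] = int((~keep).sum())
        df = df[keep]
    return df, excluded


def unadjusted_or(a: int, n1: int, b: int, n2: int) -> tuple[float, tuple[float, float]]:
    """2x2 odds ratio with the Woolf (log) 95% confidence interval.

    *a* events among *n1* exposed, *b* events among *n2* unexposed:
    ``OR = [a/(n1-a)] / [b/(n2-b)]`` and
    ``CI = exp(ln OR +/- 1.96 sqrt(1/a + 1/(n1-a) + 1/b + 1/(n2-b)))``.
    """
    if not (0 < a < n1 and 0 < b < n2):
        raise ValueError(
            "all four cells of the 2x2 table must be positive; "
            "continuity handling for zero cells is out of scope"
        )
    or_ = (a / (n1 - a)) / (b / (n2 - b))
    se = np.sqrt(1 / a + 1 / (n1 - a) + 1 / b + 1 / (n2 - b))
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return float(or_), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# model specification and design construction


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, rarity predictor, adjustment, spline detail."""

    outcome: str
    predictor: str = "fb_rdx"
    adjusted: bool = True
    n_knots: int = 5
    age_adjustment: str = "rcs"  # "rcs" | "categorical"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_NAMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.predictor not in PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.age_adjustment not in ("rcs", "categorical"):
            raise ValueError("age_adjustment must be 'rcs' or 'categorical'")

    @property
    def is_binary(self) -> bool:
        return self.outcome in BINARY_OUTCOMES


_AGE_GROUP_EDGES = [18, 35, 50, 65, 80, np.inf]
_AGE_GROUP_LABELS = ["18-34", "35-49", "50-64", "65-79", "80+"]


def _dummies(series: pd.Series, levels: list[str], ref: str, prefix: str) -> pd.DataFrame:
    cat = pd.Series(pd.Categorical(series, categories=levels), index=series.index)
    if cat.isna().any():
        bad = series[cat.isna()].unique()
        raise ValueError(f"{prefix}: unexpected level(s) {list(bad)}")
    d = pd.get_dummies(cat, prefix=prefix, dtype=float)
    return d.drop(columns=f"{prefix}_{ref}")


def _collapse_sparse_ordinal(bins: pd.Series, labels: list[str], min_count: int = 30):
    """Merge ordinal factor levels with < min_count members into neighbours.

    Sparse levels are absorbed upward (towards the next more-populated
    higher bin), the topmost downward, until every surviving level has at
    least *min_count* members or a single level remains.
    """
    counts = bins.value_counts()
    kept = [l for l in labels if counts.get(l, 0) >= min_count]
    if not kept:
        return pd.Series("any", index=bins.index), ["any"]
    pos = {l: i for i, l in enumerate(labels)}
    kept_pos = np.array([pos[l] for l in kept])
    mapping = {}
    for l in labels:
        if l in kept:
            mapping[l] = l
        else:  # nearest kept level, ties towards the higher bin
            i = pos[l]
            j = kept_pos[np.argmin(np.abs(kept_pos - i) - 1e-9 * (kept_pos > i))]
            mapping[l] = labels[j]
    return bins.map(mapping), kept


def build_design(frame: pd.DataFrame, spec: ModelSpec, knots=None) -> tuple[pd.Series, pd.DataFrame]:
    """Endog/exog for a model spec from a prepared analysis frame.

    The frame must carry the cohort covariates plus ``fb_rdx``, ``decile``,
    ``has_rd`` (as applicable) and ``n_dx_nonrare_fb`` / ``n_dx_nonrare_rd``
    (diagnosis counts excluding frequency-rare / catalog codes).
    """
    if frame.empty:
        raise ValueError("empty design: no rows left after exclusions")
    if spec.outcome == "death":
        y = frame["died"].astype(float)
    elif spec.outcome == "icu_admission":
        y = frame["icu"].astype(float)
    elif spec.outcome == "readmit30":
        d = frame["days_to_readmission"]
        y = ((d > 0) & (d <= 30)).astype(float)  # missing = no readmission
    else:
        raw = frame["los_days"] if spec.outcome == "log_los" else frame["icu_hours"]
        bad = frame.index[~(raw > 0)]
        if len(bad):
            raise ValueError(f"nonpositive outcome values at rows {list(bad[:5])}")
        y = np.log(raw.astype(float))
    y = pd.Series(np.asarray(y, dtype=float), index=frame.index, name=spec.outcome)

    parts: list[pd.DataFrame] = []
    if spec.predictor == "fb_rdx":
        parts.append(frame[["fb_rdx"]].astype(float))
    elif spec.predictor == "has_rd":
        parts.append(frame[["has_rd"]].astype(float))
    else:
        dec = _dummies(frame["decile"].astype(int).astype(str),
                       [str(i) for i in range(1, 11)], ref="10", prefix="decile")
        parts.append(dec)

    if spec.adjusted:
        cov = pd.DataFrame(index=frame.index)
        cov["sex_F"] = (frame["sex"] == "F").astype(float)
        cov["swiss_citizen"] = frame["citizen"].astype(float)
        cov["admitted_from_home"] = frame["admitted_from_home"].astype(float)
        if spec.age_adjustment == "rcs":
            if knots is None:
                knots = rcs_knots(frame["age"], spec.n_knots)
            basis = rcs_basis(frame["age"], knots)
            cov["age"] = basis[:, 0]
            for j in range(1, basis.shape[1]):
                cov[f"age_s{j}"] = basis[:, j]
        else:
            grp = pd.cut(frame["age"], _AGE_GROUP_EDGES, labels=_AGE_GROUP_LABELS,
                         right=False, include_lowest=True).astype(str)
            cov = cov.join(_dummies(grp, _AGE_GROUP_LABELS, ref="18-34", prefix="age_group"))
        ndx_col = "n_dx_nonrare_rd" if spec.predictor == "has_rd" else "n_dx_nonrare_fb"
        bins = frame[ndx_col].map(n_diagnoses_bin)
        # bins with very few patients quasi-separate small cohorts (all or
        # no events in a cell); merge them into the neighbouring bin and use
        # the lowest surviving bin as reference
        bins, labels = _collapse_sparse_ordinal(bins, N_DX_BIN_LABELS, min_count=30)
        cov = cov.join(_dummies(bins, labels, ref=labels[0], prefix="ndx"))
        cov = cov.join(_dummies(frame["admission_type"],
                                ["emergency", "planned", "other"], "emergency", "admission"))
        cov = cov.join(_dummies(frame["insurance_class"],
                                ["mandatory", "semiprivate", "private"], "mandatory", "insurance"))
        from .simulate import HOSPITAL_CATEGORIES

        cov = cov.join(_dummies(frame["hospital_category"], list(HOSPITAL_CATEGORIES),
                                "tier1_university", "hospital"))
        if spec.outcome == "readmit30":
            cov["log_los"] = np.log(frame["los_days"].astype(float))
        parts.append(cov)

    X = pd.concat(parts, axis=1).astype(float)
    # drop empty factor levels (all-zero dummies) so the fit stays full rank
    X = X.loc[:, (X != 0).any(axis=0)]
    X.insert(0, "const", 1.0)
    return y, X


# ---------------------------------------------------------------------------
# model / results objects


class OutcomeModel:
    """A single outcome model bound to its analysis population.

    Parameters
    ----------
    frame : DataFrame
        Prepared patient-level analysis frame *before* exclusions (one row
        per patient; see :func:`raredx.pipeline.prepare_analysis_frame`).
    spec : ModelSpec
    knots : array-like, optional
        Fixed age-spline knots; computed from the included population's age
        distribution when omitted.
    """

    def __init__(self, frame: pd.DataFrame, spec: ModelSpec, knots=None):
        self.spec = spec
        included, self.excluded_counts = apply_exclusions(frame, spec.outcome)
        self.n_excluded = len(frame) - len(included)
        self.endog, self.exog = build_design(included, spec, knots=knots)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, outcome: str, predictor: str = "fb_rdx",
                       adjusted: bool = True, **kw) -> "OutcomeModel":
        return cls(frame, ModelSpec(outcome=outcome, predictor=predictor, adjusted=adjusted), **kw)

    @property
    def n_included(self) -> int:
        return len(self.endog)

    def fit(self) -> "OutcomeResults":
        converged, separation, message = True, False, ""
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            try:
                if self.spec.is_binary:
                    res = sm.Logit(self.endog, self.exog).fit(disp=0, maxiter=200)
                    converged = bool(res.mle_retvals.get("converged", True))
                    if not converged:  # newton can oscillate on sparse cells
                        res = sm.Logit(self.endog, self.exog).fit(
                            disp=0, method="bfgs", maxiter=1000,
                            start_params=res.params,
                        )
                        converged = bool(res.mle_retvals.get("converged", True))
                else:
                    res = sm.OLS(self.endog, self.exog).fit()
            except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as err:
                return OutcomeResults(
                    model=self, params=pd.Series(np.nan, index=self.exog.columns),
                    bse=pd.Series(np.nan, index=self.exog.columns),
                    converged=False, separation=True, message=str(err),
                )
        if not converged:
            message = "maximum-likelihood fit did not converge"
        return OutcomeResults(model=self, params=res.params, bse=res.bse,
                              converged=converged, separation=separation, message=message)


@dataclass
class OutcomeResults:
    """Fitted coefficients with Wald inference and exclusion accounting."""

    model: OutcomeModel
    params: pd.Series
    bse: pd.Series
    converged: bool = True
    separation: bool = False
    message: str = ""

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def n_included(self) -> int:
        return self.model.n_included

    @property
    def excluded_counts(self) -> dict[str, int]:
        return self.model.excluded_counts

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def tidy(self) -> pd.DataFrame:
        """One row per term: estimate, exp(estimate), Wald 95% CI, SE."""
        ci = self.conf_int()
        label = "OR" if self.spec.is_binary else "Exp(B)"
        with np.errstate(over="ignore"):  # near-separated terms: CI bound = inf
            return pd.DataFrame(
                {
                    "term": self.params.index,
                    "estimate": self.params.to_numpy(),
                    label: np.exp(self.params.to_numpy()),
                    "ci_low": np.exp(ci["lower"].to_numpy()),
                    "ci_high": np.exp(ci["upper"].to_numpy()),
                    "se": self.bse.to_numpy(),
                }
            ).reset_index(drop=True)

    # -- convenience accessors for the rarity predictor --------------------
    def _predictor_terms(self) -> list[str]:
        if self.spec.predictor == "decile_factor":
            return [c for c in self.params.index if c.startswith("decile_")]
        return [self.spec.predictor]

    @property
    def predictor_estimate(self) -> float:
        """exp(coefficient) of the (single) rarity predictor term."""
        (term,) = self._predictor_terms()
        return float(np.exp(self.params[term]))

    @property
    def predictor_ci(self) -> tuple[float, float]:
        (term,) = self._predictor_terms()
        ci = self.conf_int().loc[term]
        return float(np.exp(ci["lower"])), float(np.exp(ci["upper"]))

    def summary(self) -> str:
        label = "OR" if self.spec.is_binary else "Exp(B)"
        head = (
            f"Outcome: {self.spec.outcome}  predictor: {self.spec.predictor}  "
            f"{'adjusted' if self.spec.adjusted else 'unadjusted'}\n"
            f"n included: {self.n_included}  excluded: {self.excluded_counts}\n"
            f"converged: {self.converged}  separation: {self.separation}"
        )
        if self.separation:
            return head + f"\n  {self.message}"
        body = self.tidy().to_string(
            index=False,
            formatters={c: "{:.4f}".format for c in ("estimate", label, "ci_low", "ci_high", "se")},
        )
        return head + "\n" + body


# ---------------------------------------------------------------------------
# dose-response across deciles


@dataclass
class DoseResponse:
    """Per-decile estimates vs the most-common decile, with a linear trend."""

    outcome: str
    table: pd.DataFrame  # columns: decile, estimate, ci_low, ci_high
    slope: float
    intercept: float
    results: OutcomeResults


def decile_dose_response(frame: pd.DataFrame, outcome: str, adjusted: bool = True,
                         weighted_trend: bool = False) -> DoseResponse:
    """Fit the decile-factor model (reference = decile 10) for one outcome.

    Returns one OR / Exp(B) per decile 1-9 against decile 10, plus an OLS
    trend line through the point estimates across deciles (unweighted by
    default; ``weighted_trend`` uses inverse-variance weights).
    """
    spec = ModelSpec(outcome=outcome, predictor="decile_factor", adjusted=adjusted)
    res = OutcomeModel(frame, spec).fit()
    terms = [f"decile_{i}" for i in range(1, 10)]
    rows = []
    ci = res.conf_int()
    for i, t in enumerate(terms, start=1):
        if t in res.params.index:
            rows.append((i, float(np.exp(res.params[t])),
                         float(np.exp(ci.loc[t, "lower"])), float(np.exp(ci.loc[t, "upper"])),
                         float(res.bse[t]) ** 2))
        else:  # empty decile after exclusions: flagged by omission
            rows.append((i, np.nan, np.nan, np.nan, np.nan))
    tab = pd.DataFrame(rows, columns=["decile", "estimate", "ci_low", "ci_high", "var_log"])
    ok = tab.dropna(subset=["estimate"])
    w = 1.0 / ok["var_log"] if weighted_trend else None
    slope, intercept = np.polyfit(ok["decile"], ok["estimate"], 1, w=w)
    return DoseResponse(outcome=outcome, table=tab.drop(columns="var_log"),
                        slope=float(slope), intercept=float(intercept), results=res)
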