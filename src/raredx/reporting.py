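"""Paper-shaped deliverables: baseline table, model comparison, plots.

Percentages are rounded half-up to one decimal (the convention of printed
baseline tables); chi-square tests (no continuity correction) compare
categorical variables across strata and Kruskal-Wallis tests (tie-corrected)
compare continuous ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .models import DoseResponse, OutcomeResults


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), unlike banker's round()."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(freq: float, denom: float, ndigits: int = 1) -> float:
    """Percentage ``100*freq/denom`` rounded half-up."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * freq / denom, ndigits)


_STRATA = ("overall", "decile_1", "deciles_2_9", "decile_10")


def _stratum_masks(frame: pd.DataFrame) -> dict[str, pd.Series]:
    d = frame["decile"].astype(int)
    return {
        "overall": pd.Series(True, index=frame.index),
        "decile_1": d == 1,
        "deciles_2_9": d.between(2, 9),
        "decile_10": d == 10,
    }


@dataclass
class BaselineTable:
    """Stratified baseline-characteristics table with group-comparison tests."""

    table: pd.DataFrame  # rows: variable/level; columns: strata
    p_values: pd.Series  # per variable
    stratum_sizes: dict[str, int]

    def to_markdown(self) -> str:
        df = self.table.copy()
        df["p"] = [
            "" if v not in self.p_values.index else f"{self.p_values[v]:.3f}"
            for v in df.index.get_level_values(0)
        ]
        return df.to_markdown()


def baseline_table(
    frame: pd.DataFrame,
    categorical: dict[str, str] | None = None,
    continuous: dict[str, str] | None = None,
) -> BaselineTable:
    """Summarise a classified cohort by decile strata (1 | 2-9 | 10).

    ``categorical``/``continuous`` map display names to column names; the
    defaults cover the standard cohort fields.  Categorical cells are
    ``"% (freq)"`` with half-up 1-decimal percentages; continuous cells are
    ``"median [q1, q3]"``.  Strata with zero patients are omitted with a
    warning column note.
    """
    if categorical is None:
        categorical = {
            "Sex": "sex", "Swiss citizen": "citizen", "Admitted from home": "admitted_from_home",
            "Admission type": "admission_type", "Insurance class": "insurance_class",
            "Hospital category": "hospital_category", "Died in hospital": "died",
            "Stayed in ICU": "icu",
        }
        if "has_rd" in frame.columns:
            categorical["Has a RD"] = "has_rd"
    if continuous is None:
        continuous = {"Age": "age", "Number of diagnoses": "n_diagnoses", "LOS (days)": "los_days"}

    masks = {k: m for k, m in _stratum_masks(frame).items() if m.sum() > 0}
    sizes = {k: int(m.sum()) for k, m in masks.items()}
    strat_cols = [k for k in _STRATA if k in masks]

    rows: dict[tuple[str, str], dict[str, str]] = {}
    pvals: dict[str, float] = {}
    group_key = frame["decile"].astype(int).map(
        lambda d: "decile_1" if d == 1 else ("decile_10" if d == 10 else "deciles_2_9")
    )

    for name, col in categorical.items():
        ser = frame[col]
        levels = sorted(ser.unique(), key=str)
        for lev in levels:
            cells = {}
            for s in strat_cols:
                sub = ser[masks[s]]
                n = int((sub == lev).sum())
                cells[s] = f"{pct(n, len(sub))} ({n})"
            rows[(name, str(lev))] = cells
        ct = pd.crosstab(ser, group_key)
        if ct.shape[0] > 1 and ct.shape[1] > 1:
            pvals[name] = float(stats.chi2_contingency(ct.to_numpy(), correction=False)[1])

    for name, col in continuous.items():
        cells = {}
        groups = []
        for s in strat_cols:
            sub = frame.loc[masks[s], col].astype(float)
            q1, med, q3 = sub.quantile([0.25, 0.5, 0.75])
            cells[s] = f"{med:.2f} [{q1:.2f}, {q3:.2f}]"
        rows[(name, "median [IQR]")] = cells
        for g in ("decile_1", "deciles_2_9", "decile_10"):
            vals = frame.loc[group_key == g, col].astype(float)
            if len(vals):
                groups.append(vals)
        if len(groups) > 1:
            pvals[name] = float(stats.kruskal(*groups)[1])

    table = pd.DataFrame.from_dict(rows, orient="index")[strat_cols]
    table.index = pd.MultiIndex.from_tuples(table.index, names=["variable", "level"])
    return BaselineTable(table=table, p_values=pd.Series(pvals), stratum_sizes=sizes)


def comparison_table(
    results_fb: dict[str, OutcomeResults],
    results_rd: dict[str, OutcomeResults],
) -> pd.DataFrame:
    """Two-column comparison of the five outcomes under both predictors.

    Each cell reads ``"est (lo, hi)"`` to two decimals.  Raises if either
    dict is missing an outcome.
    """
    from .models import OUTCOME_NAMES

    def cell(r: OutcomeResults) -> str:
        e = r.predictor_estimate
        lo, hi = r.predictor_ci
        return f"{e:.2f} ({lo:.2f}, {hi:.2f})"

    rows = []
    for outcome in OUTCOME_NAMES:
        for d, label in ((results_fb, "FB-RDx"), (results_rd, "RD")):
            if outcome not in d:
                raise ValueError(f"missing {label} result for outcome {outcome!r}")
        rows.append(
            {
                "outcome": outcome,
                "measure": "OR" if results_fb[outcome].spec.is_binary else "Exp(B)",
                "FB-RDx (95% CI)": cell(results_fb[outcome]),
                "RD (95% CI)": cell(results_rd[outcome]),
                "n_included_fb": results_fb[outcome].n_included,
                "n_included_rd": results_rd[outcome].n_included,
            }
        )
    return pd.DataFrame(rows)


def dose_response_plot(dr: DoseResponse, path) -> np.ndarray:
    """Per-decile estimates with CI bars and the fitted trend line.

    Saves one figure to *path* and returns the plotted estimate array so
    callers (and tests) can assert on the data rather than on pixels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = dr.table
    fig, ax = plt.subplots(figsize=(6, 4))
    est = tab["estimate"].to_numpy()
    ax.errorbar(
        tab["decile"], est,
        yerr=[est - tab["ci_low"], tab["ci_high"] - est],
        fmt="o", capsize=3, label="estimate (95% CI)",
    )
    xs = np.array([1, 9])
    ax.plot(xs, dr.intercept + dr.slope * xs, color="tab:blue", label="linear trend")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("rarity decile (1 = rarest)")
    ax.set_ylabel("OR vs decile 10" if dr.results.spec.is_binary else "Exp(B) vs decile 10")
    ax.set_title(dr.outcome)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return est


def write_run_manifest(path, seed: int, config: dict, exclusion_counts: dict) -> None:
    """JSON manifest (seed, config, exclusion accounting) for reproducibility."""
    manifest = {"seed": seed, "config": config, "exclusions": exclusion_counts}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
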