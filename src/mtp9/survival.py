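"""Link tumor-normal methylation change to patient survival.

Cohorts are gated on size and event rate, follow-up is administratively
censored at 60 months, and Cox proportional-hazards models relate the
per-patient methylation change to the hazard — once as a continuous
covariate (with a Schoenfeld-residual proportionality check) and once
after a median split into two equal-sized groups for an interpretable
hazard ratio. Ties use the Efron approximation (lifelines default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test

DEFAULT_CENSOR_MONTHS = 60.0
DEFAULT_MIN_N = 50
DEFAULT_MIN_DEATH_RATE = 0.25


def censor_records(
    records: pd.DataFrame, censor_months: float = DEFAULT_CENSOR_MONTHS
) -> pd.DataFrame:
    """Administrative censoring: no record contributes risk time beyond the horizon."""
    if censor_months <= 0:
        raise ValueError("censoring horizon must be positive")
    out = records.copy()
    over = out["time"] > censor_months
    out.loc[over, "time"] = censor_months
    out.loc[over, "event"] = 0
    out["event"] = out["event"].astype(int)
    if (out["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    return out


def cohort_gate(
    records: pd.DataFrame,
    min_n: int = DEFAULT_MIN_N,
    min_death_rate: float = DEFAULT_MIN_DEATH_RATE,
    censor_months: float = DEFAULT_CENSOR_MONTHS,
) -> tuple[bool, str | None]:
    """Eligible iff n >= min_n and the within-horizon event fraction >= min_death_rate."""
    rec = censor_records(records, censor_months)
    n = len(rec)
    if n < min_n:
        return False, "min_n"
    if rec["event"].mean() < min_death_rate:
        return False, "death_rate"
    return True, None


def cox_continuous(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    censor_months: float = DEFAULT_CENSOR_MONTHS,
) -> dict:
    """Cox fit with delta_methylation as a continuous covariate.

    Returns coefficient, se, p and the Schoenfeld-residual PH-test p
    (minimum over covariates); ``ph_ok`` flags PH p > 0.05 but the fit is
    reported regardless.
    """
    rec = censor_records(records, censor_months)
    if rec["event"].sum() == 0:
        raise ValueError("no events in cohort")
    cols = ["time", "event", "delta_methylation", *covariates]
    df = pd.get_dummies(rec[cols], drop_first=True, dtype=float).dropna()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    ph = proportional_hazard_test(cph, df, time_transform="rank")
    ph_p = float(np.min(ph.p_value))
    return {
        "coef": float(cph.params_["delta_methylation"]),
        "se": float(cph.standard_errors_["delta_methylation"]),
        "p_value": float(cph.summary.loc["delta_methylation", "p"]),
        "ph_p": ph_p,
        "ph_ok": ph_p > 0.05,
        "n": len(df),
        "n_events": int(df["event"].sum()),
    }


def median_split(values: pd.Series) -> pd.Series:
    """Two equal-sized groups by value; ties and the odd middle value go low.

    Deterministic: stable sort on (value, original order); the first
    ceil(n/2) records form the low group (0), the rest the high group (1).
    """
    order = values.reset_index(drop=True).sort_values(kind="stable").index
    n = len(order)
    n_low = (n + 1) // 2
    group = pd.Series(np.ones(n, dtype=int), index=values.index)
    group.iloc[order[:n_low]] = 0
    return group


def cox_binned(
    records: pd.DataFrame, censor_months: float = DEFAULT_CENSOR_MONTHS
) -> dict:
    """Cox fit on a high/low methylation-change indicator; HR with Wald CI.

    Also emits Kaplan-Meier survival-curve coordinates per group for
    plotting.
    """
    rec = censor_records(records, censor_months).dropna(subset=["delta_methylation"])
    if rec["event"].sum() == 0:
        raise ValueError("no events in cohort")
    rec = rec.reset_index(drop=True)
    rec["high_delta"] = median_split(rec["delta_methylation"])
    df = rec[["time", "event", "high_delta"]].astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["high_delta"])
    se = float(cph.standard_errors_["high_delta"])
    km_rows = []
    for grp, label in ((0, "low"), (1, "high")):
        sub = rec[rec["high_delta"] == grp]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=label)
        sf = kmf.survival_function_
        for t, s in zip(sf.index, sf[label]):
            km_rows.append({"group": label, "time": float(t), "survival": float(s)})
    def _exp(x: float) -> float:
        return float(np.exp(np.clip(x, -700, 700)))

    return {
        "hr": _exp(coef),
        "ci_low": _exp(coef - 1.96 * se),
        "ci_high": _exp(coef + 1.96 * se),
        "p_value": float(cph.summary.loc["high_delta", "p"]),
        "n_low": int((rec["high_delta"] == 0).sum()),
        "n_high": int((rec["high_delta"] == 1).sum()),
        "km_curves": pd.DataFrame(km_rows, columns=["group", "time", "survival"]),
    }


def survival_scan(
    clinical: pd.DataFrame,
    deltas: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    min_n: int = DEFAULT_MIN_N,
    min_death_rate: float = DEFAULT_MIN_DEATH_RATE,
    censor_months: float = DEFAULT_CENSOR_MONTHS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (cancer, site) Cox models of survival on methylation change.

    ``clinical``: patient_id, time, event (+ covariate columns);
    ``deltas``: patient_id, cancer_type, site_id, delta. Ineligible
    cohorts are reported with a gate reason and no fit. Bonferroni is
    over the sites tested within each cancer.
    """
    rows = []
    for (cancer, site_id), grp in deltas.groupby(["cancer_type", "site_id"]):
        rec = grp.rename(columns={"delta": "delta_methylation"}).merge(
            clinical, on="patient_id"
        )
        rec = rec.dropna(subset=["time", "event", "delta_methylation"])
        ok, reason = cohort_gate(rec, min_n, min_death_rate, censor_months)
        row = {"cancer_type": cancer, "site_id": site_id, "n": len(rec), "eligible": ok, "gate_reason": reason}
        if ok:
            try:
                fit = cox_continuous(rec, covariates, censor_months)
                binned = cox_binned(rec, censor_months)
                row.update(
                    coef=fit["coef"], se=fit["se"], p_value=fit["p_value"],
                    ph_p=fit["ph_p"], hr_binned=binned["hr"],
                    hr_ci_low=binned["ci_low"], hr_ci_high=binned["ci_high"],
                    p_binned=binned["p_value"],
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                row["gate_reason"] = f"fit_error:{exc}"
                row["eligible"] = False
        rows.append(row)
    out = pd.DataFrame(rows)
    for col in ("coef", "se", "p_value", "ph_p", "hr_binned", "hr_ci_low", "hr_ci_high", "p_binned"):
        if col not in out:
            out[col] = np.nan
    m_per_cancer = out[out["eligible"] == True].groupby("cancer_type")["site_id"].transform("size")  # noqa: E712
    out["bonferroni_significant"] = False
    out.loc[m_per_cancer.index, "bonferroni_significant"] = (
        out.loc[m_per_cancer.index, "p_value"] < alpha / m_per_cancer
    )
    return out
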