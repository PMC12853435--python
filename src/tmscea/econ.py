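"""Economic inputs: intervention costing and state-attached rewards.

Intervention (course) costs combine annuitised equipment capital divided
by annual machine throughput, session staff time, training and — for
MRI-guided iTBS — an imaging component. Health-state costs come from a
generalised-estimating-equation (GEE) panel regression of observed
health-service costs on state membership with age/sex/time/site
adjustment; utilities from an ordinary-least-squares panel regression of
cross-walked EQ-5D-3L scores; productivity costs use the human-capital
approach (workdays lost x daily earnings, stratified by state); informal
care is the analogous uncosted hours quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .states import ALIVE_STATES, N_ALIVE

__all__ = [
    "InterventionCostInputs",
    "StateEstimates",
    "annuitise",
    "course_cost",
    "fit_state_costs",
    "fit_state_utilities",
    "state_productivity",
    "state_informal_care",
]

_STATE_NAMES = [s.name.lower() for s in ALIVE_STATES]


def annuitise(capital: float, lifetime_years: float, rate: float) -> float:
    """Equivalent annual cost of a capital outlay over an asset lifetime.

    Standard annuity formula ``capital * rate / (1 - (1+rate)**-lifetime)``;
    the zero-rate limit is straight-line ``capital / lifetime``.
    """
    if lifetime_years <= 0:
        raise ValueError("lifetime must be positive")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return capital / lifetime_years
    return capital * rate / (1.0 - (1.0 + rate) ** (-lifetime_years))


@dataclass(frozen=True)
class InterventionCostInputs:
    """Unit costs and operational profile of one TMS course.

    Equipment capital covers the machine, a replacement coil and leads, an
    extended warranty and two services; it is annuitised over the machine
    lifetime and shared across the machine's annual patient throughput.
    ``imaging_cost`` is nonzero only for MRI-guided iTBS.
    """

    equipment_capital: float
    equipment_lifetime_years: float = 10.0
    throughput_per_year: float = 43.0
    sessions_per_course: float = 27.0
    minutes_per_session: float = 30.0
    staff_cost_per_hour: float = 55.0
    training_cost_per_course: float = 0.0
    imaging_cost: float = 0.0
    discount_rate: float = 0.035

    def __post_init__(self) -> None:
        if self.throughput_per_year < 1:
            raise ValueError("throughput must be at least 1 patient/year")
        for name in ("equipment_capital", "equipment_lifetime_years",
                     "sessions_per_course", "minutes_per_session",
                     "staff_cost_per_hour"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.training_cost_per_course < 0 or self.imaging_cost < 0:
            raise ValueError("training and imaging costs must be non-negative")

    def replace(self, **kwargs) -> "InterventionCostInputs":
        from dataclasses import replace as _replace
        return _replace(self, **kwargs)


def course_cost(inputs: InterventionCostInputs) -> float:
    """Per-patient cost of one TMS course.

    annuitised equipment / throughput + sessions x hours x staff rate
    + training + imaging.
    """
    equip = annuitise(
        inputs.equipment_capital, inputs.equipment_lifetime_years,
        inputs.discount_rate,
    ) / inputs.throughput_per_year
    staff = (
        inputs.sessions_per_course
        * inputs.minutes_per_session / 60.0
        * inputs.staff_cost_per_hour
    )
    return equip + staff + inputs.training_cost_per_course + inputs.imaging_cost


@dataclass(frozen=True)
class StateEstimates:
    """Per-alive-state means and standard errors for one reward quantity."""

    mean: np.ndarray  # (4,) Remission..Severe
    se: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        se = np.asarray(self.se, dtype=float)
        if mean.shape != (N_ALIVE,) or se.shape != (N_ALIVE,):
            raise ValueError("need one (mean, se) pair per alive state")
        if np.any(se < 0):
            raise ValueError("standard errors must be non-negative")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "se", se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "se": self.se}, index=_STATE_NAMES
        ).rename_axis("state")


def _prepare(data: pd.DataFrame, value_col: str) -> pd.DataFrame:
    df = data.copy()
    if df[value_col].isna().any():
        df = df.dropna(subset=[value_col])
    df["state_name"] = pd.Categorical(
        [_STATE_NAMES[int(s)] for s in df["state"]], categories=_STATE_NAMES
    )
    return df


def _adjusted_state_means(result, df: pd.DataFrame, formula_rhs: str) -> StateEstimates:
    """Predict each state's outcome at the sample's mean covariate profile."""
    exog_names = result.model.exog_names
    design = pd.DataFrame(
        result.model.exog, columns=exog_names, index=df.index
    )
    mean_row = design.mean(axis=0)
    means = np.empty(N_ALIVE)
    ses = np.empty(N_ALIVE)
    cov = np.asarray(result.cov_params())
    state_cols = [c for c in exog_names if c.startswith("C(state_name)")]
    for k, name in enumerate(_STATE_NAMES):
        row = mean_row.copy()
        for c in state_cols:
            row[c] = 1.0 if f"[T.{name}]" in c else 0.0
        x = row.to_numpy()
        means[k] = float(x @ np.asarray(result.params))
        ses[k] = float(np.sqrt(x @ cov @ x))
    return StateEstimates(means, ses)


def _covariate_rhs(df: pd.DataFrame, extra: tuple[str, ...] = ()) -> str:
    """Adjustment terms present in the data: age, sex, time and site (factors)."""
    terms = ["C(state_name)"]
    if "age" in df.columns:
        terms.append("age")
    if "sex" in df.columns:
        terms.append("C(sex)")
    for col in extra:
        if col in df.columns:
            terms.append(col)
    if "period" in df.columns and df["period"].nunique() > 1:
        terms.append("C(period)")
    if "site" in df.columns and df["site"].nunique() > 1:
        terms.append("C(site)")
    return " + ".join(terms)


def fit_state_costs(
    data: pd.DataFrame, cov_struct: str = "exchangeable"
) -> StateEstimates:
    """Health-state costs per observation period via GEE panel regression.

    Regresses per-period health-service cost on state membership with
    age, sex, time (factor) and site (factor) adjustment, clustering on
    subject with an exchangeable working correlation (identity available
    for the pooled-least-squares equivalence check). Returns per-state
    adjusted means at the mean covariate profile with robust SEs.
    """
    df = _prepare(data, "cost")
    if (df["cost"] < 0).any():
        raise ValueError("costs must be non-negative")
    structs = {
        "exchangeable": sm.cov_struct.Exchangeable(),
        "independence": sm.cov_struct.Independence(),
    }
    if cov_struct not in structs:
        raise ValueError(f"cov_struct must be one of {sorted(structs)}")
    rhs = _covariate_rhs(df)
    model = smf.gee(
        f"cost ~ {rhs}", groups="subject_id", data=df,
        cov_struct=structs[cov_struct],
    )
    result = model.fit(maxiter=100)
    return _adjusted_state_means(result, df, rhs)


def fit_state_utilities(data: pd.DataFrame) -> StateEstimates:
    """Health-state utilities via OLS panel regression.

    Cross-walked EQ-5D-3L utility on state membership, baseline utility,
    age, sex, ethnicity (when present), time and site effects; returns
    per-state adjusted utilities at the mean covariate profile.
    """
    df = _prepare(data, "utility")
    if (df["utility"] > 1.0).any():
        raise ValueError("utilities cannot exceed 1")
    extra = []
    if "baseline_utility" in df.columns:
        extra.append("baseline_utility")
    if "ethnicity" in df.columns:
        extra.append("C(ethnicity)")
    rhs = _covariate_rhs(df, tuple(extra))
    result = smf.ols(f"utility ~ {rhs}", data=df).fit()
    return _adjusted_state_means(result, df, rhs)


def _stratified_means(
    df: pd.DataFrame, value_col: str, window: tuple[float, float] | None
) -> StateEstimates:
    if window is not None:
        lo, hi = window
        df = df[(df["period_start_week"] >= lo) & (df["period_start_week"] < hi)]
        if df.empty:
            raise ValueError(f"no observations in window {window}")
    means = np.zeros(N_ALIVE)
    ses = np.zeros(N_ALIVE)
    for k in range(N_ALIVE):
        vals = df.loc[df["state"] == k, value_col].to_numpy(dtype=float)
        if len(vals):
            means[k] = vals.mean()
            ses[k] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return StateEstimates(means, ses)


def state_productivity(
    data: pd.DataFrame,
    daily_earnings: float,
    window: tuple[float, float] | None = (0.0, 16.0),
    employed_fraction: float = 1.0,
) -> StateEstimates:
    """Human-capital productivity cost per period by state.

    Mean self-reported workdays lost per state within the observation
    window (base case 0-16 weeks; 16-26 weeks in scenario analysis),
    costed at gross daily earnings and scaled by the employed fraction of
    the cohort.
    """
    if daily_earnings <= 0:
        raise ValueError("daily earnings must be positive")
    if not (0.0 <= employed_fraction <= 1.0):
        raise ValueError("employed fraction must lie in [0, 1]")
    if (data["workdays_lost"] < 0).any():
        raise ValueError("workdays lost cannot be negative")
    est = _stratified_means(data, "workdays_lost", window)
    scale = daily_earnings * employed_fraction
    return StateEstimates(est.mean * scale, est.se * scale)


def state_informal_care(
    data: pd.DataFrame, window: tuple[float, float] | None = (0.0, 16.0)
) -> StateEstimates:
    """Mean informal (unpaid friends/family) care hours per period by state."""
    if (data["care_hours"] < 0).any():
        raise ValueError("care hours cannot be negative")
    return _stratified_means(data, "care_hours", window)
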