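"""Scenario analyses and the operational sensitivity analysis (OSA).

Scenarios rerun the probabilistic analysis with one documented override
of the base case: alternative longer-term maintenance assumptions (best
case, worst case, most optimistic/pessimistic expert), no mortality,
alternative trial sources for utilities and costs, the enhanced-care
(SDS) definition of the TAU trajectory, trial-observed TMS delivery
costs, and the alternative 16-26-week window for productivity and
informal care.

The OSA varies annual machine throughput, sessions per course and
minutes per session over their elicited plausible ranges. Treatment
efficacy is held fixed, so cells differ only through the per-course
intervention cost; all cells share the base run's Monte Carlo draws
(common random numbers), making the resulting ICER and
probability-cost-effective surfaces smooth and monotone in cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import BaseCaseBundle, estimate_inputs
from .econ import course_cost
from .psa import (
    PSAResult,
    incremental_analysis,
    prob_cost_effective_vs,
    run_psa,
    societal_totals,
)
from .transitions import MaintenanceModel

__all__ = [
    "SCENARIO_NAMES",
    "run_scenario",
    "operational_grid",
    "throughput_crossing",
]

SCENARIO_NAMES = (
    "maintenance_best",
    "maintenance_worst",
    "expert_optimistic",
    "expert_pessimistic",
    "no_mortality",
    "smd_params",
    "brightmind_params",
    "tau_sds",
    "brightmind_delivery_costs",
    "informal_16_26",
)

#: Near-zero retained effect immediately beyond 26 weeks (worst case).
_WORST_CASE = MaintenanceModel(shape=1.0, scale_weeks=1e-6)


def _expert_subset_spec(base: BaseCaseBundle, expert: str):
    """Re-pool the maintenance quantities from a single expert's judgments."""
    from .elicitation import judgements_from_frame, linear_pool
    from .transitions import fit_weibull_maintenance

    judgements = judgements_from_frame(base.expert_frame, base.expert_bounds)
    pool52 = linear_pool([j for j in judgements["retained_12m"]
                          if j.expert_id == expert])
    pool78 = linear_pool([j for j in judgements["retained_18m"]
                          if j.expert_id == expert])
    point = fit_weibull_maintenance([(52.0, pool52.median), (78.0, pool78.median)])
    return base.spec.replace(
        maintenance_pool_52=pool52, maintenance_pool_78=pool78,
        maintenance_point=point,
    )


def _scenario_spec(name: str, base: BaseCaseBundle):
    """Resolve a named scenario to its overridden parameter spec."""
    spec = base.spec
    if name == "maintenance_best":
        return spec.replace(
            maintenance_point=MaintenanceModel.constant_one(),
            maintenance_pool_52=None, maintenance_pool_78=None,
        )
    if name == "maintenance_worst":
        return spec.replace(
            maintenance_point=_WORST_CASE,
            maintenance_pool_52=None, maintenance_pool_78=None,
        )
    if name == "no_mortality":
        return spec.replace(annual_mortality=0.0, mortality_rr_sdlog=0.0)
    if name == "expert_optimistic":
        # most optimistic expert = highest maintenance medians (E1)
        return _expert_subset_spec(base, "E1")
    if name == "expert_pessimistic":
        return _expert_subset_spec(base, "E4")
    if name == "tau_sds":
        n_eff = base.spec.tau_counts.sum(axis=1, keepdims=True)
        return spec.replace(tau_counts=base.truth.sds_p6 * n_eff)
    if name == "brightmind_delivery_costs":
        return spec.replace(
            intervention_rtms=spec.intervention_rtms.replace(
                sessions_per_course=20.0, minutes_per_session=60.0),
            intervention_itbs=spec.intervention_itbs.replace(
                sessions_per_course=20.0, minutes_per_session=60.0),
        )
    # estimation-route scenarios: re-simulate and re-fit trial data
    if name == "smd_params":
        return estimate_inputs(truth=base.truth, seed=base.seed,
                               utility_source="smd").spec
    if name == "brightmind_params":
        return estimate_inputs(truth=base.truth, seed=base.seed,
                               cost_source="brightmind").spec
    if name == "informal_16_26":
        return estimate_inputs(truth=base.truth, seed=base.seed,
                               productivity_window=(16.0, 26.0)).spec
    raise ValueError(
        f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
    )


def run_scenario(
    name: str,
    base: BaseCaseBundle,
    n_sims: int = 5000,
    seed: int = 1,
) -> tuple[pd.DataFrame, PSAResult]:
    """Run one named scenario's probabilistic analysis.

    Returns the incremental table (health-service perspective) and the
    full PSA result. Overrides beyond the bundle swap: the maintenance
    best/worst cases replace the retained-effect curve with a constant 1
    or (near) 0 held at point mass; ``no_mortality`` zeroes the
    background death rate.
    """
    spec = _scenario_spec(name, base)
    result = run_psa(spec, n_sims=n_sims, seed=seed)
    means = result.means()
    table = incremental_analysis(
        {a: (means.loc[a, "cost"], means.loc[a, "qalys"]) for a in result.arms}
    )
    return table, result


@dataclass(frozen=True)
class OperationalGrid:
    """OSA surface: one row per (throughput, sessions, minutes) cell."""

    table: pd.DataFrame
    lam: float


def operational_grid(
    base: BaseCaseBundle,
    throughputs: np.ndarray,
    sessions: np.ndarray,
    minutes: np.ndarray,
    lam: float = 20_000.0,
    n_sims: int = 5000,
    seed: int = 1,
    base_result: PSAResult | None = None,
) -> OperationalGrid:
    """ICER and P(cost-effective) surfaces over operational parameters.

    Efficacy is independent of delivery within the elicited plausible
    ranges, so only the per-course cost varies across cells. The base
    PSA's draws are reused in every cell with the per-cell course-cost
    difference added to each arm's cost draws — identical to rerunning
    the PSA per cell with common seeds.
    """
    for name, g in (("throughput", throughputs), ("sessions", sessions),
                    ("minutes", minutes)):
        g = np.asarray(g, dtype=float)
        if g.size == 0:
            raise ValueError(f"{name} range is empty")
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} grid must be strictly increasing")

    spec = base.spec
    result = base_result or run_psa(spec, n_sims=n_sims, seed=seed)
    base_cc = {"rtms": course_cost(spec.intervention_rtms),
               "itbs": course_cost(spec.intervention_itbs)}
    base_inputs = {"rtms": spec.intervention_rtms, "itbs": spec.intervention_itbs}

    rows = []
    for tp in np.asarray(throughputs, dtype=float):
        for ns in np.asarray(sessions, dtype=float):
            for mins in np.asarray(minutes, dtype=float):
                row = {"throughput": tp, "sessions": ns, "minutes": mins}
                for arm in ("rtms", "itbs"):
                    cc = course_cost(base_inputs[arm].replace(
                        throughput_per_year=tp, sessions_per_course=ns,
                        minutes_per_session=mins,
                    ))
                    delta = cc - base_cc[arm]
                    cost = result.cost[arm] + delta
                    dc = cost.mean() - result.cost["tau"].mean()
                    dq = result.qalys[arm].mean() - result.qalys["tau"].mean()
                    icer = dc / dq if dq > 0 else np.nan
                    shifted = PSAResult(
                        cost={arm: cost, "tau": result.cost["tau"]},
                        qalys={arm: result.qalys[arm],
                               "tau": result.qalys["tau"]},
                        informal_hours={arm: result.informal_hours[arm],
                                        "tau": result.informal_hours["tau"]},
                        productivity_cost={
                            arm: result.productivity_cost[arm],
                            "tau": result.productivity_cost["tau"]},
                        seed=result.seed, n_sims=result.n_sims,
                    )
                    p_ce = prob_cost_effective_vs(shifted, arm, "tau", lam)
                    row[f"course_cost_{arm}"] = cc
                    row[f"icer_{arm}"] = icer
                    row[f"p_ce_{arm}"] = p_ce
                rows.append(row)
    return OperationalGrid(table=pd.DataFrame(rows), lam=lam)


def throughput_crossing(
    grid: OperationalGrid, arm: str = "rtms", threshold: float = 30_000.0
) -> float:
    """Throughput at which the arm's ICER vs TAU crosses the threshold.

    Interpolates along the throughput axis at the base sessions/minutes
    cell (the grid's median sessions and minutes values); returns NaN if
    the ICER never crosses within the grid.
    """
    t = grid.table
    ns = np.median(t["sessions"].unique())
    mins = np.median(t["minutes"].unique())
    sub = t[(t["sessions"] == ns) & (t["minutes"] == mins)].sort_values("throughput")
    x = sub["throughput"].to_numpy()
    y = sub[f"icer_{arm}"].to_numpy()
    above = y > threshold
    if not above.any() or above.all():
        return float("nan")
    i = int(np.argmax(~above))  # first index at/below the threshold
    x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
    return float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0))
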