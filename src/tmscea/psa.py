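"""Probabilistic sensitivity analysis and cost-effectiveness outputs.

Monte Carlo propagation of parameter uncertainty (base 5000 draws),
pairwise and fully incremental cost-effectiveness with dominance and
extended-dominance handling, cost-effectiveness acceptability curves
(CEACs) via net monetary benefit, and convergence diagnostics. Arms share
each draw's common parameters (common random numbers), reflecting the
identical baseline population across alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bundle import (
    ARMS,
    ParameterSet,
    ParameterSpec,
    deterministic_run,
    point_estimate,
)
from .engine import ModelSettings, Totals
from .transitions import MaintenanceModel, fit_weibull_maintenance

__all__ = [
    "WillingnessToPay",
    "PSAResult",
    "sample_parameters",
    "run_psa",
    "incremental_analysis",
    "ceac",
    "societal_totals",
    "running_mean",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WillingnessToPay:
    """Willingness-to-pay grid: £0-100,000/QALY in £1000 steps by default."""

    grid: np.ndarray = field(
        default_factory=lambda: np.arange(0, 100_001, 1000, dtype=float)
    )
    nice_band: tuple[float, float] = (20_000.0, 30_000.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("willingness-to-pay grid must be increasing")
        object.__setattr__(self, "grid", g)


@dataclass(frozen=True)
class PSAResult:
    """Per-arm draws of discounted outcomes from one probabilistic run."""

    cost: dict[str, np.ndarray]
    qalys: dict[str, np.ndarray]
    informal_hours: dict[str, np.ndarray]
    productivity_cost: dict[str, np.ndarray]
    seed: int
    n_sims: int
    n_excluded: int = 0
    perspective: str = "health_service"

    def __post_init__(self) -> None:
        for d in (self.cost, self.qalys, self.informal_hours,
                  self.productivity_cost):
            for arm, v in d.items():
                v = np.asarray(v, dtype=float)
                if len(v) != self.n_sims:
                    raise ValueError(f"{arm}: draw array length != n_sims")
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"{arm}: non-finite draws present")
                d[arm] = v

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(self.cost)

    def means(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cost": {a: self.cost[a].mean() for a in self.arms},
            "qalys": {a: self.qalys[a].mean() for a in self.arms},
            "informal_hours": {a: self.informal_hours[a].mean() for a in self.arms},
            "productivity_cost": {
                a: self.productivity_cost[a].mean() for a in self.arms
            },
        }).rename_axis("arm")


def _gamma_vec(mean: np.ndarray, se: np.ndarray, rng) -> np.ndarray:
    out = np.array(mean, dtype=float)
    for i in range(len(out)):
        if se[i] > 0 and mean[i] > 0:
            shape = (mean[i] / se[i]) ** 2
            out[i] = rng.gamma(shape, mean[i] / shape)
    return out


def _beta_vec(mean: np.ndarray, se: np.ndarray, rng) -> np.ndarray:
    """Method-of-moments beta draws for quantities bounded in (0, 1)."""
    out = np.array(mean, dtype=float)
    for i in range(len(out)):
        m, s = mean[i], se[i]
        if s <= 0 or not (0 < m < 1):
            continue
        nu = m * (1 - m) / s**2 - 1.0
        if nu <= 0:
            continue
        out[i] = rng.beta(m * nu, (1 - m) * nu)
    return out


def _dirichlet_matrix(counts: np.ndarray, rng) -> np.ndarray:
    out = np.eye(counts.shape[0])
    for i, row in enumerate(counts):
        pos = row > 0
        if pos.sum() == 0:
            continue
        if pos.sum() == 1:
            out[i] = 0.0
            out[i, pos] = 1.0
            continue
        out[i] = 0.0
        out[i, pos] = rng.dirichlet(row[pos])
    return out


def _sample_maintenance(spec: ParameterSpec, rng) -> MaintenanceModel:
    """Draw a retained-effect curve from the pooled elicitation.

    Expert-consistent sampling: one expert (by pool weight) and one
    quantile level are drawn and applied to both the 12- and 18-month
    retained fractions, so each draw is a coherent judgment pair (the
    18-month fraction never exceeds the 12-month one, since every
    expert's quantiles are ordered). The two anchored points determine
    the Weibull (shape, scale) in closed form; the shape is clamped to a
    numerically safe range.
    """
    pool52, pool78 = spec.maintenance_pool_52, spec.maintenance_pool_78
    if pool52 is None or pool78 is None:
        return spec.maintenance_point
    # components are ordered identically (grouped by expert id) in both pools
    e = int(rng.choice(len(pool52.components), p=pool52.weights))
    u = rng.random()
    f12 = float(np.clip(pool52.components[e].ppf(u), 1e-4, 1.0 - 1e-6))
    f18 = float(np.clip(min(pool78.components[e].ppf(u), f12 * (1 - 1e-9)),
                        1e-8, None))
    y1, y2 = np.log(-np.log(f12)), np.log(-np.log(f18))
    x1, x2 = np.log(52.0 - 26.0), np.log(78.0 - 26.0)
    k = float(np.clip((y2 - y1) / (x2 - x1), 0.05, 8.0))
    lam = (52.0 - 26.0) / (-np.log(f12)) ** (1.0 / k)
    return MaintenanceModel(shape=k, scale_weeks=float(lam))


def sample_parameters(spec: ParameterSpec, rng_seed) -> ParameterSet:
    """Draw one coherent parameter set from the spec's distributions.

    ``rng_seed`` may be an integer or a ``numpy.random.Generator``; the
    same seed yields the same draw. Transition rows are drawn jointly per
    row (Dirichlet); groups listed in ``spec.point_mass_inputs`` stay at
    their point estimates.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    pm = spec.point_mass_inputs
    base = point_estimate(spec)
    kwargs = {}
    if "transitions" not in pm:
        kwargs["tau_p6"] = _dirichlet_matrix(spec.tau_counts, rng)
        kwargs["p_rtms"] = _dirichlet_matrix(spec.rtms_counts, rng)
        kwargs["p_itbs"] = _dirichlet_matrix(spec.itbs_counts, rng)
    if "costs" not in pm:
        kwargs["cost_per_cycle"] = _gamma_vec(spec.cost.mean, spec.cost.se, rng)
    if "utilities" not in pm:
        kwargs["utility"] = _beta_vec(spec.utility.mean, spec.utility.se, rng)
    if "productivity" not in pm:
        kwargs["productivity_cost_per_cycle"] = _gamma_vec(
            spec.productivity.mean, spec.productivity.se, rng
        )
    if "care" not in pm:
        kwargs["care_hours_per_cycle"] = _gamma_vec(
            spec.care.mean, spec.care.se, rng
        )
    if "maintenance" not in pm:
        kwargs["maintenance"] = _sample_maintenance(spec, rng)
    if "mortality" not in pm and spec.mortality_rr_sdlog > 0:
        kwargs["mortality_rr"] = float(
            spec.mortality_rr * np.exp(rng.normal(0.0, spec.mortality_rr_sdlog))
        )
    return base.replace(**kwargs)


def run_psa(
    spec: ParameterSpec,
    n_sims: int = 5000,
    seed: int = 1,
) -> PSAResult:
    """Monte Carlo probabilistic analysis.

    Each draw builds schedules and rewards for all three arms from the
    same parameter set (shared inputs shared, arm-specific transition
    matrices arm-specific), runs the cohort engine, and records the four
    discounted outcomes. Draws producing non-finite outcomes are excluded
    and counted.
    """
    rng = np.random.default_rng(seed)
    settings = spec.settings
    store = {
        key: {arm: np.empty(n_sims) for arm in ARMS}
        for key in ("cost", "qalys", "informal_hours", "productivity_cost")
    }
    kept = 0
    excluded = 0
    while kept < n_sims:
        ps = sample_parameters(spec, rng)
        draws = deterministic_run(ps, settings)
        ok = all(
            np.isfinite([t.cost, t.qalys, t.informal_hours, t.productivity_cost]).all()
            for t in draws.values()
        )
        if not ok:
            excluded += 1
            if excluded > max(100, n_sims // 10):
                raise RuntimeError("too many excluded PSA draws")
            continue
        for arm in ARMS:
            t = draws[arm]
            store["cost"][arm][kept] = t.cost
            store["qalys"][arm][kept] = t.qalys
            store["informal_hours"][arm][kept] = t.informal_hours
            store["productivity_cost"][arm][kept] = t.productivity_cost
        kept += 1
    if excluded:
        logger.warning("excluded %d PSA draw(s) with non-finite outcomes", excluded)
    return PSAResult(
        cost=store["cost"], qalys=store["qalys"],
        informal_hours=store["informal_hours"],
        productivity_cost=store["productivity_cost"],
        seed=seed, n_sims=n_sims, n_excluded=excluded,
    )


def societal_totals(result: PSAResult) -> PSAResult:
    """Societal-perspective variant: add productivity costs to costs.

    Informal care stays an uncosted secondary outcome reported in hours.
    """
    return replace(
        result,
        cost={a: result.cost[a] + result.productivity_cost[a]
              for a in result.arms},
        perspective="societal",
    )


def incremental_analysis(means: dict[str, tuple[float, float]],
                         reference: str = "tau") -> pd.DataFrame:
    """Pairwise and fully incremental cost-effectiveness table.

    ``means`` maps arm name to (mean cost, mean QALYs). The pairwise
    block compares every non-reference arm with the reference; the fully
    incremental block sorts by cost (ties broken by higher effect first),
    drops dominated options (more costly, fewer QALYs than a cheaper
    option), then repeatedly drops extendedly dominated options (ICER
    exceeding the next more-effective option's) and reports frontier
    ICERs. Dominated options are flagged, not given ICERs.
    """
    if len(means) < 2:
        raise ValueError("need at least two alternatives")
    if reference not in means:
        raise ValueError(f"reference arm {reference!r} missing")

    rows = []
    ref_c, ref_q = means[reference]
    for arm, (c, q) in means.items():
        if arm == reference:
            continue
        dc, dq = c - ref_c, q - ref_q
        if dc <= 0 and dq >= 0 and (dc < 0 or dq > 0):
            icer, flag = np.nan, "dominant"
        elif dc >= 0 and dq <= 0 and (dc > 0 or dq < 0):
            icer, flag = np.nan, "dominated"
        else:
            icer, flag = dc / dq, "icer"
        rows.append({"block": "pairwise", "arm": arm, "comparator": reference,
                     "cost": c, "qalys": q, "d_cost": dc, "d_qalys": dq,
                     "icer": icer, "status": flag})

    # fully incremental frontier
    order = sorted(means, key=lambda a: (means[a][0], -means[a][1]))
    status = {a: "on_frontier" for a in order}
    frontier = list(order)
    # strict dominance: more costly and not more effective than a cheaper option
    changed = True
    while changed:
        changed = False
        for i in range(1, len(frontier)):
            a = frontier[i]
            if any(means[b][1] >= means[a][1] for b in frontier[:i]):
                status[a] = "dominated"
                frontier.pop(i)
                changed = True
                break
    # extended dominance: ICER above the next more-effective option's
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            a, b, c = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_ab = (means[b][0] - means[a][0]) / (means[b][1] - means[a][1])
            icer_bc = (means[c][0] - means[b][0]) / (means[c][1] - means[b][1])
            if icer_ab > icer_bc:
                status[b] = "extendedly_dominated"
                frontier.pop(i)
                changed = True
                break
    prev = None
    for arm in order:
        c, q = means[arm]
        row = {"block": "incremental", "arm": arm, "comparator": prev,
               "cost": c, "qalys": q, "d_cost": np.nan, "d_qalys": np.nan,
               "icer": np.nan, "status": status[arm]}
        if status[arm] == "on_frontier":
            idx = frontier.index(arm)
            if idx > 0:
                comp = frontier[idx - 1]
                row["comparator"] = comp
                row["d_cost"] = c - means[comp][0]
                row["d_qalys"] = q - means[comp][1]
                row["icer"] = row["d_cost"] / row["d_qalys"]
            prev = arm
        rows.append(row)
    return pd.DataFrame(rows)


def nmb_matrix(result: PSAResult, lam: float) -> pd.DataFrame:
    return pd.DataFrame(
        {a: lam * result.qalys[a] - result.cost[a] for a in result.arms}
    )


def ceac(result: PSAResult, wtp: WillingnessToPay | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    At each willingness-to-pay λ, the probability that each alternative
    has the maximal net monetary benefit λ·Q − C across all alternatives;
    exact ties split their probability equally.
    """
    wtp = wtp or WillingnessToPay()
    arms = result.arms
    Q = np.column_stack([result.qalys[a] for a in arms])
    C = np.column_stack([result.cost[a] for a in arms])
    out = {"lambda": wtp.grid}
    probs = np.zeros((len(wtp.grid), len(arms)))
    for i, lam in enumerate(wtp.grid):
        nmb = lam * Q - C
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    for j, a in enumerate(arms):
        out[a] = probs[:, j]
    return pd.DataFrame(out)


def prob_cost_effective_vs(
    result: PSAResult, arm: str, reference: str, lam: float
) -> float:
    """Pairwise probability that ``arm`` beats ``reference`` at λ."""
    nmb_a = lam * result.qalys[arm] - result.cost[arm]
    nmb_r = lam * result.qalys[reference] - result.cost[reference]
    return float(np.mean(nmb_a > nmb_r) + 0.5 * np.mean(nmb_a == nmb_r))


def running_mean(draws: np.ndarray) -> np.ndarray:
    """Running mean over draws — the convergence-diagnostic curve."""
    return np.cumsum(draws) / np.arange(1, len(draws) + 1)
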