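"""Estimation of per-cycle health-state transition matrices.

Three routes feed the cohort engine:

* **TMS arms** — a time-homogeneous continuous-time Markov chain (CTMC)
  over the four alive states, fitted to interval-censored panel data
  (HDRS observed at scheduled visits, the state path between visits
  unobserved) by maximising the product of matrix-exponential interval
  likelihoods. The 2-week cycle matrix is ``expm(Q * 2)``.
* **TAU** — transitions observed at biannual assessments, assumed to
  occur uniformly within each 6-month interval: the per-cycle matrix is
  the principal 13th matrix root of the interval matrix, obtained via the
  matrix logarithm with a non-negativity regularisation on the generator.
* **Maintenance beyond 26 weeks** — a Weibull retained-effect curve
  ``w(t) = exp(-(((t-26)/lambda))**k)`` anchored at 1 at 26 weeks, fitted
  to pooled expert judgments; the TMS cohort's alive composition is then
  blended toward the contemporaneous TAU composition with weight ``w``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm, logm
from scipy.optimize import least_squares, minimize

from .engine import ModelSettings
from .states import N_ALIVE, classify_hdrs, classify_hdrs_array

__all__ = [
    "CTMCFit",
    "MaintenanceModel",
    "classify_hdrs",
    "panel_with_states",
    "fit_ctmc",
    "ctmc_to_cycle_matrix",
    "interval_matrix_to_cycle",
    "count_interval_transitions",
    "fit_weibull_maintenance",
    "blend_to_tau",
]

logger = logging.getLogger(__name__)

_MAINT_ANCHOR_WEEKS = 26.0


def panel_with_states(panel: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``state`` column (integer codes) to a long HDRS panel.

    Accepts either an ``hdrs_score`` column (classified into severity
    bands) or a pre-coded ``state`` column. Visit weeks must be strictly
    increasing within subject.
    """
    df = panel.copy()
    if "state" not in df.columns:
        df["state"] = classify_hdrs_array(df["hdrs_score"].to_numpy())
    df = df.sort_values(["subject_id", "visit_week"], kind="stable")
    gaps = df.groupby("subject_id")["visit_week"].diff().dropna()
    if (gaps <= 0).any():
        raise ValueError("visit weeks must be strictly increasing within subject")
    if (df["visit_week"] < 0).any():
        raise ValueError("visit weeks must be non-negative")
    return df


def _interval_counts(df: pd.DataFrame, n_states: int) -> dict[float, np.ndarray]:
    """Aggregate observed (from, to) pairs into count matrices keyed by gap."""
    counts: dict[float, np.ndarray] = {}
    for _, g in df.groupby("subject_id", sort=False):
        s = g["state"].to_numpy()
        t = g["visit_week"].to_numpy(dtype=float)
        for i in range(len(s) - 1):
            dt = round(float(t[i + 1] - t[i]), 6)
            c = counts.setdefault(dt, np.zeros((n_states, n_states)))
            c[s[i], s[i + 1]] += 1.0
    return counts


@dataclass(frozen=True)
class CTMCFit:
    """Fitted intensity matrix with convergence metadata."""

    Q: np.ndarray
    log_likelihood: float
    converged: bool
    n_starts: int
    message: str = ""

    def cycle_matrix(self, settings: ModelSettings) -> np.ndarray:
        return ctmc_to_cycle_matrix(self.Q, settings)


def _q_from_log_rates(theta: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n = mask.shape[0]
    Q = np.zeros((n, n))
    Q[mask] = np.exp(theta)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def fit_ctmc(
    panel: pd.DataFrame,
    n_states: int = N_ALIVE,
    structure: str = "full",
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
) -> CTMCFit:
    """Fit a time-homogeneous CTMC to interval-censored panel data.

    Maximises ``sum over observed pairs of n_{dt,i,j} * log [expm(Q dt)]_{ij}``
    over intensity matrices ``Q`` with the permitted jump ``structure``
    (``"full"``: all off-diagonals; ``"tridiagonal"``: adjacent-severity
    moves only). Optimisation runs on log-intensities (positivity by
    construction) with multi-start quasi-Newton; the best local optimum is
    returned with convergence metadata. A state row with no observed exits
    is driven toward zero rates by the likelihood itself; rates hitting the
    lower bound are reported as-is (effectively regularised to ~0).
    """
    df = panel_with_states(panel)
    counts = _interval_counts(df, n_states)
    if not counts:
        raise ValueError("panel contains no observation pairs")

    mask = ~np.eye(n_states, dtype=bool)
    if structure == "tridiagonal":
        adj = np.zeros((n_states, n_states), dtype=bool)
        for i in range(n_states - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        mask &= adj
    elif structure != "full":
        raise ValueError("structure must be 'full' or 'tridiagonal'")
    n_par = int(mask.sum())

    dts = sorted(counts)
    count_stack = [counts[dt] for dt in dts]

    def nll(theta: np.ndarray) -> float:
        Q = _q_from_log_rates(theta, mask)
        total = 0.0
        for dt, c in zip(dts, count_stack):
            P = expm(Q * dt)
            with np.errstate(divide="ignore", invalid="ignore"):
                logP = np.log(np.clip(P, 1e-300, None))
            total -= float((c * logP).sum())
        return total

    rng = np.random.default_rng(seed)
    best = None
    bounds = [(-20.0, 3.0)] * n_par
    for start in range(max(1, n_starts)):
        theta0 = np.full(n_par, np.log(0.02))
        if start > 0:
            theta0 = theta0 + rng.normal(0.0, 1.0, size=n_par)
        res = minimize(
            nll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    Q = _q_from_log_rates(best.x, mask)
    if not best.success:
        logger.warning("CTMC fit did not converge cleanly: %s", best.message)
    return CTMCFit(
        Q=Q,
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        n_starts=n_starts,
        message=str(best.message),
    )


def ctmc_to_cycle_matrix(Q: np.ndarray, settings: ModelSettings) -> np.ndarray:
    """Per-cycle transition matrix ``expm(Q * cycle_length_weeks)``."""
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-8):
        raise ValueError("generator rows must sum to 0")
    off = Q[~np.eye(Q.shape[0], dtype=bool)]
    if np.any(off < -1e-12):
        raise ValueError("generator off-diagonals must be non-negative")
    return expm(Q * settings.cycle_length_weeks)


def interval_matrix_to_cycle(
    P_interval: np.ndarray, interval_cycles: int
) -> tuple[np.ndarray, float]:
    """Per-cycle matrix whose ``interval_cycles``-fold power is ``P_interval``.

    Takes the principal matrix logarithm, divides by the number of cycles,
    and regularises any negative off-diagonal intensities by zeroing them
    and absorbing the deficit into the diagonal before re-exponentiating
    — the standard generator-regularisation approach for embedding an
    observed interval matrix as repeated short-cycle transitions
    ("transitions occur uniformly within the interval").

    Returns the per-cycle matrix and the reconstruction error
    ``max |P_cycle**k - P_interval|``.
    """
    P = np.asarray(P_interval, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("interval matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("interval matrix must be row-stochastic")
    if interval_cycles < 1:
        raise ValueError("interval_cycles must be >= 1")

    L = logm(P)
    if np.max(np.abs(L.imag)) > 1e-8:
        # routine for sampled interval matrices that are not embeddable
        logger.debug(
            "matrix logarithm has imaginary magnitude %.2e; using real part",
            np.max(np.abs(L.imag)),
        )
    G = L.real / interval_cycles

    off_mask = ~np.eye(G.shape[0], dtype=bool)
    if np.any(G[off_mask] < 0):
        G = G.copy()
        neg = G < 0
        neg[np.diag_indices_from(G)] = False
        G[neg] = 0.0
        np.fill_diagonal(G, 0.0)
        np.fill_diagonal(G, -G.sum(axis=1))

    P_cycle = expm(G)
    # expm of a valid generator is stochastic up to roundoff; tidy it
    P_cycle = np.clip(P_cycle, 0.0, None)
    P_cycle /= P_cycle.sum(axis=1, keepdims=True)
    err = float(np.max(np.abs(np.linalg.matrix_power(P_cycle, interval_cycles) - P)))
    return P_cycle, err


def count_interval_transitions(
    panel: pd.DataFrame,
    interval_weeks: float,
    tolerance_weeks: float = 2.0,
    n_states: int = N_ALIVE,
) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate state-to-state moves across a fixed assessment interval.

    Consecutive visit pairs whose gap is within ``tolerance_weeks`` of
    ``interval_weeks`` contribute one count; subjects with no qualifying
    pair are excluded (logged). Returns ``(counts, matrix)`` where rows of
    ``counts`` normalise to the interval transition ``matrix``; the raw
    counts are retained as Dirichlet effective counts for probabilistic
    analysis. Rows with no observations stay put (identity row).
    """
    df = panel_with_states(panel)
    counts = np.zeros((n_states, n_states))
    excluded = []
    for sid, g in df.groupby("subject_id", sort=False):
        s = g["state"].to_numpy()
        t = g["visit_week"].to_numpy(dtype=float)
        used = 0
        for i in range(len(s) - 1):
            if abs((t[i + 1] - t[i]) - interval_weeks) <= tolerance_weeks:
                counts[s[i], s[i + 1]] += 1.0
                used += 1
        if used == 0:
            excluded.append(sid)
    if excluded:
        logger.info(
            "%d subject(s) had no %.0f-week visit pair and were excluded: %s",
            len(excluded), interval_weeks, excluded[:10],
        )
    matrix = np.eye(n_states)
    row_tot = counts.sum(axis=1)
    nz = row_tot > 0
    matrix[nz] = counts[nz] / row_tot[nz, None]
    return counts, matrix


@dataclass(frozen=True)
class MaintenanceModel:
    """Weibull retained-effect curve for TMS benefit beyond 26 weeks.

    ``weight(t) = exp(-(((t - 26)/scale))**shape)`` for t >= 26 weeks and
    1 before; ``degenerate`` flags an all-ones fit (best-case maintenance).
    """

    shape: float
    scale_weeks: float
    degenerate: bool = False
    anchor_weeks: float = _MAINT_ANCHOR_WEEKS

    def __post_init__(self) -> None:
        if not self.degenerate and (self.shape <= 0 or self.scale_weeks <= 0):
            raise ValueError("Weibull shape and scale must be positive")

    def weight(self, t_weeks) -> np.ndarray | float:
        t = np.asarray(t_weeks, dtype=float)
        if self.degenerate:
            w = np.ones_like(t)
        else:
            dt = np.clip(t - self.anchor_weeks, 0.0, None)
            w = np.exp(-((dt / self.scale_weeks) ** self.shape))
        return w if w.ndim else float(w)

    @classmethod
    def constant_one(cls) -> "MaintenanceModel":
        """Best-case maintenance: full effect retained over the horizon."""
        return cls(shape=1.0, scale_weeks=1.0, degenerate=True)


def fit_weibull_maintenance(
    points: list[tuple[float, float]],
    shape: float | None = None,
) -> MaintenanceModel:
    """Fit the retained-effect Weibull to pooled (weeks, fraction) points.

    Least-squares fit of ``w(t) = exp(-(((t-26)/scale))**shape)``, anchored
    to 1 at 26 weeks. With ``shape`` given and a single point, the scale is
    solved in closed form. If every fraction equals 1 the fit is degenerate
    and a constant-one curve is returned (flagged).
    """
    pts = [(float(t), float(f)) for t, f in points]
    if any(not (0.0 <= f <= 1.0) for _, f in pts):
        raise ValueError("retained fractions must lie in [0, 1]")
    if any(t < _MAINT_ANCHOR_WEEKS for t, _ in pts):
        raise ValueError("maintenance points must lie at or beyond 26 weeks")
    if all(f == 1.0 for _, f in pts):
        logger.warning("all retained fractions are 1; returning constant-one curve")
        return MaintenanceModel.constant_one()
    if len(pts) < 1 or (shape is None and len(pts) < 2):
        raise ValueError("need >=2 points (or a fixed shape with >=1 point)")

    t = np.array([p[0] for p in pts]) - _MAINT_ANCHOR_WEEKS
    f = np.clip(np.array([p[1] for p in pts]), 1e-9, 1.0 - 1e-12)

    if shape is not None and len(pts) == 1:
        lam = float(t[0] / (-np.log(f[0])) ** (1.0 / shape))
        return MaintenanceModel(shape=float(shape), scale_weeks=lam)

    # log(-log f) = shape * (log dt - log scale): linear start values
    y = np.log(-np.log(f))
    x = np.log(np.clip(t, 1e-9, None))
    if shape is None:
        k0, c0 = np.polyfit(x, y, 1) if len(pts) > 1 else (1.0, 0.0)
        k0 = max(k0, 0.05)
        lam0 = float(np.exp(np.mean(x) - np.mean(y) / k0))

        def resid(p):
            k, lam = np.exp(p)
            return np.exp(-((t / lam) ** k)) - f

        sol = least_squares(resid, np.log([k0, max(lam0, 1e-3)]))
        k, lam = np.exp(sol.x)
        return MaintenanceModel(shape=float(k), scale_weeks=float(lam))

    def resid_lam(p):
        return np.exp(-((t / np.exp(p[0])) ** shape)) - f

    sol = least_squares(resid_lam, [np.log(np.mean(t))])
    return MaintenanceModel(shape=float(shape), scale_weeks=float(np.exp(sol.x[0])))


def blend_to_tau(
    tms_alive_26wk: np.ndarray,
    tau_alive: np.ndarray,
    maintenance: MaintenanceModel,
    cycle: int,
    settings: ModelSettings | None = None,
) -> np.ndarray:
    """Blend the TMS 26-week alive composition toward TAU's.

    Beyond 26 weeks (cycle >= 13 at 2-week cycles) no further improvement
    over TAU is assumed; the arm's alive composition is the convex mixture
    ``w(t) * tms + (1 - w(t)) * tau`` with the retained-effect weight
    evaluated at the cycle's time in weeks, renormalised to sum to 1.
    Mortality is handled separately by the engine.
    """
    settings = settings or ModelSettings()
    blend_start = int(round(_MAINT_ANCHOR_WEEKS / settings.cycle_length_weeks))
    if cycle < blend_start:
        raise ValueError(f"blending applies from cycle {blend_start} onward")
    tms = np.asarray(tms_alive_26wk, dtype=float)
    tau = np.asarray(tau_alive, dtype=float)
    for v, name in ((tms, "tms"), (tau, "tau")):
        if v.shape != (N_ALIVE,) or not np.isclose(v.sum(), 1.0, atol=1e-8):
            raise ValueError(f"{name} composition must be a 4-vector summing to 1")
    w = float(maintenance.weight(cycle * settings.cycle_length_weeks))
    out = w * tms + (1.0 - w) * tau
    return out / out.sum()
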