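"""Structured expert elicitation: quantile judgments and linear pooling.

Experts express uncertain quantities as variable-interval quantile
judgments (e.g. 25th/50th/75th percentiles) within stated plausible
bounds. Each expert's judgment is reconstructed as a monotone
piecewise-linear CDF through ``(low, 0)``, the quantile pairs, and
``(high, 1)`` — the least-assumption reconstruction, with no parametric
family forced on the expert. Experts are then combined by an
equal-weight linear opinion pool (a mixture of the expert CDFs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpertJudgement",
    "PiecewiseLinearCDF",
    "PooledDistribution",
    "fit_expert_cdf",
    "linear_pool",
    "between_expert_spread",
    "judgements_from_frame",
]


@dataclass(frozen=True)
class ExpertJudgement:
    """One expert's quantile judgments for one quantity."""

    expert_id: str
    quantity_name: str
    quantile_pairs: tuple[tuple[float, float], ...]  # (p, value)
    plausible_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.plausible_bounds
        if not lo < hi:
            raise ValueError("plausible bounds must satisfy low < high")
        pairs = tuple(sorted((float(p), float(v)) for p, v in self.quantile_pairs))
        ps = [p for p, _ in pairs]
        vs = [v for _, v in pairs]
        if any(not (0.0 < p < 1.0) for p in ps):
            raise ValueError("quantile probabilities must lie strictly in (0, 1)")
        if any(b > a for a, b in zip(vs[1:], vs[:-1])):
            raise ValueError(
                f"expert {self.expert_id}: quantile values must be "
                "non-decreasing in probability"
            )
        if vs and (vs[0] < lo or vs[-1] > hi):
            raise ValueError(
                f"expert {self.expert_id}: quantile values outside plausible bounds"
            )
        object.__setattr__(self, "quantile_pairs", pairs)


@dataclass(frozen=True)
class PiecewiseLinearCDF:
    """Monotone piecewise-linear CDF defined by node points."""

    xs: np.ndarray
    ps: np.ndarray

    def __post_init__(self) -> None:
        xs = np.asarray(self.xs, dtype=float)
        ps = np.asarray(self.ps, dtype=float)
        if xs.shape != ps.shape or xs.ndim != 1 or len(xs) < 2:
            raise ValueError("need matching 1-d node arrays with >=2 nodes")
        if np.any(np.diff(xs) < 0) or np.any(np.diff(ps) < 0):
            raise ValueError("CDF nodes must be non-decreasing")
        if not (np.isclose(ps[0], 0.0) and np.isclose(ps[-1], 1.0)):
            raise ValueError("CDF must run from 0 to 1")
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ps", ps)

    def cdf(self, x) -> np.ndarray | float:
        out = np.interp(np.asarray(x, dtype=float), self.xs, self.ps)
        return out if out.ndim else float(out)

    def ppf(self, u) -> np.ndarray | float:
        out = np.interp(np.asarray(u, dtype=float), self.ps, self.xs)
        return out if out.ndim else float(out)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.asarray(self.ppf(rng.random(n)))

    @property
    def median(self) -> float:
        return float(self.ppf(0.5))

    def _segment_moments(self) -> tuple[float, float]:
        """Exact mean and variance (uniform density within each segment)."""
        dx = np.diff(self.xs)
        dp = np.diff(self.ps)
        mids = 0.5 * (self.xs[:-1] + self.xs[1:])
        mean = float((dp * mids).sum())
        # E[X^2] per uniform segment: (a^2 + ab + b^2)/3
        a, b = self.xs[:-1], self.xs[1:]
        ex2 = float((dp * (a * a + a * b + b * b) / 3.0).sum())
        return mean, ex2 - mean * mean

    @property
    def mean(self) -> float:
        return self._segment_moments()[0]

    @property
    def variance(self) -> float:
        return self._segment_moments()[1]


def fit_expert_cdf(judgement: ExpertJudgement) -> PiecewiseLinearCDF:
    """Piecewise-linear CDF through the bounds and quantile nodes."""
    lo, hi = judgement.plausible_bounds
    xs = [lo] + [v for _, v in judgement.quantile_pairs] + [hi]
    ps = [0.0] + [p for p, _ in judgement.quantile_pairs] + [1.0]
    # degenerate repeats (value at a bound) are legal: vertical CDF jump
    return PiecewiseLinearCDF(np.array(xs), np.array(ps))


@dataclass(frozen=True)
class PooledDistribution:
    """Equal- or stated-weight linear opinion pool of expert CDFs."""

    components: tuple[PiecewiseLinearCDF, ...]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("linear pool needs at least one expert")
        w = self.weights
        if w is None:
            w = np.full(len(self.components), 1.0 / len(self.components))
        w = np.asarray(w, dtype=float)
        if len(w) != len(self.components) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must match components and sum to 1")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    def cdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = sum(w * np.asarray(c.cdf(x)) for w, c in zip(self.weights, self.components))
        return out if np.ndim(out) else float(out)

    def ppf(self, u) -> np.ndarray | float:
        """Numeric inverse of the pooled CDF (bisection on the mixture)."""
        u_arr = np.atleast_1d(np.asarray(u, dtype=float))
        lo = min(c.xs[0] for c in self.components)
        hi = max(c.xs[-1] for c in self.components)
        a = np.full_like(u_arr, lo)
        b = np.full_like(u_arr, hi)
        for _ in range(80):
            m = 0.5 * (a + b)
            below = np.asarray(self.cdf(m)) < u_arr
            a = np.where(below, m, a)
            b = np.where(below, b, m)
        out = 0.5 * (a + b)
        return out if np.ndim(u) else float(out[0])

    @property
    def median(self) -> float:
        return float(self.ppf(0.5))

    @property
    def mean(self) -> float:
        return float(sum(w * c.mean for w, c in zip(self.weights, self.components)))

    @property
    def variance(self) -> float:
        """Mixture variance: E[var] + var of component means."""
        means = np.array([c.mean for c in self.components])
        varis = np.array([c.variance for c in self.components])
        m = float(self.weights @ means)
        return float(self.weights @ (varis + (means - m) ** 2))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw an expert by weight, then invert that expert's CDF."""
        idx = rng.choice(len(self.components), size=n, p=self.weights)
        u = rng.random(n)
        out = np.empty(n)
        for i, c in enumerate(self.components):
            sel = idx == i
            if sel.any():
                out[sel] = np.asarray(c.ppf(u[sel]))
        return out


def linear_pool(
    judgements: list[ExpertJudgement] | list[PiecewiseLinearCDF],
    weights=None,
) -> PooledDistribution:
    """Equal-weight (or stated-weight) linear opinion pool."""
    if not judgements:
        raise ValueError("linear pool needs at least one expert")
    cdfs = tuple(
        j if isinstance(j, PiecewiseLinearCDF) else fit_expert_cdf(j)
        for j in judgements
    )
    return PooledDistribution(cdfs, weights)


def between_expert_spread(judgements: list[ExpertJudgement]) -> dict:
    """Summaries of between-expert variation for one quantity.

    Reports each expert's median, the range of medians, the identity of
    the most optimistic (highest-median) and most pessimistic expert, and
    the decomposition of the pooled variance into within- and
    between-expert components. The extreme-median experts are the inputs
    to the optimistic/pessimistic scenario analyses.
    """
    if len(judgements) < 2:
        raise ValueError("spread summary needs >=2 experts")
    cdfs = {j.expert_id: fit_expert_cdf(j) for j in judgements}
    medians = {eid: c.median for eid, c in cdfs.items()}
    pool = linear_pool(list(judgements))
    means = np.array([c.mean for c in cdfs.values()])
    varis = np.array([c.variance for c in cdfs.values()])
    w = pool.weights
    within = float(w @ varis)
    between = float(w @ (means - w @ means) ** 2)
    opt = max(medians, key=medians.get)
    pess = min(medians, key=medians.get)
    return {
        "medians": medians,
        "median_range": (min(medians.values()), max(medians.values())),
        "most_optimistic": opt,
        "most_pessimistic": pess,
        "pooled_variance": pool.variance,
        "within_expert_variance": within,
        "between_expert_variance": between,
    }


def judgements_from_frame(
    frame: pd.DataFrame, bounds: dict[str, tuple[float, float]]
) -> dict[str, list[ExpertJudgement]]:
    """Build judgments from a long table (expert_id, quantity, p, value).

    ``bounds`` maps quantity name to its plausible (low, high) range.
    Returns judgments grouped by quantity.
    """
    out: dict[str, list[ExpertJudgement]] = {}
    for (quantity, expert), g in frame.groupby(["quantity", "expert_id"]):
        j = ExpertJudgement(
            expert_id=str(expert),
            quantity_name=str(quantity),
            quantile_pairs=tuple(zip(g["p"], g["value"])),
            plausible_bounds=bounds[str(quantity)],
        )
        out.setdefault(str(quantity), []).append(j)
    return out
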