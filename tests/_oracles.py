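"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the
microsimulation propagates individuals one cycle at a time by direct
categorical sampling, and the frontier oracle maximises net monetary
benefit by brute force over a dense willingness-to-pay grid.
"""

import numpy as np


def microsimulate(initial, matrices, n_paths, rng):
    """Individual-level simulation of a cohort through a matrix schedule.

    Returns the occupancy proportions (n_cycles+1, n_states) plus the
    binomial Monte-Carlo standard error of each proportion.
    """
    initial = np.asarray(initial, dtype=float)
    matrices = np.asarray(matrices, dtype=float)
    n_states = len(initial)
    cum_init = np.cumsum(initial)
    state = np.searchsorted(cum_init, rng.random(n_paths), side="right")
    occ = np.zeros((len(matrices) + 1, n_states))
    occ[0] = np.bincount(state, minlength=n_states) / n_paths
    for c, P in enumerate(matrices):
        cum = np.cumsum(P, axis=1)
        u = rng.random(n_paths)
        state = (u[:, None] > cum[state]).sum(axis=1)
        occ[c + 1] = np.bincount(state, minlength=n_states) / n_paths
    se = np.sqrt(np.clip(occ * (1 - occ), 0, None) / n_paths)
    return occ, se


def nmb_frontier(means, lam_grid):
    """Arms that maximise net monetary benefit for some λ on the grid."""
    winners = set()
    arms = list(means)
    for lam in lam_grid:
        nmb = {a: lam * q - c for a, (c, q) in means.items()}
        winners.add(max(arms, key=lambda a: nmb[a]))
    return winners


def random_schedule(rng, n_cycles, p_death_scale=0.05):
    """Random absorbing-death 5-state schedule (varying per cycle)."""
    mats = np.zeros((n_cycles, 5, 5))
    for c in range(n_cycles):
        alive = rng.dirichlet(np.ones(4), size=4)
        p_death = p_death_scale * rng.random()
        mats[c, :4, :4] = (1 - p_death) * alive
        mats[c, :4, 4] = p_death
        mats[c, 4, 4] = 1.0
    return mats
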