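"""Health states of the depression cost-utility model.

The model tracks a cohort of adults with treatment-resistant depression
through four severity states anchored to 17-item Hamilton Depression
Rating Scale (HDRS-17) bands — Remission (0–7), Mild (8–13),
Moderate (14–22), Severe (23+) — plus an absorbing Dead state reachable
from every alive state.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class HealthState(IntEnum):
    """Model health states, ordered by severity; ``DEAD`` is absorbing."""

    REMISSION = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    DEAD = 4


#: The four alive states, in severity order.
ALIVE_STATES: tuple[HealthState, ...] = (
    HealthState.REMISSION,
    HealthState.MILD,
    HealthState.MODERATE,
    HealthState.SEVERE,
)

N_STATES = 5
N_ALIVE = 4

#: Inclusive HDRS-17 band upper bounds for the alive states.
_HDRS_UPPER = np.array([7, 13, 22, 52])

HDRS_MIN, HDRS_MAX = 0, 52


def classify_hdrs(score: int) -> HealthState:
    """Map an HDRS-17 total score onto a severity state.

    Bands: 0–7 Remission, 8–13 Mild, 14–22 Moderate, 23–52 Severe.

    Raises
    ------
    ValueError
        If ``score`` lies outside the HDRS-17 range 0–52.
    """
    if not (HDRS_MIN <= score <= HDRS_MAX):
        raise ValueError(f"HDRS-17 score {score!r} outside the 0-52 range")
    return HealthState(int(np.searchsorted(_HDRS_UPPER, score)))


def classify_hdrs_array(scores) -> np.ndarray:
    """Vectorised :func:`classify_hdrs`; returns integer state codes."""
    scores = np.asarray(scores)
    if np.any((scores < HDRS_MIN) | (scores > HDRS_MAX)):
        bad = scores[(scores < HDRS_MIN) | (scores > HDRS_MAX)]
        raise ValueError(f"HDRS-17 scores outside 0-52: {np.unique(bad)}")
    return np.searchsorted(_HDRS_UPPER, scores)
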