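"""Disease-state coding for the fibrosis progression model.

Seven ordered compartments: histological fibrosis stages F0--F3, compensated
cirrhosis (CC), decompensated cirrhosis (DC), and death.  Death is absorbing.
"""

from __future__ import annotations

from enum import IntEnum


class DiseaseState(IntEnum):
    """Ordered disease compartments; the integer code is the compartment index."""

    F0 = 0
    F1 = 1
    F2 = 2
    F3 = 3
    CC = 4
    DC = 5
    DEATH = 6


N_STATES = 7

#: indices of the six alive compartments (everything except DEATH)
ALIVE_STATES = tuple(range(6))

#: slice selecting the alive block of a state vector / matrix axis
ALIVE = slice(0, 6)


def stage_index(state: int | DiseaseState) -> int:
    """Stage index ``x`` entering the death hazard: 0..5 for F0..DC.

    CC and DC continue the compartment ordering (x = 4 and 5); the death
    compartment has no stage index.
    """
    s = int(state)
    if not 0 <= s <= 5:
        raise ValueError(f"no stage index for state {state!r}; expected F0..DC")
    return s


def fibrosis_score(state: int | DiseaseState, convention: str = "cap4") -> int:
    """Numeric fibrosis score used in progression-rate summaries.

    ``cap4`` maps both cirrhosis compartments to stage 4 (the convention of
    paired-biopsy meta-analyses); ``dc_distinct`` keeps DC at 5.
    """
    s = int(state)
    if s == DiseaseState.DEATH:
        raise ValueError("death carries no fibrosis score")
    if s <= 3:
        return s
    if convention == "cap4":
        return 4
    if convention == "dc_distinct":
        return 4 if s == DiseaseState.CC else 5
    raise ValueError(f"unknown convention {convention!r}")
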