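"""Helpers for building PK profiles whose trapezoidal AUCs are prescribed."""

import numpy as np

import permkin as pk

SCHEDULE = np.array([0.5, 1.0, 1.5, 2.0, 4.0, 6.0])
SPAN = SCHEDULE[-1] - SCHEDULE[0]


def constant_profile(auc: float, matrix: str, route: str) -> pk.PKProfile:
    """Flat profile over the in vivo schedule with an exact trapezoidal AUC."""
    return pk.PKProfile(matrix=matrix, route=route, times=SCHEDULE,
                        concentrations=np.full(SCHEDULE.size, auc / SPAN))


def study_profiles(Bin: float, Pin: float, Biv: float, Piv: float) -> list[pk.PKProfile]:
    """The four study profiles with prescribed AUCs (brain/blood x in/iv)."""
    return [
        constant_profile(Pin, "blood", "intranasal"),
        constant_profile(Bin, "brain", "intranasal"),
        constant_profile(Biv, "brain", "intravenous"),
        constant_profile(Piv, "blood", "intravenous"),
    ]
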