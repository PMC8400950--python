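"""Non-compartmental PK reduction and nose-to-brain targeting metrics.

Given blood and brain concentration-time profiles after intranasal and
intravenous dosing, exposure is summarized by the linear-trapezoidal AUC and
brain targeting is quantified by three standard ratios.  Writing ``Bin/Pin``
for the brain/blood AUCs after intranasal dosing and ``Biv/Piv`` after IV
dosing:

    DTE%  = [(Bin/Pin) / (Biv/Piv)] * 100
    Bx    = (Biv/Piv) * Pin        (brain AUC explained by systemic exposure)
    DTP%  = (Bin - Bx) / Bin * 100
    F%    = AUC_intranasal / AUC_intravenous * 100   (nasal bioavailability,
                                                      per matrix)

DTE% > 100 means the intranasal route enriches brain exposure relative to
blood beyond what IV dosing achieves; DTP% is the fraction of intranasal
brain exposure not attributable to recirculation from blood.  The three
statements DTE > 100, Bin/Pin > Biv/Piv and DTP > 0 are equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .diffusion import InputError, _require

__all__ = [
    "MATRICES",
    "ROUTES",
    "PKProfile",
    "NCAResult",
    "TargetingMetrics",
    "auc_trapezoid",
    "cmax_tmax",
    "drug_targeting_efficiency",
    "direct_transport_percentage",
    "nasal_bioavailability",
    "targeting_report",
]

MATRICES = ("blood", "brain")
ROUTES = ("intranasal", "intravenous")

_ROUTE_ALIASES = {
    "in": "intranasal", "intranasal": "intranasal",
    "iv": "intravenous", "intravenous": "intravenous",
}


def normalize_route(route: str) -> str:
    try:
        return _ROUTE_ALIASES[route.lower()]
    except KeyError:
        raise InputError(f"unknown route {route!r}; expected one of {sorted(_ROUTE_ALIASES)}")


@dataclass(frozen=True)
class PKProfile:
    """Concentration-time points for one matrix (blood|brain) and route.

    Concentrations are ng/mL for blood and ng/g for brain homogenate; times
    are hours.
    """

    matrix: str
    route: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        _require(self.matrix in MATRICES,
                 f"matrix must be one of {MATRICES}, got {self.matrix!r}")
        object.__setattr__(self, "route", normalize_route(self.route))
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        _require(t.ndim == 1 and c.ndim == 1 and t.size == c.size,
                 "times and concentrations must be 1-D arrays of equal length")
        _require(t.size >= 2, "profile needs at least 2 points")
        _require(bool(np.all(np.isfinite(t))) and bool(np.all(np.isfinite(c))),
                 "times and concentrations must be finite")
        _require(bool(np.all(t >= 0)), "times must be non-negative")
        _require(bool(np.all(np.diff(t) > 0)), "times must be strictly increasing")
        _require(bool(np.all(c >= 0)), "concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class NCAResult:
    """Cmax, its (earliest) time, and AUC from the first sample to t_end."""

    auc_0_t: float
    c_max: float
    t_max: float


class Bioavailability(NamedTuple):
    value_pct: float
    matrix: str


@dataclass(frozen=True)
class TargetingMetrics:
    """Per-group AUCs and the brain-targeting ratios derived from them."""

    Bin: float
    Pin: float
    Biv: float
    Piv: float
    Bx: float
    dte_pct: float
    dtp_pct: float
    nasal_bioavailability_pct: float
    bioavailability_matrix: str
    nca: dict[tuple[str, str], NCAResult] | None = None


def auc_trapezoid(profile: PKProfile, t_end: float | None = None) -> float:
    """Linear-trapezoidal AUC from the first sample to ``t_end``.

    No extrapolation: ``t_end`` must lie within the sampled range (defaults
    to the last sample); a ``t_end`` between samples is handled by linear
    interpolation at the cut point.
    """
    t, c = profile.times, profile.concentrations
    if t_end is None:
        t_end = float(t[-1])
    if not np.isfinite(t_end) or t_end > t[-1] + 1e-12 or t_end < t[0]:
        raise InputError(
            f"t_end={t_end} outside the sampled range [{t[0]}, {t[-1]}]; "
            "extrapolation is not performed"
        )
    t_end = min(t_end, float(t[-1]))
    keep = t <= t_end + 1e-12
    tt, cc = t[keep], c[keep]
    if tt[-1] < t_end:
        tt = np.append(tt, t_end)
        cc = np.append(cc, np.interp(t_end, t, c))
    return float(np.trapezoid(cc, tt))


def cmax_tmax(profile: PKProfile) -> tuple[float, float]:
    """Peak concentration and the earliest time attaining it."""
    i = int(np.argmax(profile.concentrations))  # argmax returns first maximum
    return float(profile.concentrations[i]), float(profile.times[i])


def _require_positive_aucs(**aucs: float) -> None:
    for name, v in aucs.items():
        if not (np.isfinite(v) and v > 0):
            raise InputError(f"AUC {name} must be > 0, got {v}")


def drug_targeting_efficiency(Bin: float, Pin: float, Biv: float, Piv: float) -> float:
    """DTE% = [(Bin/Pin) / (Biv/Piv)] * 100."""
    _require_positive_aucs(Bin=Bin, Pin=Pin, Biv=Biv, Piv=Piv)
    return (Bin / Pin) / (Biv / Piv) * 100.0


def direct_transport_percentage(
    Bin: float, Pin: float, Biv: float, Piv: float
) -> tuple[float, float]:
    """DTP% and Bx, with Bx = (Biv/Piv) * Pin.

    Bx is the part of the intranasal brain AUC delivered through systemic
    circulation; DTP% = (Bin - Bx)/Bin * 100 is the directly transported
    remainder (negative when systemic exposure over-explains the brain AUC).
    """
    _require(np.isfinite(Bin) and Bin > 0, f"Bin must be > 0, got {Bin}")
    _require(np.isfinite(Piv) and Piv > 0, f"Piv must be > 0, got {Piv}")
    _require(np.isfinite(Pin) and Pin >= 0, f"Pin must be >= 0, got {Pin}")
    _require(np.isfinite(Biv) and Biv >= 0, f"Biv must be >= 0, got {Biv}")
    Bx = (Biv / Piv) * Pin
    dtp = (Bin - Bx) / Bin * 100.0
    return dtp, Bx


def nasal_bioavailability(
    auc_intranasal: float, auc_intravenous: float, matrix: str = "brain"
) -> Bioavailability:
    """Nasal bioavailability% = AUC_in / AUC_iv * 100, labeled by matrix."""
    _require(matrix in MATRICES, f"matrix must be one of {MATRICES}, got {matrix!r}")
    _require(np.isfinite(auc_intravenous) and auc_intravenous > 0,
             f"intravenous AUC must be > 0, got {auc_intravenous}")
    _require(np.isfinite(auc_intranasal) and auc_intranasal >= 0,
             f"intranasal AUC must be >= 0, got {auc_intranasal}")
    return Bioavailability(auc_intranasal / auc_intravenous * 100.0, matrix)


def targeting_report(
    profiles: Iterable[PKProfile],
    t_end: float | None = None,
    bioavailability_matrix: str = "brain",
) -> TargetingMetrics:
    """Compute the four AUCs and all targeting metrics from a full study.

    ``profiles`` must cover every (matrix, route) combination in
    {blood, brain} x {intranasal, intravenous}; duplicates are rejected.
    ``t_end`` defaults to the latest time common to all four profiles.
    """
    table: dict[tuple[str, str], PKProfile] = {}
    for p in profiles:
        key = (p.matrix, p.route)
        if key in table:
            raise InputError(f"duplicate profile for {key}")
        table[key] = p
    missing = [k for m in MATRICES for r in ROUTES if (k := (m, r)) not in table]
    if missing:
        raise InputError(f"missing profiles for combinations: {missing}")

    if t_end is None:
        t_end = min(float(p.times[-1]) for p in table.values())

    auc = {k: auc_trapezoid(p, t_end) for k, p in table.items()}
    nca = {
        k: NCAResult(auc_0_t=auc[k], c_max=cmax_tmax(p)[0], t_max=cmax_tmax(p)[1])
        for k, p in table.items()
    }

    Bin = auc[("brain", "intranasal")]
    Pin = auc[("blood", "intranasal")]
    Biv = auc[("brain", "intravenous")]
    Piv = auc[("blood", "intravenous")]

    dte = drug_targeting_efficiency(Bin, Pin, Biv, Piv)
    dtp, Bx = direct_transport_percentage(Bin, Pin, Biv, Piv)
    f_in = {"brain": (Bin, Biv), "blood": (Pin, Piv)}[bioavailability_matrix]
    bio = nasal_bioavailability(f_in[0], f_in[1], bioavailability_matrix)

    return TargetingMetrics(
        Bin=Bin, Pin=Pin, Biv=Biv, Piv=Piv, Bx=Bx,
        dte_pct=dte, dtp_pct=dtp,
        nasal_bioavailability_pct=bio.value_pct,
        bioavailability_matrix=bio.matrix,
        nca=nca,
    )
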