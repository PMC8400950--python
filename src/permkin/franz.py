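"""Franz-diffusion-cell bookkeeping: sample reduction and mass balance.

A vertical Franz cell holds the membrane between a donor chamber and a
stirred receptor chamber of volume ``V_r``.  At each sampling time an aliquot
of volume ``V_s`` is withdrawn from the receptor and replaced with fresh
medium, so every withdrawal dilutes the receptor.  With instantaneous mixing
and constant receptor volume, the cumulative amount that has permeated by
sample ``n`` is recovered from the measured concentrations ``C_i`` by the
standard replacement ledger

    A_n = V_r * C_n + V_s * sum_{i < n} C_i        (micrograms)

i.e. what is in the chamber now plus everything carried out by earlier
aliquots.  Division by the membrane area gives the per-area series the
diffusion model works with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion import InputError, PermeationSeries, _require

__all__ = [
    "CellGeometry",
    "SamplingRecord",
    "MassBalance",
    "cumulative_from_samples",
    "mass_balance",
]


@dataclass(frozen=True)
class CellGeometry:
    """Receptor volume (mL), aliquot volume (mL) and membrane area (cm**2).

    Defaults follow the reference cell: 12.5 mL receptor, 250 uL aliquots,
    3.14 cm**2 exposed mucosa.
    """

    receptor_volume: float = 12.5
    sample_volume: float = 0.25
    area_S: float = 3.14

    def __post_init__(self) -> None:
        _require(0 < self.sample_volume < self.receptor_volume,
                 f"need 0 < sample_volume < receptor_volume, got "
                 f"{self.sample_volume} / {self.receptor_volume}")
        _require(self.area_S > 0, f"area_S must be > 0, got {self.area_S}")


@dataclass(frozen=True)
class SamplingRecord:
    """Receptor concentrations (ug/mL) measured at each withdrawal time (h)."""

    times: np.ndarray
    measured_conc: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.measured_conc, dtype=float)
        _require(t.ndim == 1 and c.ndim == 1 and t.size == c.size,
                 "times and measured_conc must be 1-D arrays of equal length")
        _require(t.size > 0, "record must contain at least one sample")
        _require(bool(np.all(np.isfinite(t))) and bool(np.all(np.isfinite(c))),
                 "times and measured_conc must be finite")
        _require(bool(np.all(np.diff(t) > 0)), "times must be strictly increasing")
        _require(bool(np.all(c >= 0)), "measured concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "measured_conc", c)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class MassBalance:
    """Where the loaded dose ended up after the experiment (all in ug)."""

    dose_loaded: float
    permeated_total: float
    recovered_donor: float
    unaccounted: float
    permeated_pct: float
    recovered_pct: float
    warn_inconsistent: bool = False


def cumulative_from_samples(record: SamplingRecord, geometry: CellGeometry) -> PermeationSeries:
    """Replacement-corrected cumulative permeation per unit area (ug/cm**2).

    Applies ``A_n = V_r*C_n + V_s*sum_{i<n} C_i`` then divides by the
    membrane area.  Raises :class:`InputError` on negative concentrations
    (enforced by :class:`SamplingRecord`).
    """
    c = record.measured_conc
    withdrawn_before = geometry.sample_volume * np.concatenate([[0.0], np.cumsum(c)[:-1]])
    amount = geometry.receptor_volume * c + withdrawn_before
    return PermeationSeries(times=record.times, cumulative_Q=amount / geometry.area_S)


def mass_balance(
    series: PermeationSeries,
    geometry: CellGeometry,
    dose_loaded: float,
    recovered_donor: float,
) -> MassBalance:
    """Account the loaded dose into permeated, donor-recovered and unaccounted.

    ``permeated_total`` is the final cumulative per-area value times the
    membrane area.  ``unaccounted`` closes the balance by construction and
    may come out negative when the inputs are inconsistent; a deficit worse
    than 5% of the dose sets ``warn_inconsistent`` rather than being hidden.
    """
    _require(dose_loaded > 0, f"dose_loaded must be > 0, got {dose_loaded}")
    _require(recovered_donor >= 0, f"recovered_donor must be >= 0, got {recovered_donor}")

    permeated = float(series.cumulative_Q[-1] * geometry.area_S)
    unaccounted = dose_loaded - permeated - recovered_donor
    return MassBalance(
        dose_loaded=dose_loaded,
        permeated_total=permeated,
        recovered_donor=recovered_donor,
        unaccounted=unaccounted,
        permeated_pct=100.0 * permeated / dose_loaded,
        recovered_pct=100.0 * recovered_donor / dose_loaded,
        warn_inconsistent=unaccounted < -0.05 * dose_loaded,
    )
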