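"""Synthetic Franz-cell records and PK profiles with known ground truth.

Every analysis stage in this package can be exercised end to end without
wet-lab data: the permeation simulator runs the membrane diffusion model
forward, converts the true cumulative curve into the receptor concentrations
an analyst would actually measure (undoing the withdrawal-with-replacement
ledger), and corrupts them with multiplicative assay noise; the PK simulator
produces one-compartment Bateman (first-order absorption) profiles for the
intranasal route and mono-exponential decay for the IV bolus, with a
controllable direct nose-to-brain transport component.

Noise is multiplicative Gaussian, ``c * (1 + eps)`` with
``eps ~ N(0, noise_cv)``, truncated at zero — assay error in these data
scales with the measured concentration.  All outputs are reproducible from
the config and seed; changing only the seed changes only the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .diffusion import (
    DiffusionParams,
    DonorSpec,
    InputError,
    MembraneSpec,
    PermeationSeries,
    _require,
    cumulative_amount,
)
from .franz import CellGeometry, SamplingRecord
from .targeting import PKProfile, auc_trapezoid, normalize_route

__all__ = [
    "DEFAULT_PERMEATION_SCHEDULE",
    "DEFAULT_PK_SCHEDULE",
    "PermeationSimConfig",
    "PKSimConfig",
    "simulate_permeation",
    "simulate_pk",
    "simulate_pk_study",
]

# every 30 min for 6 h — the reference Franz-cell sampling protocol
DEFAULT_PERMEATION_SCHEDULE = tuple(np.arange(1, 13) * 0.5)
# sacrifice times of the in vivo study
DEFAULT_PK_SCHEDULE = (0.5, 1.0, 1.5, 2.0, 4.0, 6.0)


def _check_schedule(schedule) -> np.ndarray:
    t = np.asarray(schedule, dtype=float)
    _require(t.ndim == 1 and t.size > 0, "schedule must be a non-empty 1-D sequence")
    _require(bool(np.all(np.isfinite(t))) and bool(np.all(t >= 0)),
             "schedule times must be finite and non-negative")
    _require(bool(np.all(np.diff(t) > 0)), "schedule must be strictly increasing")
    return t


@dataclass(frozen=True)
class PermeationSimConfig:
    """One simulated Franz-cell run.

    Defaults are the reference study conditions: 0.12 cm mucosa of 3.14 cm**2
    in a 12.5 mL receptor sampled with 0.25 mL aliquots every 30 min for 6 h,
    5% assay CV.  The default membrane parameters (D = 0.0024 cm**2/h,
    K = 0.5) put the diffusional lag at exactly 1 h — squarely inside the
    sampling window, as a time-lag experiment requires — and give
    J_ss = 10 ug/(cm**2 h) and P_app = 1e-2 cm/h, the order measured for
    this kind of mucosal barrier.
    """

    params: DiffusionParams = DiffusionParams(D=0.0024, K=0.5)
    membrane: MembraneSpec = MembraneSpec(thickness_L=0.12, area_S=3.14)
    donor: DonorSpec = DonorSpec(concentration_Cd=1000.0)
    geometry: CellGeometry = CellGeometry()
    schedule: tuple[float, ...] = DEFAULT_PERMEATION_SCHEDULE
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.noise_cv >= 0, f"noise_cv must be >= 0, got {self.noise_cv}")
        object.__setattr__(self, "schedule", tuple(_check_schedule(self.schedule)))


@dataclass(frozen=True)
class PKSimConfig:
    """One simulated concentration-time profile (or study, see below).

    ``ka``/``ke`` are first-order absorption and elimination rates (1/h),
    ``scale`` the dose/volume amplitude of the blood profile,
    ``brain_partition`` the systemic brain:blood exposure ratio, and
    ``dtp_target`` the fraction (0 <= f < 1) of the intranasal brain AUC to
    be contributed by direct nose-to-brain transport.
    """

    route: str = "intranasal"
    matrix: str = "blood"
    ka: float = 1.2
    ke: float = 0.4
    scale: float = 300.0
    brain_partition: float = 0.3
    dtp_target: float = 0.0
    schedule: tuple[float, ...] = DEFAULT_PK_SCHEDULE
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", normalize_route(self.route))
        _require(self.matrix in ("blood", "brain"),
                 f"matrix must be blood or brain, got {self.matrix!r}")
        _require(self.ke > 0, f"ke must be > 0, got {self.ke}")
        _require(self.scale > 0, f"scale must be > 0, got {self.scale}")
        _require(self.brain_partition > 0,
                 f"brain_partition must be > 0, got {self.brain_partition}")
        _require(0 <= self.dtp_target < 1,
                 f"dtp_target must be in [0, 1), got {self.dtp_target}")
        _require(self.noise_cv >= 0, f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.route == "intranasal":
            _require(self.ka > 0, f"ka must be > 0, got {self.ka}")
            if self.ka == self.ke:
                raise InputError("ka must differ from ke (Bateman closed form)")
        object.__setattr__(self, "schedule", tuple(_check_schedule(self.schedule)))


def _apply_noise(values: np.ndarray, noise_cv: float, rng: np.random.Generator) -> np.ndarray:
    if noise_cv == 0:
        return values.copy()
    noisy = values * (1.0 + rng.normal(0.0, noise_cv, size=values.shape))
    return np.maximum(noisy, 0.0)


# ---------------------------------------------------------------------------
# Franz-cell simulator
# ---------------------------------------------------------------------------

def simulate_permeation(config: PermeationSimConfig) -> tuple[SamplingRecord, PermeationSeries]:
    """Simulate one Franz-cell run; returns (noisy record, noiseless truth).

    The true cumulative per-area curve comes from the diffusion forward
    model; receptor concentrations are obtained by inverting the replacement
    ledger ``A_n = V_r*C_n + V_s*sum_{i<n} C_i`` step by step, then noise is
    applied to the measured concentrations only.
    """
    t = np.asarray(config.schedule, dtype=float)
    truth_q = cumulative_amount(t, config.params, config.membrane, config.donor)
    truth = PermeationSeries(times=t, cumulative_Q=np.asarray(truth_q, dtype=float))

    geom = config.geometry
    amount = truth.cumulative_Q * geom.area_S  # total ug permeated by each sample
    conc = np.empty_like(amount)
    withdrawn = 0.0
    for i, a in enumerate(amount):
        conc[i] = (a - withdrawn) / geom.receptor_volume
        withdrawn += geom.sample_volume * conc[i]
    conc = np.maximum(conc, 0.0)

    rng = np.random.default_rng(config.seed)
    noisy = _apply_noise(conc, config.noise_cv, rng)
    return SamplingRecord(times=t, measured_conc=noisy), truth


# ---------------------------------------------------------------------------
# PK simulator
# ---------------------------------------------------------------------------

def _bateman(t: np.ndarray, scale: float, ka: float, ke: float) -> np.ndarray:
    return scale * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def _blood_curve(config: PKSimConfig, t: np.ndarray) -> np.ndarray:
    if config.route == "intranasal":
        return _bateman(t, config.scale, config.ka, config.ke)
    return config.scale * np.exp(-config.ke * t)


def _brain_curve(config: PKSimConfig, t: np.ndarray) -> np.ndarray:
    """Systemic brain exposure plus, intranasally, a direct-transport term.

    The direct term reuses a faster Bateman shape (absorption rate 3*ka,
    the quicker olfactory pathway) whose amplitude is solved so that the
    trapezoidal-AUC direct transport percentage on this schedule equals
    ``dtp_target`` exactly at zero noise.
    """
    systemic = config.brain_partition * _blood_curve(config, t)
    if config.route != "intranasal" or config.dtp_target == 0:
        return systemic

    def trap(y: np.ndarray) -> float:
        return float(np.trapezoid(y, t))

    # Bx = (Biv/Piv) * Pin; by construction Biv/Piv = brain_partition
    bx = config.brain_partition * trap(_blood_curve(config, t))
    direct_auc_needed = bx * config.dtp_target / (1.0 - config.dtp_target)
    shape = _bateman(t, 1.0, 3.0 * config.ka, config.ke)
    return systemic + direct_auc_needed / trap(shape) * shape


def simulate_pk(config: PKSimConfig) -> PKProfile:
    """Simulate one blood or brain concentration-time profile."""
    t = np.asarray(config.schedule, dtype=float)
    clean = _blood_curve(config, t) if config.matrix == "blood" else _brain_curve(config, t)
    rng = np.random.default_rng(config.seed)
    noisy = _apply_noise(clean, config.noise_cv, rng)
    return PKProfile(matrix=config.matrix, route=config.route, times=t, concentrations=noisy)


def simulate_pk_study(config: PKSimConfig) -> dict[tuple[str, str], PKProfile]:
    """Simulate the full {blood, brain} x {intranasal, intravenous} study.

    The four profiles share PK parameters; each gets an independent noise
    stream spawned deterministically from ``config.seed``.
    """
    children = np.random.SeedSequence(config.seed).spawn(4)
    out: dict[tuple[str, str], PKProfile] = {}
    for child, (matrix, route) in zip(
        children,
        [(m, r) for m in ("blood", "brain") for r in ("intranasal", "intravenous")],
    ):
        sub = replace(config, matrix=matrix, route=route, seed=0)
        t = np.asarray(sub.schedule, dtype=float)
        clean = _blood_curve(sub, t) if matrix == "blood" else _brain_curve(sub, t)
        rng = np.random.default_rng(child)
        noisy = _apply_noise(clean, sub.noise_cv, rng)
        out[(matrix, route)] = PKProfile(matrix=matrix, route=route, times=t,
                                         concentrations=noisy)
    return out
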