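"""Single-membrane diffusion kinetics: forward model, time-lag analysis, fitting.

The forward model is the classic non-steady-state solution for permeation
through a single homogeneous membrane of thickness ``L`` held between an
infinite, well-stirred donor (concentration ``Cd``, membrane/donor partition
coefficient ``K``) and a perfect-sink receptor::

    Q(t) = Cd * K * L * [ D*t/L**2 - 1/6
           - (2/pi**2) * sum_{n>=1} ((-1)**n / n**2) * exp(-D*n**2*pi**2*t/L**2) ]

``Q(t)`` is the cumulative amount permeated per unit membrane area
(micrograms per cm**2).  At large times the series vanishes and ``Q``
approaches the straight line ``(D*K*Cd/L) * (t - L**2/(6*D))``: its slope is
the steady-state flux ``J_ss = D*K*Cd/L`` and its t-axis intercept is the
diffusional time lag ``t_lag = L**2/(6*D)``.  The derived coefficients are

    P_app = J_ss / Cd          (apparent permeability, cm/h)
    D     = P_app * L / K      (steady-state diffusivity, cm**2/h)

Times are in hours, lengths in cm, concentrations in ug/mL throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "InputError",
    "ConvergenceError",
    "MembraneSpec",
    "DonorSpec",
    "DiffusionParams",
    "PermeationSeries",
    "FluxRegression",
    "DiffusionFit",
    "cumulative_amount",
    "lag_time",
    "steady_state_flux",
    "apparent_permeability",
    "diffusivity_from_papp",
    "fit_diffusion_model",
]

_PI2 = np.pi**2


class InputError(ValueError):
    """Invalid domain input (wrong sign, wrong shape, non-finite value)."""


class ConvergenceError(RuntimeError):
    """Series summation or optimizer failed to converge."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InputError(msg)


@dataclass(frozen=True)
class MembraneSpec:
    """Geometry and partitioning of the diffusion barrier.

    Parameters
    ----------
    thickness_L:
        Diffusion path length in cm (sheep nasal mucosa specimens in the
        reference setup are 0.12 cm thick).
    area_S:
        Effective diffusion surface in cm**2 (3.14 cm**2 in the reference
        Franz cell).
    partition_K:
        Dimensionless membrane/donor partition coefficient.  ``None`` when
        unknown (it is then an output of :func:`fit_diffusion_model`).
    """

    thickness_L: float
    area_S: float = 3.14
    partition_K: float | None = None

    def __post_init__(self) -> None:
        _require(np.isfinite(self.thickness_L) and self.thickness_L > 0,
                 f"thickness_L must be > 0, got {self.thickness_L}")
        _require(np.isfinite(self.area_S) and self.area_S > 0,
                 f"area_S must be > 0, got {self.area_S}")
        if self.partition_K is not None:
            _require(np.isfinite(self.partition_K) and self.partition_K > 0,
                     f"partition_K must be > 0, got {self.partition_K}")


@dataclass(frozen=True)
class DonorSpec:
    """Donor-chamber loading: concentration in ug/mL, optional volume in mL."""

    concentration_Cd: float
    volume: float | None = None

    def __post_init__(self) -> None:
        _require(np.isfinite(self.concentration_Cd) and self.concentration_Cd > 0,
                 f"concentration_Cd must be > 0, got {self.concentration_Cd}")
        if self.volume is not None:
            _require(self.volume > 0, f"volume must be > 0, got {self.volume}")


@dataclass(frozen=True)
class DiffusionParams:
    """Membrane diffusion coefficient D (cm**2/h) and partition coefficient K."""

    D: float
    K: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.D) and self.D > 0, f"D must be > 0, got {self.D}")
        _require(np.isfinite(self.K) and self.K > 0, f"K must be > 0, got {self.K}")


@dataclass(frozen=True)
class PermeationSeries:
    """Cumulative permeated amount per unit area (ug/cm**2) over time (h)."""

    times: np.ndarray
    cumulative_Q: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.cumulative_Q, dtype=float)
        _require(t.ndim == 1 and q.ndim == 1 and t.size == q.size,
                 "times and cumulative_Q must be 1-D arrays of equal length")
        _require(t.size > 0, "series must contain at least one point")
        _require(bool(np.all(np.isfinite(t))) and bool(np.all(np.isfinite(q))),
                 "times and cumulative_Q must be finite")
        _require(bool(np.all(t >= 0)), "times must be non-negative")
        _require(bool(np.all(np.diff(t) > 0)), "times must be strictly increasing")
        _require(bool(np.all(q >= 0)), "cumulative_Q must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative_Q", q)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FluxRegression:
    """Ordinary least-squares line through the late, linear part of Q(t).

    ``J_ss`` is the slope (steady-state flux, ug/(cm**2 h)); ``window`` is the
    half-open index range ``[start, stop)`` used.  ``warn_nonlinear`` is set
    when no candidate window met the linearity threshold and the best
    available one was returned instead.
    """

    J_ss: float
    intercept: float
    window: tuple[int, int]
    r_squared: float
    warn_nonlinear: bool = False


@dataclass(frozen=True)
class DiffusionFit:
    """Full time-lag analysis of one permeation curve."""

    params: DiffusionParams
    J_ss: float
    P_app: float
    D_from_Papp: float
    t_lag: float
    linear_window: tuple[int, int]
    residual_sse: float
    converged: bool
    weak_identifiability: bool = False
    regression: FluxRegression | None = field(default=None, compare=False)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _dimensionless_cumulative(tau: np.ndarray, tol: float, max_terms: int) -> np.ndarray:
    """Evaluate q(tau) = tau - 1/6 - (2/pi^2) * sum ((-1)^n/n^2) exp(-n^2 pi^2 tau).

    tau = D*t/L**2 must be > 0.  The alternating series is accumulated in
    consecutive (+,-) pairs to limit cancellation near tau = 0; summation
    stops once the next term's magnitude drops below
    ``tol * max(|partial sum|, 1/6)``.
    """
    tau = np.asarray(tau, dtype=float)
    series = np.zeros(tau.shape)
    done = np.zeros(tau.shape, dtype=bool)
    remaining = np.arange(tau.size)

    n = 1
    block = 64  # even: keeps (+,-) pairs intact within a block
    while remaining.size and n <= max_terms:
        ns = np.arange(n, min(n + block, max_terms + 1), dtype=float)
        ta = tau.flat[remaining]
        terms = (((-1.0) ** ns) / ns**2)[:, None] * np.exp(-np.outer(ns**2 * _PI2, ta))
        # pairwise accumulation of the alternating terms
        if terms.shape[0] % 2:
            terms = np.vstack([terms, np.zeros((1, terms.shape[1]))])
        partial = terms.reshape(-1, 2, terms.shape[1]).sum(axis=1).sum(axis=0)
        series.flat[remaining] += partial

        n_next = ns[-1] + 1
        bracket = ta + (-1.0 / 6.0) - (2.0 / _PI2) * series.flat[remaining]
        next_mag = np.exp(-n_next**2 * _PI2 * ta) / n_next**2
        ok = next_mag < tol * np.maximum(np.abs(bracket), 1.0 / 6.0)
        done.flat[remaining[ok]] = True
        remaining = remaining[~ok]
        n = int(n_next)

    if remaining.size:
        raise ConvergenceError(
            f"series did not converge within {max_terms} terms for "
            f"tau={tau.flat[remaining][:5]!r} (tol={tol})"
        )
    return tau - 1.0 / 6.0 - (2.0 / _PI2) * series


def cumulative_amount(
    t,
    params: DiffusionParams,
    membrane: MembraneSpec,
    donor: DonorSpec,
    tol: float = 1e-10,
    max_terms: int = 100_000,
):
    """Cumulative amount permeated per unit area, Q(t), in ug/cm**2.

    ``t`` may be a scalar or array of times in hours (all >= 0).  ``tol`` is
    the relative truncation tolerance of the eigenfunction series.  Values in
    ``(-1e-9, 0)`` arising from truncation/rounding are clamped to 0.
    """
    _require(tol > 0, f"tol must be > 0, got {tol}")
    t_arr = np.asarray(t, dtype=float)
    _require(bool(np.all(np.isfinite(t_arr))), "t must be finite")
    _require(bool(np.all(t_arr >= 0)), "t must be non-negative")

    L = membrane.thickness_L
    scale = donor.concentration_Cd * params.K * L
    tau = params.D * t_arr / L**2

    q = np.zeros(t_arr.shape)
    pos = tau > 0
    if np.any(pos):
        q[pos] = _dimensionless_cumulative(tau[pos], tol, max_terms)
    out = scale * q
    # physical non-negativity: tiny negatives from truncation are zeroed
    out = np.where((out < 0) & (out > -1e-9 * max(scale, 1.0)), 0.0, out)
    if np.ndim(t) == 0:
        return float(out)
    return out


def lag_time(params: DiffusionParams, membrane: MembraneSpec) -> float:
    """Diffusional time lag L**2/(6*D), the t-intercept of the Q(t) asymptote."""
    _require(params.D > 0, f"D must be > 0, got {params.D}")
    return membrane.thickness_L**2 / (6.0 * params.D)


# ---------------------------------------------------------------------------
# steady-state regression and derived coefficients
# ---------------------------------------------------------------------------

def _ols_line(t: np.ndarray, q: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r**2; a zero-variance response is a perfect flat line."""
    if np.ptp(q) == 0.0:
        return 0.0, float(q[0]), 1.0
    res = stats.linregress(t, q)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def steady_state_flux(
    series: PermeationSeries,
    window: tuple[int, int] | None = None,
    r2_threshold: float = 0.99,
) -> FluxRegression:
    """Steady-state flux J_ss: OLS slope of the linear portion of Q(t).

    When ``window`` (half-open index range) is not given, every suffix window
    with at least 4 points is scored and the longest one with
    ``r**2 >= r2_threshold`` is chosen; if none qualifies, the best-r**2
    suffix is returned with ``warn_nonlinear=True``.
    """
    t, q = series.times, series.cumulative_Q
    n = len(series)
    if n < 4:
        raise InputError(f"need at least 4 points for the flux regression, got {n}")

    if window is not None:
        lo, hi = int(window[0]), int(window[1])
        if not (0 <= lo < hi <= n) or hi - lo < 4:
            raise InputError(f"window {window!r} must contain >= 4 points within the series")
        slope, intercept, r2 = _ols_line(t[lo:hi], q[lo:hi])
        return FluxRegression(slope, intercept, (lo, hi), r2)

    best: tuple[float, int] | None = None  # (r2, start)
    for start in range(0, n - 3):
        slope, intercept, r2 = _ols_line(t[start:], q[start:])
        if r2 >= r2_threshold - 1e-12:
            return FluxRegression(slope, intercept, (start, n), r2)
        if best is None or r2 > best[0]:
            best = (r2, start)
    assert best is not None
    start = best[1]
    slope, intercept, r2 = _ols_line(t[start:], q[start:])
    return FluxRegression(slope, intercept, (start, n), r2, warn_nonlinear=True)


def apparent_permeability(J_ss: float, donor: DonorSpec) -> float:
    """Apparent permeability coefficient P_app = J_ss / Cd, in cm/h."""
    _require(donor.concentration_Cd > 0,
             f"donor concentration must be > 0, got {donor.concentration_Cd}")
    return J_ss / donor.concentration_Cd


def diffusivity_from_papp(P_app: float, membrane: MembraneSpec) -> float:
    """Steady-state diffusivity D = P_app * L / K, in cm**2/h.

    Inverse of the asymptotic identity P_app = D*K/L; requires the membrane's
    partition coefficient to be set.
    """
    if membrane.partition_K is None:
        raise InputError("membrane.partition_K is required to convert P_app to D")
    return P_app * membrane.thickness_L / membrane.partition_K


# ---------------------------------------------------------------------------
# inverse fitting
# ---------------------------------------------------------------------------

def fit_diffusion_model(
    series: PermeationSeries,
    membrane: MembraneSpec,
    donor: DonorSpec,
) -> DiffusionFit:
    """Least-squares estimate of (D, K) from a cumulative permeation curve.

    Minimizes the sum of squared model-weighted residuals
    ``(Q_model(t_i) - Q_i) / Q_model(t_i)`` in (log D, log K) space so both
    parameters stay positive.  The relative weighting is the maximum-
    likelihood choice for assay error that scales with the measured
    concentration (multiplicative noise); it also keeps the small early
    samples, which carry the lag information, from being swamped by the
    large late ones.  The start point comes from the steady-state
    regression: the line's t-intercept gives ``t_lag`` hence
    ``D0 = L**2/(6*t_lag)`` and its slope gives ``K0 = slope*L/(D0*Cd)``.
    ``Cd`` and ``L`` are fixed known inputs and are never fitted.

    A series that is linear through the origin carries no lag information; D
    is then weakly identified and the fit is flagged accordingly.
    """
    t, q = series.times, series.cumulative_Q
    if len(series) < 5:
        raise InputError(f"need at least 5 points to fit the diffusion model, got {len(series)}")

    L = membrane.thickness_L
    Cd = donor.concentration_Cd

    reg = steady_state_flux(series)
    slope, intercept = reg.J_ss, reg.intercept
    q_scale = float(np.max(np.abs(q))) or 1.0

    # t-intercept of the asymptote; near-zero intercept => no lag information
    weak = slope <= 0 or intercept > -1e-6 * q_scale
    if weak:
        t0 = 0.05 * t[-1]
        slope = max(slope, q_scale / max(t[-1], 1e-12))
    else:
        t0 = -intercept / slope
        t0 = min(max(t0, 1e-4 * t[-1]), t[-1])
    D0 = L**2 / (6.0 * t0)
    K0 = max(slope * L / (D0 * Cd), 1e-12)

    floor = 1e-6 * q_scale  # keeps near-zero model values from blowing up weights

    def residuals(theta: np.ndarray) -> np.ndarray:
        D, K = np.exp(theta)
        try:
            model = cumulative_amount(t, DiffusionParams(D, K), membrane, donor)
        except ConvergenceError:
            return np.full(t.shape, 1e6)
        return (model - q) / np.maximum(model, floor)

    sol = optimize.least_squares(
        residuals,
        x0=np.log([D0, K0]),
        method="lm",
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=400,
    )
    D_hat, K_hat = np.exp(sol.x)
    params = DiffusionParams(float(D_hat), float(K_hat))

    J_ss = params.D * params.K * Cd / L
    P_app = J_ss / Cd
    t_lag = lag_time(params, membrane)
    model = cumulative_amount(t, params, membrane, donor)
    sse = float(np.sum((model - q) ** 2))  # unweighted, in (ug/cm^2)^2
    weak = weak or t_lag > t[-1]

    return DiffusionFit(
        params=params,
        J_ss=J_ss,
        P_app=P_app,
        D_from_Papp=P_app * L / params.K,
        t_lag=t_lag,
        linear_window=reg.window,
        residual_sse=sse,
        converged=bool(sol.success),
        weak_identifiability=bool(weak),
        regression=reg,
    )
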