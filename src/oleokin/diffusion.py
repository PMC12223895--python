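"""Fick's-law spherical diffusion for the slow stage of solid-liquid extraction.

For a homogeneous sphere of radius R with constant surface concentration,
the fraction of oil extracted by internal diffusion is the series

    M_t/M_inf = 1 - (6/pi^2) * sum_{n>=1} (1/n^2) exp(-n^2 pi^2 De t / R^2)

with De the effective diffusivity (m^2/s) and t in **seconds**. At long
times the series collapses to its first term,

    M_t/M_inf = 1 - A exp(-B t),

where geometry fixes A = 6/pi^2 for an ideal sphere and B = De pi^2 / R^2.
In practice A is fitted freely alongside B (surface washing inflates the
apparent A), and De is recovered from the fitted B and the particle radius:
De = B R^2 / pi^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
from scipy.optimize import least_squares

from .fitting import FitStatistics, fit_statistics

__all__ = [
    "DEFAULT_PARTICLE_RADIUS_M",
    "DiffusionDataset",
    "DiffusionResult",
    "fick_series_full",
    "fick_longtime",
    "fit_diffusion",
    "effective_diffusivity",
    "radius_from_anchor",
]

#: Mean kernel-particle radius (m) back-calculated from the 25 degC anchor
#: pair De = 1.8e-11 m^2/s, B = 1.18e-4 1/s via radius_from_anchor.
DEFAULT_PARTICLE_RADIUS_M = 1.22700e-3

_SERIES_TOL = 1e-12
_SERIES_MAX_TERMS = 10_000


@dataclass(frozen=True)
class DiffusionDataset:
    """Normalised extraction curve M_t/M_inf vs time in seconds."""

    temperature_c: float
    times_s: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(self, "fractions", np.asarray(self.fractions, dtype=float))
        t, f = self.times_s, self.fractions
        if t.ndim != 1 or t.shape != f.shape or t.size == 0:
            raise ValueError("times and fractions must be nonempty 1-D of equal length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and >= 0")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def n_points(self) -> int:
        return int(self.times_s.size)


@dataclass
class DiffusionResult:
    """Fitted long-time diffusion model and the diffusivity derived from it."""

    A: float  # dimensionless pre-exponential
    B: float  # 1/s decay coefficient
    n_points: int
    sse: float
    r_squared: float
    r_squared_adj: float
    rmse_n: float
    rmse_df: float
    converged: bool
    residuals: np.ndarray
    effective_diffusivity: float | None = None  # m^2/s, set via with_radius
    particle_radius: float | None = None  # m
    dataset: DiffusionDataset | None = field(default=None, repr=False)

    def with_radius(self, radius: float) -> "DiffusionResult":
        """Return a copy with De = B*radius^2/pi^2 filled in."""
        de = effective_diffusivity(self.B, radius)
        return DiffusionResult(
            **{
                **self.__dict__,
                "effective_diffusivity": de,
                "particle_radius": radius,
            }
        )

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "B_per_s": self.B,
            "effective_diffusivity_m2_per_s": self.effective_diffusivity,
            "particle_radius_m": self.particle_radius,
            "n_points": self.n_points,
            "sse": self.sse,
            "r_squared": self.r_squared,
            "r_squared_adj": self.r_squared_adj,
            "rmse": {"sqrt_sse_over_n": self.rmse_n, "sqrt_sse_over_df": self.rmse_df},
            "converged": self.converged,
        }


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


def fick_series_full(
    de: float,
    radius: float,
    t: npt.ArrayLike,
    n_terms: int | None = None,
) -> np.ndarray | float:
    """Full spherical-diffusion series, truncated adaptively.

    Terms are added until the next term's magnitude falls below 1e-12 or
    10^4 terms are reached; ``n_terms`` forces a fixed truncation instead.
    Exactly 0 at t = 0 (the prefactor (6/pi^2) sums the series to 1).
    """
    _check_positive(de=de, radius=radius)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    tau = de * math.pi**2 * t / radius**2  # dimensionless time
    out = np.zeros_like(tau)
    pos = tau > 0
    if np.any(pos):
        acc = np.zeros(pos.sum())
        tau_pos = tau[pos]
        max_terms = n_terms if n_terms is not None else _SERIES_MAX_TERMS
        for n in range(1, max_terms + 1):
            term = np.exp(-(n**2) * tau_pos) / n**2
            acc += term
            if n_terms is None and term.max() < _SERIES_TOL:
                break
        out[pos] = 1.0 - (6.0 / math.pi**2) * acc
    np.clip(out, 0.0, 1.0, out=out)
    return float(out[0]) if scalar else out


def fick_longtime(A: float, B: float, t: npt.ArrayLike) -> np.ndarray | float:
    """One-term (long-time) model 1 - A*exp(-B*t), floored at 0.

    With a freely fitted A > 1 the raw expression is negative at small t;
    the reported value is clipped at 0 from below.
    """
    _check_positive(A=A, B=B)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.maximum(1.0 - A * np.exp(-B * t), 0.0)
    return out if out.ndim else float(out)


def fit_diffusion(dataset: DiffusionDataset) -> DiffusionResult:
    """Least-squares fit of the long-time model over (A, B).

    Both parameters are fitted on log scale (positivity without bounds);
    the starting point comes from the log-linearisation ln(1-f) = ln A - B t
    over the points with f < 1. The diffusivity is left unset; apply
    :meth:`DiffusionResult.with_radius` or :func:`effective_diffusivity`.
    """
    if dataset.n_points < 3:
        raise ValueError(f"need at least 3 points, got {dataset.n_points}")
    t, f = dataset.times_s, dataset.fractions

    mask = f < 1.0
    if mask.sum() >= 2:
        coef = np.polyfit(t[mask], np.log1p(-f[mask]), 1)
        b0 = max(-coef[0], 1e-12)
        a0 = min(max(math.exp(coef[1]), 1e-6), 1e6)
    else:
        b0, a0 = 1.0 / max(t[-1], 1.0), 1.0

    def resid(log_params: np.ndarray) -> np.ndarray:
        a, b = np.exp(log_params)
        return (1.0 - a * np.exp(-b * t)) - f  # raw model, no clipping

    sol = least_squares(
        resid,
        np.log([a0, b0]),
        method="lm",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=10_000,
    )
    a, b = np.exp(sol.x)
    stats: FitStatistics = fit_statistics(f, 1.0 - a * np.exp(-b * t), 2)
    return DiffusionResult(
        A=float(a),
        B=float(b),
        n_points=dataset.n_points,
        sse=stats.sse,
        r_squared=stats.r_squared,
        r_squared_adj=stats.r_squared_adj,
        rmse_n=stats.rmse_n,
        rmse_df=stats.rmse_df,
        converged=bool(sol.success),
        residuals=sol.fun.copy(),
        dataset=dataset,
    )


def effective_diffusivity(B: float, radius: float) -> float:
    """De = B * radius^2 / pi^2 (m^2/s) from the first-term decay coefficient."""
    _check_positive(B=B, radius=radius)
    return B * radius**2 / math.pi**2


def radius_from_anchor(de: float, B: float) -> float:
    """Particle radius pi*sqrt(De/B) implied by a (De, B) pair.

    Exact inverse of :func:`effective_diffusivity`; used to back-calculate
    the radius from a published diffusivity/decay anchor when the particle
    size itself is not reported.
    """
    _check_positive(de=de, B=B)
    return math.pi * math.sqrt(de / B)
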