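"""Closed-form extraction-kinetics models.

Two empirical models describe cumulative solid-liquid extraction as the
dimensionless extracted fraction f(t) = m_l / m_tl, where m_l is the lipid
mass recovered at time t and m_tl the total extractable lipid basis of the
solid (both g per 100 g kernel):

* pseudo-first-order:  f(t) = 1 - exp(-k1 * t)
* Brimberg:            f(t) = 1 - exp(-k2 * t**n)

The Brimberg form interpolates between washing-dominated (n < 1, fast early
uptake) and first-order behaviour (n = 1), to which it reduces exactly.

Time is in **minutes** throughout this module and rate constants in min^-1;
the diffusion module works in seconds. Unit conversion is the caller's
responsibility and never implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "KineticDataset",
    "KineticModelSpec",
    "PSEUDO_FIRST_ORDER",
    "BRIMBERG",
    "get_model",
    "eval_pseudo_first_order",
    "eval_brimberg",
]


def _require_positive(name: str, value: float) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be > 0, got {value!r}")


def _require_nonnegative_time(t: npt.ArrayLike) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"t must be >= 0, got {t!r}")
    return t


def eval_pseudo_first_order(k1: float, t: npt.ArrayLike) -> np.ndarray | float:
    """Extracted fraction 1 - exp(-k1*t) for a first-order rate constant.

    Parameters
    ----------
    k1
        Extraction rate constant, min^-1; must be positive.
    t
        Time in minutes, scalar or array; must be non-negative.

    Returns
    -------
    Extracted fraction in [0, 1), monotone nondecreasing in both arguments.
    """
    _require_positive("k1", k1)
    t = _require_nonnegative_time(t)
    out = -np.expm1(-k1 * t)
    return out if out.ndim else float(out)


def eval_brimberg(k2: float, n: float, t: npt.ArrayLike) -> np.ndarray | float:
    """Extracted fraction 1 - exp(-k2 * t**n) (Brimberg washing/diffusion model).

    Reduces exactly to :func:`eval_pseudo_first_order` at n = 1. The exponent
    is not restricted to n <= 1: any positive n is a valid model.
    """
    _require_positive("k2", k2)
    _require_positive("n", n)
    t = _require_nonnegative_time(t)
    out = -np.expm1(-k2 * np.power(t, n))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KineticModelSpec:
    """Named kinetic model with its parameter layout.

    ``curve(params, t)`` evaluates the extracted fraction for a parameter
    vector ordered as ``parameter_names``. All parameters are positive with
    no upper bound.
    """

    name: str
    parameter_names: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = {"pseudo_first_order": 1, "brimberg": 2}
        if self.name not in expected:
            raise ValueError(f"unknown kinetic model {self.name!r}")
        if len(self.parameter_names) != expected[self.name]:
            raise ValueError(
                f"{self.name} takes {expected[self.name]} parameter(s), "
                f"got {self.parameter_names}"
            )

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    def curve(self, params: npt.ArrayLike, t: npt.ArrayLike) -> np.ndarray | float:
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"{self.name} expects {self.n_params} parameter(s), got shape {params.shape}"
            )
        if self.name == "pseudo_first_order":
            return eval_pseudo_first_order(params[0], t)
        return eval_brimberg(params[0], params[1], t)


PSEUDO_FIRST_ORDER = KineticModelSpec("pseudo_first_order", ("k1",))
BRIMBERG = KineticModelSpec("brimberg", ("k2", "n"))

_MODELS = {m.name: m for m in (PSEUDO_FIRST_ORDER, BRIMBERG)}


def get_model(name: str) -> KineticModelSpec:
    """Look up a model spec by name ('pseudo_first_order' or 'brimberg')."""
    try:
        return _MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown kinetic model {name!r}; choose from {sorted(_MODELS)}"
        ) from None


@dataclass(frozen=True)
class KineticDataset:
    """One temperature's extraction time series.

    Attributes
    ----------
    temperature_c
        Extraction temperature, deg C.
    times_min
        Sampling times in minutes, strictly increasing and positive.
    yields_g_per_100g
        Cumulative lipid yield at each time, g per 100 g kernel.
    total_lipid_basis
        The normaliser m_tl (g per 100 g kernel) used to convert yields to
        extracted fractions. Required; there is no default because the basis
        (total vs hexane-extractable lipids) is a modelling choice.
    """

    temperature_c: float
    times_min: np.ndarray
    yields_g_per_100g: np.ndarray
    total_lipid_basis: float
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_min", np.asarray(self.times_min, dtype=float))
        object.__setattr__(
            self, "yields_g_per_100g", np.asarray(self.yields_g_per_100g, dtype=float)
        )
        t, y = self.times_min, self.yields_g_per_100g
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and yields must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("dataset is empty")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and > 0")
        if np.any(y < 0):
            raise ValueError("yields must be >= 0")
        if self.total_lipid_basis <= 0:
            raise ValueError("total_lipid_basis must be > 0")
        if np.any(y > self.total_lipid_basis * (1 + 1e-12)):
            raise ValueError(
                "yield exceeds total_lipid_basis: extracted fraction would be > 1"
            )

    @property
    def n_points(self) -> int:
        return int(self.times_min.size)

    @property
    def fractions(self) -> np.ndarray:
        """Extracted fractions yields / total_lipid_basis, in [0, 1]."""
        return self.yields_g_per_100g / self.total_lipid_basis
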