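"""Arrhenius analysis of extraction rate constants.

The temperature dependence of a rate constant k (min^-1) is modelled as

    k = k0 * exp(-Ea / (R * T))

with Ea the activation energy (J/mol), k0 the frequency factor (min^-1),
R = 8.314 J mol^-1 K^-1 and T the absolute temperature (K). Estimation is
ordinary least squares on the linearised Arrhenius plot, ln k vs 1/T:
the slope is -Ea/R and the intercept ln k0.

For this oil-extraction system the analysis is applied to the
pseudo-first-order rate constants: the fitted Brimberg k2 *decreases* with
temperature (its role is entangled with the exponent n), which is unphysical
for an Arrhenius law, while k1 increases monotonically. The functions below
accept any positive rate series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy import stats

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
ABSOLUTE_ZERO_C = -273.15

__all__ = ["GAS_CONSTANT", "ArrheniusResult", "fit_arrhenius", "predict_k"]


@dataclass(frozen=True)
class ArrheniusResult:
    """Activation energy and the log-linear regression behind it."""

    activation_energy: float  # J/mol
    frequency_factor: float  # min^-1
    slope: float  # of ln k vs 1/T_K, in K
    intercept: float  # ln(k0)
    r_squared: float
    temperatures_k: np.ndarray

    @property
    def activation_energy_kj(self) -> float:
        return self.activation_energy / 1000.0

    def to_dict(self) -> dict:
        return {
            "activation_energy_J_per_mol": self.activation_energy,
            "activation_energy_kJ_per_mol": self.activation_energy_kj,
            "frequency_factor_per_min": self.frequency_factor,
            "slope_K": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "temperatures_K": self.temperatures_k.tolist(),
        }


def fit_arrhenius(
    rate_constants: npt.ArrayLike, temperatures_c: npt.ArrayLike
) -> ArrheniusResult:
    """OLS of ln k on 1/T_K over >= 3 (rate constant, temperature) pairs.

    Parameters
    ----------
    rate_constants
        Positive rate constants, min^-1, one per temperature.
    temperatures_c
        Matching temperatures in deg C (converted internally with
        T_K = T_C + 273.15).
    """
    k = np.asarray(rate_constants, dtype=float)
    temp_c = np.asarray(temperatures_c, dtype=float)
    if k.shape != temp_c.shape or k.ndim != 1:
        raise ValueError("rate_constants and temperatures must be 1-D of equal length")
    if k.size < 3:
        raise ValueError(f"need at least 3 (k, T) pairs, got {k.size}")
    if np.any(k <= 0):
        raise ValueError("rate constants must be > 0")
    if np.any(temp_c <= ABSOLUTE_ZERO_C):
        raise ValueError("temperatures must be above absolute zero")
    temp_k = temp_c + 273.15
    reg = stats.linregress(1.0 / temp_k, np.log(k))
    return ArrheniusResult(
        activation_energy=-reg.slope * GAS_CONSTANT,
        frequency_factor=float(np.exp(reg.intercept)),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
        temperatures_k=temp_k,
    )


def predict_k(result: ArrheniusResult, temperature_c: float) -> float:
    """Rate constant k0*exp(-Ea/(R*T_K)) at a temperature in deg C."""
    if temperature_c <= ABSOLUTE_ZERO_C:
        raise ValueError(f"temperature must be above {ABSOLUTE_ZERO_C} degC")
    temp_k = temperature_c + 273.15
    return result.frequency_factor * float(
        np.exp(-result.activation_energy / (GAS_CONSTANT * temp_k))
    )
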