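"""Seeded generators of synthetic extraction experiments with known ground truth.

The kinetics generator emulates a bench solvent-extraction run: cumulative
yield sampled at 15, 30, 60, 120, 180 and 240 min at 25, 50 and 60 degC,
with the underlying curve drawn from one of the two kinetic models and,
optionally, per-temperature rate constants derived from an Arrhenius law.
Measurement noise is additive Gaussian on the *fraction* scale (the
simplest model consistent with gravimetric replicate error), truncated to
[0, 1] afterwards; truncation events are counted in the truth record.

The diffusion generator produces normalised long-duration curves from the
full spherical Fick series, by default at 9 time points.

One integer seed expands deterministically into independent substreams, one
per generated dataset, so identical configurations are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arrhenius import GAS_CONSTANT
from .diffusion import DiffusionDataset, fick_series_full
from .models import KineticDataset, get_model

__all__ = [
    "DEFAULT_SAMPLING_TIMES_MIN",
    "DEFAULT_TEMPERATURES_C",
    "DEFAULT_DIFFUSION_TIMES_S",
    "SimulationConfig",
    "simulate_kinetics",
    "simulate_diffusion",
]

DEFAULT_SAMPLING_TIMES_MIN = (15.0, 30.0, 60.0, 120.0, 180.0, 240.0)
DEFAULT_TEMPERATURES_C = (25.0, 50.0, 60.0)
#: 9-point grid spanning the washing and diffusion stages (s): 5 min - 4 h.
DEFAULT_DIFFUSION_TIMES_S = (
    300.0, 900.0, 1800.0, 3600.0, 5400.0, 7200.0, 9000.0, 10800.0, 14400.0,
)
#: Kernel total-lipid content, g per 100 g (the fraction->yield scale).
DEFAULT_TOTAL_LIPID_BASIS = 64.19


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth description of a simulated extraction experiment.

    ``parameters`` holds the true model parameters (``{"k1": ...}`` or
    ``{"k2": ..., "n": ...}``). When ``arrhenius`` is given as
    ``(Ea_J_per_mol, k0_per_min)``, the rate constant at each temperature is
    derived as k0*exp(-Ea/(R*T_K)) and overrides the one in ``parameters``
    (the Brimberg exponent n stays fixed across temperatures).
    """

    model: str
    parameters: dict[str, float]
    temperatures_c: tuple[float, ...] = DEFAULT_TEMPERATURES_C
    arrhenius: tuple[float, float] | None = None  # (Ea J/mol, k0 min^-1)
    times_min: tuple[float, ...] = DEFAULT_SAMPLING_TIMES_MIN
    noise_sigma: float = 0.0
    n_replicates: int = 1
    total_lipid_basis: float = DEFAULT_TOTAL_LIPID_BASIS
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        get_model(self.model)  # validates the name
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        t = np.asarray(self.times_min)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be positive and strictly increasing")


def _rate_at(config: SimulationConfig, temperature_c: float) -> dict[str, float]:
    params = dict(config.parameters)
    if config.arrhenius is not None:
        ea, k0 = config.arrhenius
        k = k0 * float(np.exp(-ea / (GAS_CONSTANT * (temperature_c + 273.15))))
        rate_name = "k1" if config.model == "pseudo_first_order" else "k2"
        params[rate_name] = k
    return params


def simulate_kinetics(
    config: SimulationConfig,
) -> tuple[list[KineticDataset], dict]:
    """Generate noisy kinetic datasets plus the ground-truth record.

    Returns one :class:`KineticDataset` per (temperature, replicate), in
    temperature-major order, and a JSON-serialisable truth dict holding the
    per-temperature true parameters, the seed, and the count of noisy
    fractions truncated into [0, 1].
    """
    model = get_model(config.model)
    times = np.asarray(config.times_min, dtype=float)
    streams = np.random.SeedSequence(config.seed).spawn(
        len(config.temperatures_c) * config.n_replicates
    )
    datasets: list[KineticDataset] = []
    truth_by_temp: dict[str, dict] = {}
    truncated = 0
    i = 0
    for temp in config.temperatures_c:
        params = _rate_at(config, temp)
        pvec = np.array([params[name] for name in model.parameter_names])
        clean = np.asarray(model.curve(pvec, times), dtype=float)
        truth_by_temp[f"{temp:g}"] = dict(params)
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(streams[i])
            i += 1
            noisy = clean + rng.normal(0.0, config.noise_sigma, size=times.shape)
            clipped = np.clip(noisy, 0.0, 1.0)
            truncated += int(np.sum(clipped != noisy))
            datasets.append(
                KineticDataset(
                    temperature_c=temp,
                    times_min=times.copy(),
                    yields_g_per_100g=clipped * config.total_lipid_basis,
                    total_lipid_basis=config.total_lipid_basis,
                    label=f"T{temp:g}C_rep{rep}",
                )
            )
    truth = {
        "model": config.model,
        "parameters_by_temperature": truth_by_temp,
        "arrhenius": (
            {"Ea_J_per_mol": config.arrhenius[0], "k0_per_min": config.arrhenius[1]}
            if config.arrhenius
            else None
        ),
        "noise_sigma": config.noise_sigma,
        "total_lipid_basis": config.total_lipid_basis,
        "seed": config.seed,
        "n_truncated": truncated,
    }
    return datasets, truth


def simulate_diffusion(
    de: float,
    radius: float,
    times_s=DEFAULT_DIFFUSION_TIMES_S,
    noise_sigma: float = 0.0,
    seed: int = 0,
    temperature_c: float = 25.0,
) -> tuple[DiffusionDataset, dict]:
    """Generate one normalised diffusion curve from the full Fick series.

    Noise is additive Gaussian on the fraction scale, truncated to [0, 1].
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    times = np.asarray(times_s, dtype=float)
    clean = np.asarray(fick_series_full(de, radius, times), dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noisy = clean + rng.normal(0.0, noise_sigma, size=times.shape)
    clipped = np.clip(noisy, 0.0, 1.0)
    dataset = DiffusionDataset(
        temperature_c=temperature_c, times_s=times, fractions=clipped
    )
    truth = {
        "effective_diffusivity_m2_per_s": de,
        "particle_radius_m": radius,
        "noise_sigma": noise_sigma,
        "seed": seed,
        "n_truncated": int(np.sum(clipped != noisy)),
    }
    return dataset, truth
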