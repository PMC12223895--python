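"""Bundled reference measurements for *Attalea tessmannii* kernel-oil extraction.

Small published tables shipped with the package as CSV: fitted kinetic and
diffusion coefficients per extraction temperature (25, 50, 60 degC), the
gas-chromatography FAME profile, NMR-derived oil quality indices, and the
kernel's proximate composition. These are measured inputs for worked
examples and downstream calculations (e.g. the Arrhenius fit over the
published rate constants), not quantities the package computes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fame import FattyAcidRecord

__all__ = [
    "DE_ANCHOR_25C_M2_PER_S",
    "kinetic_fits",
    "diffusion_fits",
    "fame_profile",
    "fame_records",
    "oil_quality_indices",
    "proximate_composition",
]

#: Published effective diffusivity at 25 degC (m^2/s); with the matching
#: B coefficient it anchors the back-calculated particle radius.
DE_ANCHOR_25C_M2_PER_S = 1.8e-11


def _load(name: str) -> pd.DataFrame:
    with resources.files("oleokin.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def kinetic_fits() -> pd.DataFrame:
    """Published kinetic-model coefficients and fit statistics per temperature.

    Columns: temperature_C, model, k, k_std, n, n_std, r_squared,
    r_squared_adj, sse, rmse. The published RMSE column follows the
    sqrt(SSE/(N-p)) convention for this table.
    """
    return _load("kinetic_fits.csv")


def diffusion_fits() -> pd.DataFrame:
    """Published long-time diffusion-model coefficients per temperature.

    Columns: temperature_C, A, B_per_s, sse, r_squared, r_squared_adj, rmse.
    The published RMSE column here follows the sqrt(SSE) convention.
    """
    return _load("diffusion_fits.csv")


def fame_profile() -> pd.DataFrame:
    """Published FAME area-percent profile at each extraction temperature."""
    return _load("fame_profile.csv")


def fame_records(temperature_c: float) -> list[FattyAcidRecord]:
    """FAME profile at one temperature as :class:`FattyAcidRecord` objects."""
    df = fame_profile()
    sub = df[df["temperature_C"] == temperature_c]
    if sub.empty:
        raise ValueError(
            f"no FAME profile at {temperature_c} degC; "
            f"available: {sorted(df['temperature_C'].unique())}"
        )
    return [
        FattyAcidRecord(row["name"], row["shorthand"], row["area_pct"])
        for _, row in sub.iterrows()
    ]


def oil_quality_indices() -> pd.DataFrame:
    """Measured peroxide/saponification/FFA/iodine indices (data, not computed)."""
    return _load("oil_quality_indices.csv")


def proximate_composition() -> pd.DataFrame:
    """Measured kernel proximate composition, percent by mass (data, not computed)."""
    return _load("proximate_composition.csv")
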