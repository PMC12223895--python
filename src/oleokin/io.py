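"""Delimited-text readers and writers for kinetic, diffusion and FAME tables.

All tables are comma-separated with dot decimals and a header row:

* kinetics:  ``temperature_C,time_min,yield_g_per_100g``
* diffusion: ``temperature_C,time_s,fraction``
* FAME:      ``name,shorthand,area_pct,temperature_C``

One file may hold several temperatures; rows are grouped by temperature and
sorted by time on load. Validation failures raise :class:`LoadError` naming
the offending file row (1-based, counting the header as row 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fame import FattyAcidRecord
from .diffusion import DiffusionDataset
from .models import KineticDataset

__all__ = [
    "LoadError",
    "read_kinetics_table",
    "write_kinetics_table",
    "read_diffusion_table",
    "write_diffusion_table",
    "read_fame_table",
    "write_fame_table",
]


class LoadError(ValueError):
    """A delimited-text table failed validation on load."""


def _read_numeric_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise LoadError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise LoadError(f"{path}: no data rows")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise LoadError(
                f"{path}: unparseable value {df.loc[bad[0], col]!r} "
                f"in column {col!r} at row {bad[0] + 2}"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2
            raise LoadError(f"{path}: missing value in column {col!r} at row {row}")
        df[col] = coerced
    return df


def read_kinetics_table(
    path: str | Path, total_lipid_basis: float
) -> list[KineticDataset]:
    """Load one kinetic dataset per temperature from a CSV file.

    ``total_lipid_basis`` (g per 100 g) is required: the basis used to
    normalise yields into fractions is a modelling choice, never defaulted.
    """
    path = Path(path)
    df = _read_numeric_table(path, ["temperature_C", "time_min", "yield_g_per_100g"])
    over = df.index[df["yield_g_per_100g"] > total_lipid_basis]
    if len(over):
        raise LoadError(
            f"{path}: yield {df.loc[over[0], 'yield_g_per_100g']} exceeds "
            f"total_lipid_basis {total_lipid_basis} at row {over[0] + 2}"
        )
    datasets = []
    for temp, group in df.groupby("temperature_C", sort=True):
        group = group.sort_values("time_min")
        try:
            datasets.append(
                KineticDataset(
                    temperature_c=float(temp),
                    times_min=group["time_min"].to_numpy(),
                    yields_g_per_100g=group["yield_g_per_100g"].to_numpy(),
                    total_lipid_basis=total_lipid_basis,
                )
            )
        except ValueError as exc:
            raise LoadError(f"{path}: temperature {temp:g} degC: {exc}") from exc
    return datasets


def write_kinetics_table(datasets: Iterable[KineticDataset], path: str | Path) -> None:
    rows = [
        {
            "temperature_C": d.temperature_c,
            "time_min": t,
            "yield_g_per_100g": y,
        }
        for d in datasets
        for t, y in zip(d.times_min, d.yields_g_per_100g)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_diffusion_table(path: str | Path) -> list[DiffusionDataset]:
    """Load one normalised diffusion curve per temperature from a CSV file."""
    path = Path(path)
    df = _read_numeric_table(path, ["temperature_C", "time_s", "fraction"])
    datasets = []
    for temp, group in df.groupby("temperature_C", sort=True):
        group = group.sort_values("time_s")
        try:
            datasets.append(
                DiffusionDataset(
                    temperature_c=float(temp),
                    times_s=group["time_s"].to_numpy(),
                    fractions=group["fraction"].to_numpy(),
                )
            )
        except ValueError as exc:
            raise LoadError(f"{path}: temperature {temp:g} degC: {exc}") from exc
    return datasets


def write_diffusion_table(datasets: Iterable[DiffusionDataset], path: str | Path) -> None:
    rows = [
        {"temperature_C": d.temperature_c, "time_s": t, "fraction": f}
        for d in datasets
        for t, f in zip(d.times_s, d.fractions)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fame_table(path: str | Path) -> dict[float, list[FattyAcidRecord]]:
    """Load FAME profiles keyed by temperature from a CSV file."""
    path = Path(path)
    df = _read_numeric_table(path, ["area_pct", "temperature_C"])
    for col in ("name", "shorthand"):
        if col not in df.columns:
            raise LoadError(f"{path}: missing required column(s) ['{col}']")
    profiles: dict[float, list[FattyAcidRecord]] = {}
    for idx, row in df.iterrows():
        try:
            rec = FattyAcidRecord(
                common_name=str(row["name"]),
                shorthand=str(row["shorthand"]).strip(),
                area_pct=float(row["area_pct"]),
            )
        except ValueError as exc:
            raise LoadError(f"{path}: row {idx + 2}: {exc}") from exc
        profiles.setdefault(float(row["temperature_C"]), []).append(rec)
    return profiles


def write_fame_table(
    profiles: dict[float, Sequence[FattyAcidRecord]], path: str | Path
) -> None:
    rows = [
        {
            "name": rec.common_name,
            "shorthand": rec.shorthand,
            "area_pct": rec.area_pct,
            "temperature_C": temp,
        }
        for temp, records in sorted(profiles.items())
        for rec in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
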