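"""End-to-end analysis pipeline: kinetics fits, model selection, Arrhenius,
diffusion, and FAME summaries composed into one structured report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .arrhenius import fit_arrhenius
from .diffusion import DEFAULT_PARTICLE_RADIUS_M, fit_diffusion
from .fame import aggregate_saturation
from .fitting import compare_models, fit_kinetic_model
from .io import read_diffusion_table, read_fame_table, read_kinetics_table
from .models import get_model

logger = logging.getLogger("oleokin")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    ``total_lipid_basis`` is mandatory whenever kinetics data are supplied;
    there is no default basis. ``arrhenius_model`` names the kinetic model
    whose rate constants enter the Arrhenius fit (pseudo-first-order by
    default: its constant increases with temperature, as an Arrhenius law
    requires, while the Brimberg constant is entangled with its exponent).
    """

    kinetics_path: str | Path | None = None
    total_lipid_basis: float | None = None
    diffusion_path: str | Path | None = None
    particle_radius: float = DEFAULT_PARTICLE_RADIUS_M
    fame_path: str | Path | None = None
    models: tuple[str, ...] = ("pseudo_first_order", "brimberg")
    arrhenius_model: str = "pseudo_first_order"
    seed: int | None = None  # echoed into the report; no stage draws randomness

    def __post_init__(self) -> None:
        if self.kinetics_path is not None and (
            self.total_lipid_basis is None or self.total_lipid_basis <= 0
        ):
            raise ValueError("total_lipid_basis (> 0) is required for kinetics runs")
        for name in self.models + (self.arrhenius_model,):
            get_model(name)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and return one JSON-serialisable report.

    Stages with no input are marked ``"not run"``. Stage failures raise
    :class:`PipelineError` carrying the stage name.
    """
    report: dict = {
        "package_version": __version__,
        "config": {
            "kinetics_path": str(config.kinetics_path) if config.kinetics_path else None,
            "total_lipid_basis": config.total_lipid_basis,
            "diffusion_path": str(config.diffusion_path) if config.diffusion_path else None,
            "particle_radius_m": config.particle_radius,
            "fame_path": str(config.fame_path) if config.fame_path else None,
            "models": list(config.models),
            "arrhenius_model": config.arrhenius_model,
            "seed": config.seed,
        },
    }

    rate_constants: list[tuple[float, float]] = []
    if config.kinetics_path is None:
        report["kinetics"] = "not run"
        report["arrhenius"] = "not run"
    else:
        try:
            datasets = read_kinetics_table(config.kinetics_path, config.total_lipid_basis)
            kin: dict = {}
            for ds in datasets:
                fits = [fit_kinetic_model(ds, get_model(m)) for m in config.models]
                ranked = compare_models(fits) if len(fits) > 1 else fits
                kin[f"{ds.temperature_c:g}"] = {
                    "fits": {f.model_name: f.to_dict() for f in fits},
                    "best_model": ranked[0].model_name,
                }
                sel = next(f for f in fits if f.model_name == config.arrhenius_model)
                rate_name = get_model(config.arrhenius_model).parameter_names[0]
                rate_constants.append((ds.temperature_c, sel.parameters[rate_name]))
            report["kinetics"] = kin
            logger.info("fitted %d kinetic dataset(s)", len(datasets))
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineError("kinetics", exc) from exc

        try:
            if len(rate_constants) >= 3:
                temps, ks = zip(*rate_constants)
                arr = fit_arrhenius(ks, temps)
                report["arrhenius"] = {
                    "rate_model": config.arrhenius_model,
                    **arr.to_dict(),
                }
                logger.info("activation energy %.3f kJ/mol", arr.activation_energy_kj)
            else:
                report["arrhenius"] = "not run"
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("arrhenius", exc) from exc

    if config.diffusion_path is None:
        report["diffusion"] = "not run"
    else:
        try:
            diff: dict = {}
            for ds in read_diffusion_table(config.diffusion_path):
                res = fit_diffusion(ds).with_radius(config.particle_radius)
                diff[f"{ds.temperature_c:g}"] = res.to_dict()
            report["diffusion"] = diff
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("diffusion", exc) from exc

    if config.fame_path is None:
        report["fame"] = "not run"
    else:
        try:
            fame: dict = {}
            for temp, records in sorted(read_fame_table(config.fame_path).items()):
                summary = aggregate_saturation(records)
                fame[f"{temp:g}"] = {
                    "sfa_total": summary.sfa_total,
                    "mufa_total": summary.mufa_total,
                    "pufa_total": summary.pufa_total,
                    "n_species": len(records),
                }
            report["fame"] = fame
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("fame", exc) from exc

    return report
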