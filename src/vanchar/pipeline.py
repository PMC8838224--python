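"""End-to-end characterization runs: configuration, orchestration, report.

A run is described by a :class:`RunConfig` (typically loaded from YAML):
per-stage input paths, tolerances and a seed.  :func:`run` executes every
configured stage in dependency order, isolates stage failures (a failing
or unconfigured stage is reported as skipped/failed while the rest
complete), and assembles a :class:`CharacterizationReport` whose JSON
payload is byte-identical across reruns with the same inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import io as vio
from ._rounding import round_half_away, round_sig
from .dna_binding import benesi_hildebrand_fit
from .formulas import molar_mass, parse_formula, percent_composition
from .molar_ratio import fit_breakpoint
from .qsar import fit_mlr, predict, validate
from .reactivity import (
    FrontierOrbitals,
    bond_length_from_frequency,
    descriptors_from_orbitals,
)
from .tga import check_step_assignment, coats_redfern_fit, horowitz_metzger_fit, segment_steps

__all__ = ["RunConfig", "Tolerances", "CharacterizationReport", "run", "load_config"]


class Tolerances(BaseModel):
    """Stage tolerances with field-specific defaults."""

    model_config = ConfigDict(extra="forbid")

    mass_loss_percent: float = 0.5     # observed vs formula mass loss, %
    breakpoint: float = 0.05           # molar-ratio label assignment
    chromism_threshold: float = 0.01   # relative absorbance change
    descriptor_consistency: float = 0.01  # eV, printed vs recomputed


class StageInputs(BaseModel):
    """Input paths per stage; a stage with no path is skipped."""

    model_config = ConfigDict(extra="forbid")

    compounds: Optional[Path] = None       # compound table (id, formula, role, mass)
    orbitals: Optional[Path] = None        # id, e_homo_eV, e_lumo_eV
    vo_frequencies: Optional[Path] = None  # id, frequency_cm1
    titrations: dict[str, Path] = {}       # compound id -> titration csv
    thermograms: dict[str, Path] = {}      # compound id -> thermogram csv
    molar_ratio: dict[str, Path] = {}      # compound id -> series csv
    qsar_training: Optional[Path] = None
    qsar_testing: Optional[Path] = None


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    min_loss_percent: float = 1.0          # TGA segmentation floor
    qsar_response_transform: str = "none"  # "none" | "log10"
    inputs: StageInputs = StageInputs()
    tolerances: Tolerances = Tolerances()

    def referenced_paths(self) -> list[Path]:
        paths = [
            p
            for p in (
                self.inputs.compounds,
                self.inputs.orbitals,
                self.inputs.vo_frequencies,
                self.inputs.qsar_training,
                self.inputs.qsar_testing,
            )
            if p is not None
        ]
        for mapping in (
            self.inputs.titrations,
            self.inputs.thermograms,
            self.inputs.molar_ratio,
        ):
            paths.extend(mapping.values())
        return paths


def load_config(path: Path | str) -> RunConfig:
    """Load and validate a YAML run configuration."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    config = RunConfig.model_validate(raw)
    base = Path(path).parent
    # resolve relative paths against the config file's directory

    def _resolve(p: Optional[Path]) -> Optional[Path]:
        return None if p is None else (p if p.is_absolute() else base / p)

    config.inputs.compounds = _resolve(config.inputs.compounds)
    config.inputs.orbitals = _resolve(config.inputs.orbitals)
    config.inputs.vo_frequencies = _resolve(config.inputs.vo_frequencies)
    config.inputs.qsar_training = _resolve(config.inputs.qsar_training)
    config.inputs.qsar_testing = _resolve(config.inputs.qsar_testing)
    for mapping in (
        config.inputs.titrations,
        config.inputs.thermograms,
        config.inputs.molar_ratio,
    ):
        for key in mapping:
            mapping[key] = _resolve(mapping[key])
    return config


@dataclass
class CharacterizationReport:
    """Aggregated per-stage results plus a consistency log."""

    sections: dict = dataclass_field(default_factory=dict)
    consistency_log: list = dataclass_field(default_factory=list)
    stage_status: dict = dataclass_field(default_factory=dict)

    @property
    def any_failed(self) -> bool:
        return any(status == "failed" for status in self.stage_status.values())

    def to_dict(self) -> dict:
        return {
            "sections": self.sections,
            "consistency_log": self.consistency_log,
            "stage_status": self.stage_status,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _stage(report: CharacterizationReport, name: str, configured: bool, fn) -> None:
    if not configured:
        report.stage_status[name] = "skipped (no input configured)"
        return
    try:
        report.sections[name] = fn()
        report.stage_status[name] = "ok"
    except Exception as exc:  # isolate stage failures
        report.stage_status[name] = "failed"
        report.sections[name] = {"error": f"{type(exc).__name__}: {exc}"}


def run(config: RunConfig) -> CharacterizationReport:
    """Execute all configured stages and assemble the report."""
    missing = [str(p) for p in config.referenced_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"configured input path(s) missing: {missing}")
    report = CharacterizationReport()
    inputs = config.inputs

    _stage(report, "composition", inputs.compounds is not None,
           lambda: _composition_stage(config, report))
    _stage(report, "reactivity", inputs.orbitals is not None,
           lambda: _reactivity_stage(config))
    _stage(report, "vo_bond", inputs.vo_frequencies is not None,
           lambda: _vo_bond_stage(config))
    _stage(report, "dna_binding", bool(inputs.titrations),
           lambda: _dna_stage(config))
    _stage(report, "tga", bool(inputs.thermograms),
           lambda: _tga_stage(config))
    _stage(report, "molar_ratio", bool(inputs.molar_ratio),
           lambda: _molar_ratio_stage(config))
    _stage(report, "qsar", inputs.qsar_training is not None,
           lambda: _qsar_stage(config))
    return report


def _composition_stage(config: RunConfig, report: CharacterizationReport) -> dict:
    records = vio.read_compound_table(config.inputs.compounds)
    section = {}
    for rec in records:
        comp = percent_composition(rec.formula)
        entry = {
            "formula": str(rec.formula),
            "role": rec.role,
            "molar_mass": round_half_away(comp.mass, 2),
            "percent_by_element": comp.rounded(),
        }
        if rec.nominal_mass is not None:
            deviation = comp.mass - rec.nominal_mass
            entry["nominal_mass"] = rec.nominal_mass
            entry["mass_deviation"] = round_half_away(deviation, 2)
            # nominal masses are printed to 1 d.p.; anything past rounding slack is flagged
            if abs(deviation) > 0.1:
                report.consistency_log.append(
                    {
                        "stage": "composition",
                        "id": rec.identifier,
                        "quantity": "molar_mass",
                        "nominal": rec.nominal_mass,
                        "recomputed": round_half_away(comp.mass, 2),
                    }
                )
        section[rec.identifier] = entry
    return section


def _reactivity_stage(config: RunConfig) -> dict:
    frame = vio.read_orbital_table(config.inputs.orbitals)
    section = {}
    for _, row in frame.iterrows():
        orb = FrontierOrbitals(float(row["e_homo_eV"]), float(row["e_lumo_eV"]))
        section[str(row["id"])] = descriptors_from_orbitals(orb).rounded()
    return section


def _vo_bond_stage(config: RunConfig) -> dict:
    frame = pd.read_csv(config.inputs.vo_frequencies)
    return {
        str(row["id"]): {
            "frequency_cm1": float(row["frequency_cm1"]),
            "length_angstrom": round_half_away(
                bond_length_from_frequency(float(row["frequency_cm1"])), 3
            ),
        }
        for _, row in frame.iterrows()
    }


def _dna_stage(config: RunConfig) -> dict:
    section = {}
    for ident, path in sorted(config.inputs.titrations.items()):
        series = vio.read_titration(path)
        fit = benesi_hildebrand_fit(
            series, chromism_threshold=config.tolerances.chromism_threshold
        )
        section[ident] = {
            "k_b": round_sig(fit.k_b, 3),
            "r_squared": round_half_away(fit.r_squared, 4),
            "chromism": fit.chromism,
            "shift": fit.shift,
            "n_used": fit.n_used,
            "warnings": fit.warnings,
        }
    return section


def _tga_stage(config: RunConfig) -> dict:
    section = {}
    for ident, path in sorted(config.inputs.thermograms.items()):
        curve = vio.read_thermogram(path)
        steps = segment_steps(curve, min_loss_percent=config.min_loss_percent)
        step_entries = []
        for step in steps:
            entry = {
                "t_start_K": round_half_away(step.t_start, 1),
                "t_end_K": round_half_away(step.t_end, 1),
                "percent_loss": round_half_away(step.percent_loss, 2),
                "t_peak_K": round_half_away(step.t_peak, 1),
            }
            for fit_fn, name in (
                (coats_redfern_fit, "coats_redfern"),
                (horowitz_metzger_fit, "horowitz_metzger"),
            ):
                try:
                    fit = fit_fn(step, curve.heating_rate_beta)
                    entry[name] = {
                        "e_a_kJ_per_mol": round_half_away(fit.e_a, 1),
                        "pre_exponential_per_min": round_sig(fit.pre_exponential_a, 3),
                        "r_squared": round_half_away(fit.r_squared, 4),
                        "delta_h_kJ_per_mol": round_half_away(fit.delta_h, 1),
                        "delta_s_J_per_mol_K": round_half_away(fit.delta_s, 1),
                        "delta_g_kJ_per_mol": round_half_away(fit.delta_g, 1),
                    }
                except Exception as exc:
                    entry[name] = {"error": f"{type(exc).__name__}: {exc}"}
            step_entries.append(entry)
        section[ident] = {"n_steps": len(steps), "steps": step_entries}
    return section


def _molar_ratio_stage(config: RunConfig) -> dict:
    section = {}
    for ident, path in sorted(config.inputs.molar_ratio.items()):
        series = vio.read_molar_ratio(path)
        result = fit_breakpoint(series, tol=config.tolerances.breakpoint)
        section[ident] = {
            "breakpoint": None
            if result.breakpoint is None
            else round_half_away(result.breakpoint, 3),
            "ratio_label": result.ratio_label,
            "warnings": result.warnings,
        }
    return section


def _qsar_stage(config: RunConfig) -> dict:
    training = vio.read_descriptor_table(config.inputs.qsar_training)
    model = fit_mlr(training, response_transform=config.qsar_response_transform)
    report = validate(model, training)
    section = {
        "coefficients": {k: round_sig(v, 6) for k, v in model.coefficients.items()},
        "intercept": round_sig(model.intercept, 6),
        "r": round_half_away(report.r, 4),
        "r_squared": round_half_away(report.r_squared, 4),
        "q_squared_loo": round_half_away(report.q_squared, 4),
    }
    if config.inputs.qsar_testing is not None:
        testing = vio.read_descriptor_table(config.inputs.qsar_testing)
        preds = predict(model, testing)
        ids = testing.get("compound_id", pd.Series(range(len(preds))))
        section["predictions"] = {
            str(i): (None if pd.isna(p) else round_sig(float(p), 4))
            for i, p in zip(ids, preds)
        }
    return section
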