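"""Delimited-text readers and writers for every stage's tables.

All formats are plain comma-separated text.  Series files that need
scalar metadata (A0, band maxima, heating rate) carry it in leading
``# key=value`` comment lines, so a file is self-describing::

    # a0=0.5
    # lambda_free_nm=265
    # lambda_bound_nm=259
    dna_M,absorbance
    1e-07,0.503
    ...
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .dna_binding import TitrationSeries
from .formulas import CompoundRecord, parse_formula
from .molar_ratio import MolarRatioSeries
from .qsar import normalize_columns
from .tga import ThermogramCurve

PathLike = Union[str, Path]

__all__ = [
    "read_compound_table",
    "write_compound_table",
    "read_orbital_table",
    "read_titration",
    "write_titration",
    "read_thermogram",
    "write_thermogram",
    "read_molar_ratio",
    "write_molar_ratio",
    "read_descriptor_table",
    "write_json",
]


def _read_with_metadata(path: PathLike) -> tuple[dict[str, str], pd.DataFrame]:
    meta: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("#").strip().partition("=")
            if value:
                meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    frame = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    return meta, frame


def _write_with_metadata(
    path: PathLike, meta: dict[str, object], frame: pd.DataFrame
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in meta.items():
            if value is not None:
                fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=False)


def read_compound_table(path: PathLike) -> list[CompoundRecord]:
    """Read a compound table (columns: id, formula, role, mass)."""
    frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        mass = row.get("mass")
        records.append(
            CompoundRecord(
                identifier=str(row["id"]),
                formula=parse_formula(str(row["formula"])),
                role=str(row["role"]),
                nominal_mass=None if pd.isna(mass) else float(mass),
            )
        )
    return records


def write_compound_table(path: PathLike, records: list[CompoundRecord]) -> None:
    pd.DataFrame(
        {
            "id": [r.identifier for r in records],
            "formula": [str(r.formula) for r in records],
            "role": [r.role for r in records],
            "mass": [r.nominal_mass for r in records],
        }
    ).to_csv(path, index=False)


def read_orbital_table(path: PathLike) -> pd.DataFrame:
    """Read frontier-orbital energies (columns: id, e_homo_eV, e_lumo_eV)."""
    frame = pd.read_csv(path)
    required = {"id", "e_homo_eV", "e_lumo_eV"}
    if not required <= set(frame.columns):
        raise ValueError(f"orbital table must have columns {sorted(required)}")
    return frame


def read_titration(path: PathLike) -> TitrationSeries:
    meta, frame = _read_with_metadata(path)
    if "a0" not in meta:
        raise ValueError("titration file must carry '# a0=...' metadata")
    return TitrationSeries(
        a0=float(meta["a0"]),
        dna_concentration=frame["dna_M"].to_numpy(float),
        absorbance=frame["absorbance"].to_numpy(float),
        lambda_free=float(meta["lambda_free_nm"]) if "lambda_free_nm" in meta else None,
        lambda_bound=float(meta["lambda_bound_nm"]) if "lambda_bound_nm" in meta else None,
    )


def write_titration(path: PathLike, series: TitrationSeries) -> None:
    _write_with_metadata(
        path,
        {
            "a0": series.a0,
            "lambda_free_nm": series.lambda_free,
            "lambda_bound_nm": series.lambda_bound,
        },
        pd.DataFrame(
            {"dna_M": series.dna_concentration, "absorbance": series.absorbance}
        ),
    )


def read_thermogram(path: PathLike) -> ThermogramCurve:
    meta, frame = _read_with_metadata(path)
    if "beta_K_per_min" not in meta:
        raise ValueError("thermogram file must carry '# beta_K_per_min=...' metadata")
    beta = float(meta["beta_K_per_min"])
    if "temperature_K" in frame.columns:
        return ThermogramCurve(
            frame["temperature_K"].to_numpy(float),
            frame["mass_percent"].to_numpy(float),
            beta,
        )
    if "temperature_C" in frame.columns:
        return ThermogramCurve.from_celsius(
            frame["temperature_C"].to_numpy(float),
            frame["mass_percent"].to_numpy(float),
            beta,
        )
    raise ValueError("thermogram needs a temperature_K or temperature_C column")


def write_thermogram(path: PathLike, curve: ThermogramCurve) -> None:
    _write_with_metadata(
        path,
        {"beta_K_per_min": curve.heating_rate_beta},
        pd.DataFrame(
            {"temperature_K": curve.temperature, "mass_percent": curve.mass_percent}
        ),
    )


def read_molar_ratio(path: PathLike) -> MolarRatioSeries:
    frame = pd.read_csv(path)
    return MolarRatioSeries(
        frame["mole_fraction_metal"].to_numpy(float),
        frame["absorbance"].to_numpy(float),
    )


def write_molar_ratio(path: PathLike, series: MolarRatioSeries) -> None:
    pd.DataFrame(
        {
            "mole_fraction_metal": series.mole_fraction_metal,
            "absorbance": series.absorbance,
        }
    ).to_csv(path, index=False)


def read_descriptor_table(path: PathLike) -> pd.DataFrame:
    """Read a QSAR descriptor table, accepting h_pkb/h_pkp header variants."""
    return normalize_columns(pd.read_csv(path))


def write_json(path: PathLike, payload: dict) -> None:
    """Deterministic JSON output (sorted keys, fixed float formatting)."""
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )
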