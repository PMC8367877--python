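"""Readers, writers and pipeline configuration.

File dialects (all plain text, UTF-8, "." decimal separator):

* **energy table CSV** — one row per conformer x solvent with columns
  ``compound_id, microstate_id, formal_charge, conformer_id, source_set,
  solvent, E_sol_kcal, mu_ex_corr_kcal``;
* **multi-record XYZ** — standard XYZ blocks whose comment line carries
  ``id=<text> E=<float> kcal/mol``;
* **SDF** (read-only, requires rdkit) — conformer energies taken from a
  configurable property field.

Solvent names are fixed strings "water"/"octanol" in files; internally they
are opaque labels, so a cyclohexane-water reuse only needs configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .conformers import ClusterConfig, ConformerGeometry
from .ensemble_thermo import (
    CompoundStateModel,
    ConformerRecord,
    MicrostateEnsemble,
    SolventEnergies,
    ThermoSettings,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ENERGY_TABLE_COLUMNS",
    "PipelineConfig",
    "read_energy_table",
    "write_energy_table",
    "models_to_table",
    "read_structures",
    "write_xyz",
]

ENERGY_TABLE_COLUMNS = [
    "compound_id", "microstate_id", "formal_charge", "conformer_id",
    "source_set", "solvent", "E_sol_kcal", "mu_ex_corr_kcal",
]

_KEY_COLUMNS = ["compound_id", "microstate_id", "conformer_id", "solvent"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of the end-to-end pipeline."""

    energies: str = ""
    experimental: str = ""
    output_dir: str = "microthermo_out"
    temperature: float = 298.15
    ph: float = 7.4
    lfer_a: float | None = None  # None -> physical slope 1/(RT ln 10)
    lfer_b: float = 0.0
    solvent_aqueous: str = "water"
    solvent_organic: str = "octanol"
    energy_window: float = 20.0
    rmsd_cutoff: float = 0.5
    max_representatives: int = 5
    output_precision: int = 2
    reference_microstate: str = ""
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path}: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(
                f"config {path}: unknown keys {unknown}; valid keys: {sorted(known)}"
            )
        return cls(**raw)

    def thermo_settings(self) -> ThermoSettings:
        return ThermoSettings(temperature=self.temperature, ph=self.ph)

    def cluster_config(self) -> ClusterConfig:
        return ClusterConfig(
            energy_window=self.energy_window,
            rmsd_cutoff=self.rmsd_cutoff,
            max_representatives=self.max_representatives,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _validate_energy_frame(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in ENERGY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{origin}: missing columns {missing}")
    for col in ("E_sol_kcal", "mu_ex_corr_kcal"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            row = int(bad[0])
            raise ValueError(
                f"{origin}: non-numeric {col} at row {row + 2} "
                f"(value {df.loc[row, col]!r})"
            )
        df[col] = numeric
    if not np.isfinite(df[["E_sol_kcal", "mu_ex_corr_kcal"]].to_numpy()).all():
        raise ValueError(f"{origin}: non-finite energy values present")
    dup = df.duplicated(subset=_KEY_COLUMNS, keep=False)
    if dup.any():
        row = int(df.index[dup][0])
        key = tuple(df.loc[row, _KEY_COLUMNS])
        raise ValueError(
            f"{origin}: duplicate (compound, microstate, conformer, solvent) "
            f"key {key} first seen at row {row + 2}"
        )
    df["formal_charge"] = df["formal_charge"].astype(int)
    return df


def table_to_models(df: pd.DataFrame, origin: str = "energy table") -> list[CompoundStateModel]:
    """Group a validated energy table into compound state models."""
    df = _validate_energy_frame(df.copy(), origin)
    models: list[CompoundStateModel] = []
    for cid, cgrp in df.groupby("compound_id", sort=False):
        microstates: list[MicrostateEnsemble] = []
        for ms_id, mgrp in cgrp.groupby("microstate_id", sort=False):
            charges = mgrp["formal_charge"].unique()
            if len(charges) > 1:
                raise ValueError(
                    f"{origin}: microstate {ms_id!r} has conflicting formal "
                    f"charges {sorted(int(q) for q in charges)}"
                )
            conformers: list[ConformerRecord] = []
            for conf_id, kgrp in mgrp.groupby("conformer_id", sort=False):
                terms = {
                    row.solvent: SolventEnergies(
                        e_sol=float(row.E_sol_kcal),
                        mu_ex_corr=float(row.mu_ex_corr_kcal),
                    )
                    for row in kgrp.itertuples()
                }
                source = kgrp["source_set"].iloc[0]
                conformers.append(
                    ConformerRecord(
                        conformer_id=str(conf_id),
                        microstate_id=str(ms_id),
                        energy_terms=terms,
                        source_set=str(source),
                    )
                )
            microstates.append(
                MicrostateEnsemble(
                    microstate_id=str(ms_id),
                    formal_charge=int(charges[0]),
                    conformers=tuple(conformers),
                )
            )
        models.append(CompoundStateModel(compound_id=str(cid), microstates=tuple(microstates)))
    logger.info(
        "%s: loaded %d rows -> %d compounds, %d microstates",
        origin, len(df), len(models), sum(len(m.microstates) for m in models),
    )
    return models


def read_energy_table(path: str | Path) -> list[CompoundStateModel]:
    """Read and validate an energy-table CSV, grouped by compound."""
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    return table_to_models(df, origin=str(path))


def models_to_table(models: Sequence[CompoundStateModel]) -> pd.DataFrame:
    rows = []
    for model in models:
        for ms in model.microstates:
            for conf in ms.conformers:
                for solvent, terms in conf.energy_terms.items():
                    rows.append(
                        (model.compound_id, ms.microstate_id, ms.formal_charge,
                         conf.conformer_id, conf.source_set, solvent,
                         terms.e_sol, terms.mu_ex_corr)
                    )
    return pd.DataFrame(rows, columns=ENERGY_TABLE_COLUMNS)


def write_energy_table(
    data: pd.DataFrame | Sequence[CompoundStateModel], path: str | Path
) -> None:
    """Write an energy table (DataFrame or state models) as CSV."""
    if not isinstance(data, pd.DataFrame):
        data = models_to_table(data)
    missing = [c for c in ENERGY_TABLE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"energy table missing columns: {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data.to_csv(path, index=False, encoding="utf-8")


# --------------------------------------------------------------------------
# Structures


def write_xyz(geoms: Sequence[ConformerGeometry], path: str | Path) -> None:
    """Write a multi-record XYZ file; the comment line carries the id and
    energy as ``id=<text> E=<float> kcal/mol``."""
    lines: list[str] = []
    for g in geoms:
        lines.append(str(g.n_atoms))
        lines.append(f"id={g.conformer_id} E={g.energy:.10g} kcal/mol")
        for label, (x, y, z) in zip(g.atom_labels, g.coordinates):
            lines.append(f"{label} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_xyz(path: Path) -> list[ConformerGeometry]:
    lines = path.read_text(encoding="utf-8").splitlines()
    geoms: list[ConformerGeometry] = []
    i = 0
    record = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}: expected atom count at line {i + 1}")
        if i + 1 + n >= len(lines) + 1:
            raise ValueError(f"{path}: truncated record at line {i + 1}")
        comment = lines[i + 1].strip()
        conf_id, energy = f"conf{record}", math.nan
        for tok in comment.split():
            if tok.startswith("id="):
                conf_id = tok[3:]
            elif tok.startswith("E="):
                energy = float(tok[2:])
        if math.isnan(energy):
            raise ValueError(
                f"{path}: record {record} comment line lacks 'E=<float>': "
                f"{comment!r}"
            )
        labels: list[str] = []
        coords: list[list[float]] = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed atom line {i + 3 + j}")
            labels.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        geoms.append(
            ConformerGeometry(
                conformer_id=conf_id,
                coordinates=np.array(coords),
                atom_labels=tuple(labels),
                energy=energy,
            )
        )
        record += 1
        i += 2 + n
    _check_consistent_atoms(geoms, str(path))
    return geoms


def _check_consistent_atoms(geoms: Sequence[ConformerGeometry], origin: str) -> None:
    if not geoms:
        return
    first = geoms[0]
    for g in geoms[1:]:
        if g.n_atoms != first.n_atoms or g.atom_labels != first.atom_labels:
            raise ValueError(
                f"{origin}: conformer {g.conformer_id!r} has different atoms "
                f"({g.n_atoms}) than {first.conformer_id!r} ({first.n_atoms})"
            )


def _parse_sdf(path: Path, energy_property: str) -> list[ConformerGeometry]:
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading SDF files requires rdkit") from exc
    geoms: list[ConformerGeometry] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for k, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: unparseable molecule record {k}")
        if not mol.HasProp(energy_property):
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record {k}"
            raise ValueError(
                f"{path}: {name} lacks the configured energy property "
                f"{energy_property!r}"
            )
        conf = mol.GetConformer()
        coords = np.array(conf.GetPositions(), dtype=float)
        labels = tuple(a.GetSymbol() for a in mol.GetAtoms())
        conf_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"conf{k}"
        geoms.append(
            ConformerGeometry(
                conformer_id=conf_id or f"conf{k}",
                coordinates=coords,
                atom_labels=labels,
                energy=float(mol.GetProp(energy_property)),
            )
        )
    _check_consistent_atoms(geoms, str(path))
    return geoms


def read_structures(
    path: str | Path,
    format: str | None = None,
    energy_property: str = "energy_kcal",
) -> list[ConformerGeometry]:
    """Read conformer geometries from a multi-record XYZ or an SDF file.

    ``format`` defaults to the file suffix.  All records of one file must
    share atom count and element labels (one conformer set).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _parse_xyz(path)
    if fmt == "sdf":
        return _parse_sdf(path, energy_property)
    raise ValueError(f"unsupported structure format {fmt!r} (use xyz or sdf)")


def run_log(config: PipelineConfig) -> dict:
    """Machine-readable provenance record for a pipeline run."""
    import microthermo

    return {
        "package": "microthermo",
        "version": getattr(microthermo, "__version__", "unknown"),
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
    }
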