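"""Boltzmann aggregation of conformer and microstate energies.

A *microstate* is one protonation/tautomer form of a compound, represented in
solution by a small ensemble of conformations.  Each conformation ``c`` of
microstate ``t`` carries, per solvent, an electronic energy ``E_tc`` and a
corrected excess chemical potential ``mu_tc`` (both kcal/mol, produced
upstream by a QM/solvation engine such as EC-RISM).  The microstate Gibbs
energy is the Boltzmann-weighted free energy of its conformer ensemble,

    G_t = -(1/beta) * ln sum_c exp[-beta * (E_tc + mu_tc)],   beta = 1/(RT),

and the *macrostate* (compound-level, fixed formal charge) free energy
extends the sum over the tautomers t of that charge state.  The
octanol-water partition coefficient of the neutral species follows from the
water->octanol transfer free energy,

    log P = (G_wat - G_oct) / (RT ln 10).

Gas-phase energies never appear: they cancel identically between the two
solution phases because the evaporating ensembles are the same.

All energies are kcal/mol at the API boundary; no unit inference is done.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "SolventEnergies",
    "ConformerRecord",
    "MicrostateEnsemble",
    "CompoundStateModel",
    "ThermoSettings",
    "boltzmann_free_energy",
    "microstate_gibbs",
    "compound_gibbs",
    "log_p",
    "combine_conformer_sets",
]

#: Molar gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987204e-3

#: Ambient standard temperature (K) conventional for SAMPL-type measurements.
DEFAULT_TEMPERATURE = 298.15

WATER = "water"
OCTANOL = "octanol"


@dataclass(frozen=True)
class SolventEnergies:
    """Per-solvent energy terms of one conformation.

    Attributes
    ----------
    e_sol : float
        Electronic energy of the solvent-polarized wave function, kcal/mol.
    mu_ex_corr : float
        Corrected excess chemical potential (solvation term), kcal/mol.
    """

    e_sol: float
    mu_ex_corr: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.e_sol) and math.isfinite(self.mu_ex_corr)):
            raise ValueError(
                f"non-finite energy terms: e_sol={self.e_sol}, "
                f"mu_ex_corr={self.mu_ex_corr}"
            )

    @property
    def total(self) -> float:
        """E_sol + mu_ex_corr, the quantity entering the Boltzmann sum."""
        return self.e_sol + self.mu_ex_corr


@dataclass(frozen=True)
class ConformerRecord:
    """One conformation of a microstate with its per-solvent energy terms."""

    conformer_id: str
    microstate_id: str
    energy_terms: Mapping[str, SolventEnergies]
    coordinates: np.ndarray | None = None
    source_set: str = "orig"

    def __post_init__(self) -> None:
        object.__setattr__(self, "energy_terms", dict(self.energy_terms))
        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=float)
            if coords.ndim != 2 or coords.shape[1] != 3:
                raise ValueError(
                    f"conformer {self.conformer_id!r}: coordinates must be N x 3"
                )
            object.__setattr__(self, "coordinates", coords)

    def total_energy(self, solvent: str) -> float:
        try:
            return self.energy_terms[solvent].total
        except KeyError:
            raise KeyError(
                f"conformer {self.conformer_id!r} of microstate "
                f"{self.microstate_id!r} has no energy terms for solvent "
                f"{solvent!r}"
            ) from None


@dataclass(frozen=True)
class MicrostateEnsemble:
    """A protonation/tautomer microstate with its conformer ensemble."""

    microstate_id: str
    formal_charge: int
    conformers: tuple[ConformerRecord, ...]
    tautomer_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "conformers", tuple(self.conformers))
        for c in self.conformers:
            if c.microstate_id != self.microstate_id:
                raise ValueError(
                    f"conformer {c.conformer_id!r} belongs to microstate "
                    f"{c.microstate_id!r}, not {self.microstate_id!r}"
                )

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass(frozen=True)
class CompoundStateModel:
    """All microstates of one compound; the unit of pKa/logP/logD work."""

    compound_id: str
    microstates: tuple[MicrostateEnsemble, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "microstates", tuple(self.microstates))
        seen: set[str] = set()
        for ms in self.microstates:
            if ms.microstate_id in seen:
                raise ValueError(
                    f"duplicate microstate id {ms.microstate_id!r} in compound "
                    f"{self.compound_id!r}"
                )
            seen.add(ms.microstate_id)

    def charges(self) -> list[int]:
        """Distinct formal charges present, descending (acid side first)."""
        return sorted({ms.formal_charge for ms in self.microstates}, reverse=True)

    def macrostate(self, charge: int) -> tuple[MicrostateEnsemble, ...]:
        states = tuple(
            ms for ms in self.microstates if ms.formal_charge == charge
        )
        if not states:
            raise KeyError(
                f"compound {self.compound_id!r} has no microstates with formal "
                f"charge {charge:+d}"
            )
        return states

    def get_microstate(self, microstate_id: str) -> MicrostateEnsemble:
        for ms in self.microstates:
            if ms.microstate_id == microstate_id:
                return ms
        valid = [ms.microstate_id for ms in self.microstates]
        raise KeyError(
            f"microstate {microstate_id!r} not found in compound "
            f"{self.compound_id!r}; valid ids: {valid}"
        )


@dataclass(frozen=True)
class ThermoSettings:
    """Thermodynamic conditions: temperature (K) and pH.

    ``beta = 1/(RT)`` with R in kcal mol^-1 K^-1; all derived quantities
    (RT, RT ln 10) are in kcal/mol.
    """

    temperature: float = DEFAULT_TEMPERATURE
    ph: float = 7.4

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.rt

    @property
    def rt_ln10(self) -> float:
        return self.rt * math.log(10.0)


def boltzmann_free_energy(
    values: Sequence[float], temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Free energy of a discrete ensemble: -(1/beta) ln sum_i exp(-beta v_i).

    Overflow-safe for raw QM-scale energies (|v| ~ 1e5 kcal/mol): the
    log-sum-exp is evaluated with the standard shift by the extreme term,
    i.e. relative to the minimum energy.

    Parameters
    ----------
    values : sequence of float
        Ensemble member energies, kcal/mol.
    temperature : float
        Temperature in K, > 0.

    Returns
    -------
    float
        Ensemble free energy in kcal/mol; always <= min(values).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty ensemble")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"non-finite energy at position {bad}: {arr[bad]}")
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    beta = 1.0 / (GAS_CONSTANT_KCAL * temperature)
    return float(-logsumexp(-beta * arr) / beta)


def microstate_gibbs(
    ensemble: MicrostateEnsemble,
    solvent: str,
    settings: ThermoSettings | None = None,
) -> float:
    """Microstate Gibbs energy: Boltzmann sum over conformer E + mu terms."""
    settings = settings or ThermoSettings()
    if len(ensemble) == 0:
        raise ValueError(f"microstate {ensemble.microstate_id!r}: empty ensemble")
    totals = [c.total_energy(solvent) for c in ensemble.conformers]
    return boltzmann_free_energy(totals, settings.temperature)


def compound_gibbs(
    microstates: Sequence[MicrostateEnsemble],
    solvent: str,
    settings: ThermoSettings | None = None,
) -> float:
    """Macrostate Gibbs energy: double Boltzmann sum over tautomers and
    conformers of one charge state.

    Algebraically identical to :func:`boltzmann_free_energy` applied to the
    pooled per-conformer energies of all member microstates.  Mixing formal
    charges is rejected: the partition sum is only meaningful within one
    charge macrostate (for log P, the neutral one).
    """
    settings = settings or ThermoSettings()
    states = list(microstates)
    if not states:
        raise ValueError("empty macrostate: no microstates given")
    charges = {ms.formal_charge for ms in states}
    if len(charges) > 1:
        raise ValueError(
            f"mixed formal charges in macrostate: {sorted(charges)}; the "
            "partition sum applies within a single charge state"
        )
    totals = [
        c.total_energy(solvent) for ms in states for c in ms.conformers
    ]
    if not totals:
        raise ValueError("macrostate has no conformers")
    return boltzmann_free_energy(totals, settings.temperature)


def log_p(
    g_wat: float, g_oct: float, settings: ThermoSettings | None = None
) -> float:
    """Octanol-water partition coefficient from phase free energies.

    log P = (G_wat - G_oct) / (RT ln 10); positive when the octanol phase
    is the more favorable one.
    """
    settings = settings or ThermoSettings()
    if not (math.isfinite(g_wat) and math.isfinite(g_oct)):
        raise ValueError(f"non-finite phase free energies: {g_wat}, {g_oct}")
    return (g_wat - g_oct) / settings.rt_ln10


def combine_conformer_sets(
    a: MicrostateEnsemble, b: MicrostateEnsemble
) -> MicrostateEnsemble:
    """Pool two conformer sets of the same microstate, keeping duplicates.

    This is the "comb" treatment: the partition function is simply augmented
    with the second set's energies, deliberately ignoring the possibility of
    geometric duplicates (a true duplicate lowers the free energy by
    RT ln 2, by construction of the sum).  Conformer ids colliding across
    the sets are relabelled by suffixing the source-set label so every
    record stays addressable; input order is a-then-b.
    """
    if a.microstate_id != b.microstate_id:
        raise ValueError(
            f"cannot combine different microstates: {a.microstate_id!r} vs "
            f"{b.microstate_id!r}"
        )
    combined: list[ConformerRecord] = list(a.conformers)
    used = {c.conformer_id for c in combined}
    for rec in b.conformers:
        cid = rec.conformer_id
        if cid in used:
            cid = f"{rec.conformer_id}:{rec.source_set}"
            n = 1
            while cid in used:
                cid = f"{rec.conformer_id}:{rec.source_set}{n}"
                n += 1
            rec = replace(rec, conformer_id=cid)
        used.add(cid)
        combined.append(rec)
    return MicrostateEnsemble(
        microstate_id=a.microstate_id,
        formal_charge=a.formal_charge,
        conformers=tuple(combined),
        tautomer_label=a.tautomer_label,
    )
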