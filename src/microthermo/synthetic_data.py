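"""Synthetic energy tables and conformer clouds with known ground truth.

The generator emulates the *outputs* of a QM/solvation pipeline — per
conformer and solvent, an electronic energy and a corrected excess chemical
potential — for compounds with a prescribed macroscopic pKa and log P, so
that every downstream stage (Boltzmann aggregation, PF/ST pKa, log P,
log D, clustering) can be tested against exact truths without any external
engine.

Construction inverts the analysis: target macrostate free energies are
derived from the true pKa and log P through the physical LFER and the
transfer-free-energy relation, then each macrostate free energy is split
into tautomer and conformer contributions whose Boltzmann sum reproduces
the target *exactly* (relative energies are drawn randomly, then shifted by
a constant so the partition sum is conserved).  With zero table noise the
pipeline therefore recovers the truths to numerical precision; any
discrepancy is a pipeline bug, not generator bias.

Also here: the packaged SAMPL7 reference tables (experimental values and
the EC-RISM challenge predictions) as ready-made prediction tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import _sampl7
from .conformers import ConformerGeometry, kabsch_rmsd
from .ensemble_thermo import (
    ThermoSettings,
    boltzmann_free_energy,
)
from .stats import PredictionTable

__all__ = [
    "SyntheticSpec",
    "CompoundTruth",
    "CloudTruth",
    "GroundTruth",
    "generate_energy_tables",
    "generate_conformer_clouds",
    "sampl7_prediction_tables",
    "sampl7_pka_table",
    "sampl7_logp_logd_table",
]

#: energy-table CSV dialect shared with the readers/writers
ENERGY_TABLE_COLUMNS = [
    "compound_id", "microstate_id", "formal_charge", "conformer_id",
    "source_set", "solvent", "E_sol_kcal", "mu_ex_corr_kcal",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic energy-table generator.

    Defaults mirror the structure of the SAMPL7 inputs: one neutral and one
    anionic macrostate per compound, 1-3 tautomers per macrostate, 1-5
    conformations per microstate with relative energies spread over a few
    kcal/mol, true pKa in the measured 4-11 range and true log P in the
    predicted -1..6 range.  ``table_noise_sd`` adds Gaussian noise (kcal/mol)
    to every per-conformer, per-solvent energy after construction.
    """

    seed: int
    n_compounds: int = 22
    tautomers_per_macrostate: tuple[int, int] = (1, 3)
    conformers_per_microstate: tuple[int, int] = (1, 5)
    conformer_energy_spread: float = 2.0
    true_pka_range: tuple[float, float] = (4.0, 11.0)
    true_logp_range: tuple[float, float] = (-1.0, 6.0)
    table_noise_sd: float = 0.0
    temperature: float = 298.15
    ph: float = 7.4

    def __post_init__(self) -> None:
        for name in ("tautomers_per_macrostate", "conformers_per_microstate"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")
        for name in ("true_pka_range", "true_logp_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.table_noise_sd < 0 or self.conformer_energy_spread < 0:
            raise ValueError("spreads must be non-negative")


@dataclass(frozen=True)
class CompoundTruth:
    pka: float
    logp: float
    logd: float  # at the spec's pH, logp - log10(1 + 10**(ph - pka))


@dataclass(frozen=True)
class CloudTruth:
    """Cluster memberships of a generated conformer cloud."""

    n_clusters: int
    memberships: tuple[int, ...]


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    compounds: dict[str, CompoundTruth]
    #: (compound_id, microstate_id, solvent) -> exact pre-noise Gibbs energy
    microstate_gibbs: dict[tuple[str, str, str], float]
    spec: SyntheticSpec | None = None


def _split_free_energy(
    rng: np.random.Generator,
    target: float,
    n_per_microstate: Sequence[int],
    spread: float,
    temperature: float,
) -> list[np.ndarray]:
    """Split a macrostate free energy into per-conformer energies.

    Draws non-negative relative energies (tautomer offset plus conformer
    jitter, uniform on [0, spread]), then shifts all of them by the constant
    that makes the pooled Boltzmann sum equal ``target`` exactly.
    """
    rel: list[np.ndarray] = []
    for n_conf in n_per_microstate:
        taut_offset = rng.uniform(0.0, spread)
        conf = rng.uniform(0.0, spread, size=n_conf)
        conf[0] = 0.0  # anchor the microstate minimum at its offset
        rel.append(taut_offset + conf)
    pooled = np.concatenate(rel)
    shift = target - boltzmann_free_energy(pooled, temperature)
    return [r + shift for r in rel]


def generate_energy_tables(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a per-conformer energy table with exact known truths.

    Returns the energy table in the package CSV dialect (one row per
    conformer x solvent) and the :class:`GroundTruth` carrying the true
    macroscopic pKa, log P and log D per compound plus the exact pre-noise
    per-microstate Gibbs energies.
    """
    rng = np.random.default_rng(spec.seed)
    settings = ThermoSettings(temperature=spec.temperature, ph=spec.ph)
    rows: list[tuple] = []
    compounds: dict[str, CompoundTruth] = {}
    ms_gibbs: dict[tuple[str, str, str], float] = {}

    for i in range(spec.n_compounds):
        cid = f"SYN{i:03d}"
        pka = rng.uniform(*spec.true_pka_range)
        logp = rng.uniform(*spec.true_logp_range)
        logd = logp - math.log10(1.0 + 10.0 ** (spec.ph - pka))
        compounds[cid] = CompoundTruth(pka=pka, logp=logp, logd=logd)

        g_neutral_wat = rng.uniform(-120.0, -80.0)
        # physical LFER: pKa = (G_anion - G_neutral) / (RT ln 10)
        # transfer relation: log P = (G_wat - G_oct) / (RT ln 10)
        targets = {
            (0, "water"): g_neutral_wat,
            (0, "octanol"): g_neutral_wat - logp * settings.rt_ln10,
            (-1, "water"): g_neutral_wat + pka * settings.rt_ln10,
            # anion octanol energies are present but thermodynamically inert
            (-1, "octanol"): g_neutral_wat + pka * settings.rt_ln10
            + rng.uniform(2.0, 8.0),
        }

        for charge in (0, -1):
            n_taut = int(rng.integers(spec.tautomers_per_macrostate[0],
                                      spec.tautomers_per_macrostate[1] + 1))
            n_conf = [
                int(rng.integers(spec.conformers_per_microstate[0],
                                 spec.conformers_per_microstate[1] + 1))
                for _ in range(n_taut)
            ]
            per_solvent: dict[str, list[np.ndarray]] = {}
            for solvent in ("water", "octanol"):
                per_solvent[solvent] = _split_free_energy(
                    rng, targets[(charge, solvent)], n_conf,
                    spec.conformer_energy_spread, spec.temperature,
                )
            for t in range(n_taut):
                ms_id = f"{cid}_q{charge:+d}_t{t}"
                for solvent in ("water", "octanol"):
                    totals = per_solvent[solvent][t]
                    ms_gibbs[(cid, ms_id, solvent)] = boltzmann_free_energy(
                        totals, spec.temperature
                    )
                    for c, total in enumerate(totals):
                        noisy = total + (
                            rng.normal(0.0, spec.table_noise_sd)
                            if spec.table_noise_sd > 0 else 0.0
                        )
                        mu = rng.normal(-8.0, 3.0)
                        rows.append(
                            (cid, ms_id, charge, f"conf{c}", "orig",
                             solvent, noisy - mu, mu)
                        )

    table = pd.DataFrame(rows, columns=ENERGY_TABLE_COLUMNS)
    truth = GroundTruth(compounds=compounds, microstate_gibbs=ms_gibbs, spec=spec)
    return table, truth


def generate_conformer_clouds(
    seed: int,
    n_clusters: int,
    jitter_sd: float,
    centroid_separation: float,
    points_per_cluster: int,
    n_atoms: int = 8,
) -> tuple[list[ConformerGeometry], CloudTruth]:
    """Conformer clouds with known cluster structure.

    ``n_clusters`` reference conformations are drawn with pairwise
    superposition RMSD >= ``centroid_separation``; each cloud member is the
    cluster reference plus per-atom Gaussian jitter, then an arbitrary
    rigid rotation + translation so raw coordinates differ even within a
    cluster.  Energies increase with the global index (cluster-major), so
    the first member of each cloud is its energy minimum.  Requires
    ``centroid_separation > 4 * jitter_sd`` for separability.
    """
    if not centroid_separation > 4.0 * jitter_sd:
        raise ValueError(
            f"separability violated: centroid_separation={centroid_separation} "
            f"must exceed 4 * jitter_sd = {4.0 * jitter_sd}"
        )
    if n_clusters < 1 or points_per_cluster < 1 or n_atoms < 3:
        raise ValueError("need n_clusters >= 1, points_per_cluster >= 1, n_atoms >= 3")
    rng = np.random.default_rng(seed)
    labels = ("C",) * n_atoms

    def _pairwise_ok(refs: list[np.ndarray]) -> bool:
        geoms = [
            ConformerGeometry(f"ref{k}", r, labels, 0.0)
            for k, r in enumerate(refs)
        ]
        return all(
            kabsch_rmsd(geoms[i], geoms[j]) >= centroid_separation
            for i in range(len(geoms)) for j in range(i + 1, len(geoms))
        )

    sigma = max(centroid_separation, 1.0)
    for _ in range(200):
        refs = [rng.normal(0.0, sigma, size=(n_atoms, 3)) for _ in range(n_clusters)]
        if _pairwise_ok(refs):
            break
    else:
        raise RuntimeError(
            "could not draw cluster references with the requested separation"
        )

    geoms: list[ConformerGeometry] = []
    memberships: list[int] = []
    idx = 0
    for k, ref in enumerate(refs):
        for _ in range(points_per_cluster):
            coords = ref + rng.normal(0.0, jitter_sd, size=(n_atoms, 3))
            rot = Rotation.random(rng=rng).as_matrix()
            coords = coords @ rot.T + rng.uniform(-10.0, 10.0, size=3)
            geoms.append(
                ConformerGeometry(
                    conformer_id=f"cloud{k}_p{idx}",
                    coordinates=coords,
                    atom_labels=labels,
                    energy=0.5 * idx,
                )
            )
            memberships.append(k)
            idx += 1
    return geoms, CloudTruth(n_clusters=n_clusters, memberships=tuple(memberships))


# --------------------------------------------------------------------------
# Packaged SAMPL7 reference tables


def sampl7_pka_table() -> pd.DataFrame:
    """Per-compound SAMPL7 pKa data: experimental and EC-RISM variants."""
    rows = [
        (cid, *vals) for cid, vals in _sampl7.PKA_TABLE.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["compound_id", "pka_exp", "pka_calc_orig_pf",
                 "pka_calc_orig_st", "pka_calc_new_st", "pka_calc_comb_st"],
    )


def sampl7_logp_logd_table() -> pd.DataFrame:
    """Per-compound SAMPL7 log P / log D data (pH 7.4)."""
    rows = [(cid, *vals) for cid, vals in _sampl7.LOGP_LOGD_TABLE.items()]
    return pd.DataFrame(
        rows,
        columns=["compound_id", "logp_exp", "logp_calc_orig", "logp_calc_new",
                 "logp_calc_comb", "logd_exp_direct", "logd_exp_indirect",
                 "logd_calc_orig", "logd_calc_new", "logd_calc_comb"],
    )


def sampl7_prediction_tables() -> dict[str, PredictionTable]:
    """The SAMPL7 reference data as aligned prediction tables.

    Keys: ``pka_{orig_pf,orig_st,new_st,comb_st}`` (experimental pKa vs
    the EC-RISM variant; compounds without experimental pKa are dropped),
    ``logp_{orig,new,comb}`` and ``logd_{orig,new,comb}`` (the latter vs
    the directly measured experimental log D), plus
    ``logd_indirect_{orig,new,comb}`` vs the reconstructed experimental
    values.
    """
    pka = sampl7_pka_table()
    lp = sampl7_logp_logd_table()
    out: dict[str, PredictionTable] = {}
    for variant in ("orig_pf", "orig_st", "new_st", "comb_st"):
        out[f"pka_{variant}"] = PredictionTable(
            pd.DataFrame({
                "compound_id": pka["compound_id"],
                "predicted": pka[f"pka_calc_{variant}"],
                "experimental": pka["pka_exp"],
            }),
            property_label=f"pKa ({variant})",
        )
    for variant in ("orig", "new", "comb"):
        out[f"logp_{variant}"] = PredictionTable(
            pd.DataFrame({
                "compound_id": lp["compound_id"],
                "predicted": lp[f"logp_calc_{variant}"],
                "experimental": lp["logp_exp"],
            }),
            property_label=f"logP ({variant})",
        )
        for exp_col, key in (("logd_exp_direct", f"logd_{variant}"),
                             ("logd_exp_indirect", f"logd_indirect_{variant}")):
            out[key] = PredictionTable(
                pd.DataFrame({
                    "compound_id": lp["compound_id"],
                    "predicted": lp[f"logd_calc_{variant}"],
                    "experimental": lp[exp_col],
                }),
                property_label=f"logD7.4 ({variant}, {exp_col})",
            )
    return out
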