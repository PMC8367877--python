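"""End-to-end pipeline: energies -> pKa (PF+ST) -> log P -> log D -> metrics.

The unit of work is one compound state model (all microstates with their
conformer energies in water and octanol).  For each compound the pipeline

1. Boltzmann-aggregates microstate and macrostate Gibbs energies,
2. computes every adjacent-charge macroscopic pKa by both formalisms,
3. computes log P from the neutral macrostate's phase free energies,
4. converts to log D at the working pH using the headline
   (neutral -> anion) pKa — skipping negative predicted pKa values by
   default, and falling back to log D = log P when no usable pKa exists,
5. evaluates challenge statistics when an experimental table is supplied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .acidity import LferModel, MacroPkaResult, compound_macro_pka
from .distribution import (
    ConventionFlag,
    DistributionResult,
    IonizationProfile,
    log_d,
    log_d_no_pka,
)
from .ensemble_thermo import CompoundStateModel, ThermoSettings, compound_gibbs, log_p
from .io import PipelineConfig, read_energy_table, run_log
from .stats import MetricsReport, PredictionTable, evaluate

logger = logging.getLogger(__name__)

__all__ = ["CompoundResult", "PipelineReport", "run_pipeline", "process_compound"]


@dataclass(frozen=True)
class CompoundResult:
    compound_id: str
    macro_pkas: tuple[MacroPkaResult, ...]
    logp: float | None
    distribution: DistributionResult | None

    @property
    def headline_pka(self) -> MacroPkaResult | None:
        for r in self.macro_pkas:
            if r.headline:
                return r
        return None


@dataclass(frozen=True)
class PipelineReport:
    results: tuple[CompoundResult, ...]
    metrics: dict[str, MetricsReport]
    log: dict


def process_compound(
    model: CompoundStateModel,
    lfer: LferModel,
    settings: ThermoSettings,
    aqueous: str = "water",
    organic: str = "octanol",
    include_negative_pka: bool = False,
    reference: str | None = None,
) -> CompoundResult:
    """All derived properties of one compound."""
    charges = model.charges()
    pkas = tuple(compound_macro_pka(model, lfer, settings, reference))

    logp_value: float | None = None
    dist: DistributionResult | None = None
    if 0 in charges:
        neutral = model.macrostate(0)
        g_wat = compound_gibbs(neutral, aqueous, settings)
        g_oct = compound_gibbs(neutral, organic, settings)
        logp_value = log_p(g_wat, g_oct, settings)
        headline = next((r for r in pkas if r.headline), None)
        if headline is not None and (include_negative_pka or headline.pka_st > 0):
            dist = log_d(
                logp_value,
                IonizationProfile.monoprotic_acid(headline.pka_st, settings.ph),
            )
        else:
            dist = log_d_no_pka(logp_value)
    return CompoundResult(
        compound_id=model.compound_id,
        macro_pkas=pkas,
        logp=logp_value,
        distribution=dist,
    )


def _metrics_tables(
    results: tuple[CompoundResult, ...], experimental: pd.DataFrame
) -> dict[str, MetricsReport]:
    pred = {
        r.compound_id: r for r in results
    }
    out: dict[str, MetricsReport] = {}
    spec = {
        "pka": ("pka_exp", lambda r: r.headline_pka.pka_st if r.headline_pka else None),
        "logp": ("logp_exp", lambda r: r.logp),
        "logd": ("logd_exp", lambda r: r.distribution.log_d if r.distribution else None),
    }
    for prop, (col, getter) in spec.items():
        if col not in experimental.columns:
            continue
        rows = []
        for rec in experimental.itertuples():
            r = pred.get(rec.compound_id)
            if r is None:
                continue
            p = getter(r)
            if p is None:
                continue
            rows.append((rec.compound_id, p, getattr(rec, col)))
        if len(rows) >= 3:
            out[prop] = evaluate(
                PredictionTable.from_pairs(rows, property_label=prop)
            )
    return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis described by a :class:`PipelineConfig`.

    Writes per-compound pKa, log P and log D tables, a metrics table when
    experimental data are configured, and a machine-readable run log into
    ``config.output_dir``.  Stage failures are re-raised with the stage and
    compound named.
    """
    settings = config.thermo_settings()
    lfer = (
        LferModel(config.lfer_a, config.lfer_b)
        if config.lfer_a is not None
        else LferModel.physical(settings)
    )
    if not config.energies:
        raise ValueError("pipeline config has no energy table path")
    models = read_energy_table(config.energies)
    if not models:
        raise ValueError(f"{config.energies}: no compounds found")

    results: list[CompoundResult] = []
    for model in models:
        try:
            results.append(
                process_compound(
                    model, lfer, settings,
                    aqueous=config.solvent_aqueous,
                    organic=config.solvent_organic,
                    reference=config.reference_microstate or None,
                )
            )
        except Exception as exc:
            raise RuntimeError(
                f"property stage failed for compound {model.compound_id!r}: {exc}"
            ) from exc

    metrics: dict[str, MetricsReport] = {}
    if config.experimental:
        exp = pd.read_csv(config.experimental, encoding="utf-8")
        if "compound_id" not in exp.columns:
            raise ValueError(f"{config.experimental}: missing compound_id column")
        metrics = _metrics_tables(tuple(results), exp)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nd = config.output_precision

    pka_rows = [
        (r.compound_id, m.charge_from, m.charge_to,
         round(m.pka_pf, nd), round(m.pka_st, nd),
         m.reference_microstate, m.headline)
        for r in results for m in r.macro_pkas
    ]
    pd.DataFrame(
        pka_rows,
        columns=["compound_id", "charge_from", "charge_to", "pka_pf",
                 "pka_st", "reference_microstate", "headline"],
    ).to_csv(out_dir / "macro_pka.csv", index=False)

    prop_rows = []
    for r in results:
        if r.logp is None:
            continue
        d = r.distribution
        prop_rows.append(
            (r.compound_id, round(r.logp, nd),
             round(r.headline_pka.pka_st, nd) if r.headline_pka else "",
             round(d.log_d, nd), d.neutral_fraction_aq,
             d.convention_flag.value)
        )
    pd.DataFrame(
        prop_rows,
        columns=["compound_id", "log_p", "pka_used", "log_d",
                 "neutral_fraction", "convention_flag"],
    ).to_csv(out_dir / "logp_logd.csv", index=False)

    if metrics:
        pd.DataFrame([m.to_dict() for m in metrics.values()]).to_csv(
            out_dir / "metrics.csv", index=False
        )

    log = run_log(config)
    log["n_compounds"] = len(results)
    (out_dir / "run_log.json").write_text(
        json.dumps(log, indent=2), encoding="utf-8"
    )
    for stage, count in (
        ("aggregate", sum(len(m.microstates) for m in models)),
        ("pka", sum(len(r.macro_pkas) for r in results)),
        ("logp_logd", len(prop_rows)),
        ("evaluate", len(metrics)),
    ):
        logger.info("stage %s: %d item(s)", stage, count)
    return PipelineReport(results=tuple(results), metrics=metrics, log=log)
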